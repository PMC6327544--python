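import math

import numpy as np
import pytest

from tfbind.model import (
    BernoulliComponent,
    GaussianComponent,
    Markov3Component,
    TwoClassModel,
    train_mcl,
)


def _two_gaussian_model(mu_b=1.0, mu_u=-1.0, sigma2=1.0, beta=0.0):
    return TwoClassModel(
        beta_b=beta,
        beta_u=0.0,
        components_b=[GaussianComponent.from_moments(mu_b, sigma2)],
        components_u=[GaussianComponent.from_moments(mu_u, sigma2)],
        families=["gaussian"],
    )


def _simulate_two_class(rng, n, mu_u=0.0, mu_b=2.0):
    nb = n // 2
    x = np.concatenate([rng.normal(mu_u, 1, n - nb), rng.normal(mu_b, 1, nb)])
    y = np.array(["U"] * (n - nb) + ["B"] * nb)
    return x[:, None], y


class TestComponents:
    def test_standard_normal_log_density_closed_form(self):
        g = GaussianComponent(eta1=0.0, eta2=-0.5)
        assert g.log_density(0.0) == pytest.approx(-0.5 * math.log(2 * math.pi))

    def test_natural_parameter_map_both_ways(self):
        g = GaussianComponent.from_moments(2.0, 4.0)
        assert (g.eta1, g.eta2) == (0.5, -0.125)
        assert (g.mu, g.sigma2) == (2.0, 4.0)

    def test_gaussian_requires_negative_eta2(self):
        with pytest.raises(ValueError):
            GaussianComponent(eta1=0.0, eta2=0.1)

    def test_gaussian_density_normalizes(self):
        g = GaussianComponent.from_moments(0.7, 2.3)
        x = np.linspace(-20, 20, 20001)
        total = np.trapezoid(np.exp(g.log_density(x)), x)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_bernoulli_log_density(self):
        b = BernoulliComponent(logit=0.0)
        assert b.p == pytest.approx(0.5)
        assert b.log_density(1.0) == pytest.approx(math.log(0.5))

    def test_markov3_uniform_closed_form(self):
        m = Markov3Component.uniform()
        assert m.log_density("ACGTACGTAC") == pytest.approx(10 * math.log(0.25))

    def test_markov3_rejects_unnormalized_tables(self):
        tables = [np.full(s, math.log(0.3)) for s in [(4,), (4, 4), (4, 4, 4), (4, 4, 4, 4)]]
        with pytest.raises(ValueError, match="sum to 1"):
            Markov3Component(tables)


class TestPosterior:
    def test_identical_components_give_half(self, rng):
        model = _two_gaussian_model(mu_b=0.5, mu_u=0.5)
        x = rng.normal(size=(20, 1))
        np.testing.assert_allclose(model.posterior(x), 0.5)

    def test_large_prior_gap_saturates(self):
        model = _two_gaussian_model(beta=200.0)
        assert model.posterior(np.array([[0.0]]))[0] == pytest.approx(1.0)

    def test_symmetric_classes_cross_at_midpoint(self):
        model = _two_gaussian_model(mu_b=1.0, mu_u=-1.0)
        assert model.posterior(np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_invariant_to_common_beta_shift(self, rng):
        model = _two_gaussian_model(beta=0.3)
        x = rng.normal(size=(10, 1))
        shifted = TwoClassModel(
            beta_b=model.beta_b + 5.0,
            beta_u=model.beta_u + 5.0,
            components_b=model.components_b,
            components_u=model.components_u,
            families=model.families,
        )
        np.testing.assert_allclose(model.posterior(x), shifted.posterior(x), atol=1e-12)

    def test_posterior_from_log_densities(self, rng):
        """P(B|x) ~ exp(beta_B) f_B(x), renormalized."""
        model = _two_gaussian_model(mu_b=1.3, mu_u=-0.4, beta=0.7)
        for x in rng.normal(size=5):
            lb = model.beta_b + model.log_density([x], "B")
            lu = model.beta_u + model.log_density([x], "U")
            expected = 1.0 / (1.0 + math.exp(lu - lb))
            assert model.posterior(np.array([[x]]))[0] == pytest.approx(expected)


class TestTrainMCL:
    def test_duplicating_example_equals_doubling_weight(self, rng):
        X, y = _simulate_two_class(rng, 200)
        w = rng.uniform(0.5, 2.0, 200)
        Xd = np.vstack([X, X[:15]])
        yd = np.concatenate([y, y[:15]])
        wd = np.concatenate([w, w[:15]])
        w2 = w.copy()
        w2[:15] *= 2
        ma = train_mcl(Xd, yd, wd, ["gaussian"])
        mb = train_mcl(X, y, w2, ["gaussian"])
        ga, gb = ma.components_b[0], mb.components_b[0]
        assert ga.eta1 == pytest.approx(gb.eta1, abs=1e-6)
        assert ga.eta2 == pytest.approx(gb.eta2, abs=1e-6)
        assert ma.beta_b - ma.beta_u == pytest.approx(mb.beta_b - mb.beta_u, abs=1e-6)

    def test_decision_boundary_recovered(self, rng):
        """N(0,1) vs N(2,1) data: the Bayes boundary sits near x = 1."""
        X, y = _simulate_two_class(rng, 4000, mu_u=0.0, mu_b=2.0)
        model = train_mcl(X, y, None, ["gaussian"], prior_scale=10.0)
        grid = np.linspace(0, 2, 2001)[:, None]
        post = model.posterior(grid)
        boundary = grid[np.argmin(np.abs(post - 0.5)), 0]
        assert boundary == pytest.approx(1.0, abs=0.1)

    def test_matches_l2_logistic_regression_oracle(self, rng):
        """Fitted posteriors equal an independently optimized L2 logistic
        regression on (x, x^2) sufficient statistics."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = _simulate_two_class(rng, 500)
        w = rng.uniform(0.5, 2.0, 500)
        model = train_mcl(X, y, w, ["gaussian"], prior_scale=1.0)
        D = np.column_stack([X[:, 0], X[:, 0] ** 2])
        wn = w / w.sum()
        mu = wn @ D
        sd = np.sqrt(wn @ (D - mu) ** 2)
        Z = (D - mu) / sd
        clf = sklearn.LogisticRegression(C=1.0, tol=1e-12, max_iter=50_000)
        clf.fit(Z, (y == "B").astype(int), sample_weight=w)
        np.testing.assert_allclose(
            model.posterior(X), clf.predict_proba(Z)[:, 1], atol=1e-4
        )

    def test_two_random_inits_reach_same_objective(self, rng):
        """The MCL objective is concave: random restarts agree to 1e-6."""
        X, y = _simulate_two_class(rng, 300)
        xb = (rng.random(300) < 0.4).astype(float)[:, None]
        X = np.hstack([X, xb])
        fams = ["gaussian", "bernoulli"]
        m1 = train_mcl(X, y, None, fams, init_rng=np.random.default_rng(1))
        m2 = train_mcl(X, y, None, fams, init_rng=np.random.default_rng(2))
        assert m1.fit_info["objective"] == pytest.approx(
            m2.fit_info["objective"], abs=1e-6
        )

    def test_posterior_recovery_large_n(self, rng):
        """Fitted posteriors approach the generating model's posteriors."""
        n = 10_000
        X, y = _simulate_two_class(rng, n, mu_u=-1.0, mu_b=1.0)
        model = train_mcl(X, y, None, ["gaussian"], prior_scale=10.0)
        truth = _two_gaussian_model(mu_b=1.0, mu_u=-1.0)
        err = np.abs(model.posterior(X) - truth.posterior(X)).mean()
        assert err < 0.02

    def test_rejects_single_class_and_nonfinite(self, rng):
        X = rng.normal(size=(10, 1))
        with pytest.raises(ValueError):
            train_mcl(X, ["B"] * 10, None, ["gaussian"])
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_mcl(X, ["B"] * 5 + ["U"] * 5, None, ["gaussian"])

    def test_dimension_mismatch_errors(self, rng):
        X, y = _simulate_two_class(rng, 50)
        model = train_mcl(X, y, None, ["gaussian"])
        with pytest.raises(ValueError):
            model.posterior(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            model.log_density([0.0, 1.0], "B")

    def test_markov3_component_trains_jointly(self, rng):
        """Sequence composition separates the classes; training uses it."""
        seqs, labels = [], []
        for i in range(240):
            p = [0.4, 0.1, 0.1, 0.4] if i < 120 else [0.1, 0.4, 0.4, 0.1]
            seqs.append("".join(rng.choice(list("ACGT"), 25, p=p)))
            labels.append("U" if i < 120 else "B")
        x = rng.normal(size=(240, 1))  # uninformative numeric feature
        model = train_mcl(x, labels, None, ["gaussian", "markov3"], seqs=seqs)
        post = model.posterior(x, seqs=seqs)
        acc = ((post > 0.5) == (np.array(labels) == "B")).mean()
        assert acc > 0.9
        assert model.fit_info["grad_norm"] < 1e-5


class TestSerialization:
    def test_round_trip_exact(self, rng):
        X, y = _simulate_two_class(rng, 200)
        xb = (rng.random(200) < 0.5).astype(float)[:, None]
        model = train_mcl(np.hstack([X, xb]), y, None, ["gaussian", "bernoulli"])
        back = TwoClassModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(
            model.posterior(np.hstack([X, xb])), back.posterior(np.hstack([X, xb]))
        )

    def test_save_load_file(self, tmp_path, rng):
        X, y = _simulate_two_class(rng, 100)
        model = train_mcl(X, y, None, ["gaussian"])
        path = tmp_path / "model.json"
        model.save(path)
        back = TwoClassModel.load(path)
        np.testing.assert_array_equal(model.posterior(X), back.posterior(X))

    def test_version_check(self):
        with pytest.raises(ValueError, match="version"):
            TwoClassModel.from_dict({"version": 99})
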