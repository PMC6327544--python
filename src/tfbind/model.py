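"""Two-class exponential-family classifier trained by weighted discriminative
maximum conditional likelihood (MCL).

Each class ``c`` in {B, U} carries a product of independent components, one per
feature: Gaussian densities for numeric features, Bernoulli distributions for
binary indicator features, and (optionally) a homogeneous Markov model of
order 3 for raw sequence.  All components use their natural parameterization,
so the class log-density is linear in the sufficient statistics ``T(x)``
(``x`` and ``x^2`` for a Gaussian, ``x`` for a Bernoulli, k-mer counts for the
Markov model) minus the log-partition function.  The posterior is

    P(B | x) = sigmoid( (beta_B - beta_U) + log f_B(x) - log f_U(x) ).

MCL maximizes the weighted conditional log-likelihood
``sum_n w_n log P(c_n | x_n)`` with a Gaussian (quadratic) prior on the
parameters.  Because the posterior depends on the natural parameters only
through class differences, the Gaussian/Bernoulli fit is carried out in the
difference parameterization, where the objective is the strictly concave
L2-regularized weighted logistic regression on sufficient statistics; the
fitted difference is then split symmetrically into two normalized class
components, which leaves the posterior unchanged.  Sufficient statistics are
z-scored internally for conditioning; the prior therefore acts on the
standardized-scale coefficients (scale ``prior_scale``, default 1).  When a
sequence component is present its per-class conditional probability tables
are optimized jointly with the rest (smooth but no longer concave).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .motifs import encode

GAUSSIAN = "gaussian"
BERNOULLI = "bernoulli"
MARKOV3 = "markov3"

_SERIAL_VERSION = 1


class ConvergenceError(RuntimeError):
    """Raised when the MCL optimizer fails to reach the gradient tolerance."""


@dataclass
class GaussianComponent:
    """1-D Gaussian in natural parameters: eta1 = mu/sigma^2, eta2 = -1/(2 sigma^2)."""

    eta1: float
    eta2: float  # must be < 0

    def __post_init__(self) -> None:
        if not self.eta2 < 0:
            raise ValueError(f"gaussian eta2 must be negative, got {self.eta2}")

    @classmethod
    def from_moments(cls, mu: float, sigma2: float) -> "GaussianComponent":
        return cls(eta1=mu / sigma2, eta2=-1.0 / (2.0 * sigma2))

    @property
    def mu(self) -> float:
        return -self.eta1 / (2.0 * self.eta2)

    @property
    def sigma2(self) -> float:
        return -1.0 / (2.0 * self.eta2)

    def log_partition(self) -> float:
        return -self.eta1**2 / (4.0 * self.eta2) + 0.5 * math.log(math.pi / -self.eta2)

    def log_density(self, x):
        return self.eta1 * x + self.eta2 * np.square(x) - self.log_partition()


@dataclass
class BernoulliComponent:
    """Bernoulli indicator in natural parameterization (a single logit)."""

    logit: float

    @property
    def p(self) -> float:
        return float(expit(self.logit))

    def log_partition(self) -> float:
        return float(np.logaddexp(0.0, self.logit))

    def log_density(self, x):
        return self.logit * x - self.log_partition()


# k-mer table shapes for orders 0..3 over the 4-letter alphabet
_M3_SHAPES = [(4,), (4, 4), (4, 4, 4), (4, 4, 4, 4)]
_M3_SIZES = [4, 16, 64, 256]
_M3_OFFSETS = np.cumsum([0] + _M3_SIZES)  # 0, 4, 20, 84, 340
M3_DIM = int(_M3_OFFSETS[-1])


@dataclass
class Markov3Component:
    """Homogeneous Markov model of order 3 over A,C,G,T.

    The first three positions use lower-order conditionals (orders 0-2).
    ``log_tables`` holds natural-log conditional probabilities, flattened per
    order; each conditional distribution (last axis) sums to 1.  Positions
    whose base or context contains a non-ACGT symbol are skipped.
    """

    log_tables: list[np.ndarray]  # shapes (4,), (4,4), (4,4,4), (4,4,4,4)

    def __post_init__(self) -> None:
        self.log_tables = [np.asarray(t, dtype=np.float64) for t in self.log_tables]
        for t, shape in zip(self.log_tables, _M3_SHAPES):
            if t.shape != shape:
                raise ValueError(f"markov3 table shape {t.shape} != {shape}")
            sums = np.exp(t).sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("markov3 conditional distributions must sum to 1")

    @classmethod
    def uniform(cls) -> "Markov3Component":
        return cls([np.full(s, math.log(0.25)) for s in _M3_SHAPES])

    def flat(self) -> np.ndarray:
        return np.concatenate([t.ravel() for t in self.log_tables])

    def log_density(self, seq: str) -> float:
        counts = markov3_counts([seq])[0][0]
        return float(counts @ self.flat())


def markov3_counts(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Sufficient statistics of the order-3 Markov model for each sequence.

    Returns ``(counts, context_counts)`` where ``counts`` is (n, 340): k-mer
    occurrence counts flattened per order (order k applies at position k for
    k < 3 and at every position >= 3), and ``context_counts`` is (n, 85)
    (1 + 4 + 16 + 64) holding the corresponding context marginals.
    """
    n = len(seqs)
    counts = np.zeros((n, M3_DIM), dtype=np.float64)
    ctx_sizes = [1, 4, 16, 64]
    ctx_off = np.cumsum([0] + ctx_sizes)
    ctx_counts = np.zeros((n, int(ctx_off[-1])), dtype=np.float64)
    for i, seq in enumerate(seqs):
        codes = encode(seq)
        L = len(codes)
        for pos in range(min(3, L)):
            window = codes[: pos + 1]
            if (window < 0).any():
                continue
            idx = 0
            for c in window:
                idx = idx * 4 + int(c)
            counts[i, _M3_OFFSETS[pos] + idx] += 1
            ctx_idx = idx // 4
            ctx_counts[i, ctx_off[pos] + ctx_idx] += 1
        if L >= 4:
            k = codes[:-3] * 64 + codes[1:-2] * 16 + codes[2:-1] * 4 + codes[3:]
            valid = (
                (codes[:-3] >= 0) & (codes[1:-2] >= 0) & (codes[2:-1] >= 0) & (codes[3:] >= 0)
            )
            np.add.at(counts[i], _M3_OFFSETS[3] + k[valid], 1.0)
            np.add.at(ctx_counts[i], ctx_off[3] + k[valid] // 4, 1.0)
    return counts, ctx_counts


def _normalize_logits(theta: np.ndarray) -> np.ndarray:
    """Per-context log-softmax of a flat (340,) logit vector."""
    out = np.empty_like(theta)
    for off, size in zip(_M3_OFFSETS[:-1], _M3_SIZES):
        block = theta[off : off + size].reshape(-1, 4)
        m = block.max(axis=1, keepdims=True)
        lse = m + np.log(np.exp(block - m).sum(axis=1, keepdims=True))
        out[off : off + size] = (block - lse).ravel()
    return out


@dataclass
class TwoClassModel:
    """Trained two-class product model with class log-priors beta_B, beta_U."""

    beta_b: float
    beta_u: float
    components_b: list
    components_u: list
    families: list[str]
    feature_names: list[str] = field(default_factory=list)
    fit_info: dict = field(default_factory=dict)

    def _linear_form(self) -> tuple[np.ndarray, float, int | None]:
        """Cache the posterior logit as bias + weights . T(x) for vector features."""
        weights: list[float] = []
        bias = self.beta_b - self.beta_u
        seq_idx = None
        col = 0
        for j, fam in enumerate(self.families):
            cb, cu = self.components_b[j], self.components_u[j]
            if fam == GAUSSIAN:
                weights.append(cb.eta1 - cu.eta1)
                weights.append(cb.eta2 - cu.eta2)
                bias += cu.log_partition() - cb.log_partition()
                col += 1
            elif fam == BERNOULLI:
                weights.append(cb.logit - cu.logit)
                bias += cu.log_partition() - cb.log_partition()
                col += 1
            elif fam == MARKOV3:
                seq_idx = j
            else:
                raise ValueError(f"unknown family {fam!r}")
        return np.asarray(weights), bias, seq_idx

    def decision_function(
        self, X: np.ndarray, seqs: Sequence[str] | None = None
    ) -> np.ndarray:
        """Posterior log-odds log(P(B|x) / P(U|x)) for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        n_vec = sum(1 for f in self.families if f != MARKOV3)
        if X.shape[1] != n_vec:
            raise ValueError(f"expected {n_vec} feature columns, got {X.shape[1]}")
        w, bias, seq_idx = self._linear_form()
        stats = np.empty((X.shape[0], len(w)))
        k = 0
        col = 0
        for fam in self.families:
            if fam == GAUSSIAN:
                stats[:, k] = X[:, col]
                stats[:, k + 1] = X[:, col] ** 2
                k += 2
                col += 1
            elif fam == BERNOULLI:
                stats[:, k] = X[:, col]
                k += 1
                col += 1
        d = bias + stats @ w
        if seq_idx is not None:
            if seqs is None:
                raise ValueError("model has a sequence component but no seqs given")
            counts, _ = markov3_counts(seqs)
            d += counts @ (
                self.components_b[seq_idx].flat() - self.components_u[seq_idx].flat()
            )
        return d

    def posterior(self, X: np.ndarray, seqs: Sequence[str] | None = None) -> np.ndarray:
        """P(B | x) for each example."""
        return expit(self.decision_function(X, seqs))

    def log_density(self, x: np.ndarray, cls: str, seq: str | None = None) -> float:
        """Class-conditional log f_c(x) of one feature window."""
        comps = self.components_b if cls == "B" else self.components_u
        x = np.asarray(x, dtype=np.float64).ravel()
        total = 0.0
        col = 0
        for fam, comp in zip(self.families, comps):
            if fam == MARKOV3:
                if seq is None:
                    raise ValueError("sequence component requires seq")
                total += comp.log_density(seq)
            else:
                total += float(comp.log_density(x[col]))
                col += 1
        expected = sum(1 for f in self.families if f != MARKOV3)
        if col != expected or len(x) != expected:
            raise ValueError("feature vector does not match model dimensionality")
        return total

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def comp_dict(c, fam):
            if fam == GAUSSIAN:
                return {"eta1": c.eta1, "eta2": c.eta2}
            if fam == BERNOULLI:
                return {"logit": c.logit}
            return {"log_tables": [t.ravel().tolist() for t in c.log_tables]}

        return {
            "version": _SERIAL_VERSION,
            "beta_b": self.beta_b,
            "beta_u": self.beta_u,
            "families": self.families,
            "feature_names": self.feature_names,
            "components_b": [
                comp_dict(c, f) for c, f in zip(self.components_b, self.families)
            ],
            "components_u": [
                comp_dict(c, f) for c, f in zip(self.components_u, self.families)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoClassModel":
        if d.get("version") != _SERIAL_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')!r}")

        def comp(obj, fam):
            if fam == GAUSSIAN:
                return GaussianComponent(obj["eta1"], obj["eta2"])
            if fam == BERNOULLI:
                return BernoulliComponent(obj["logit"])
            return Markov3Component(
                [
                    np.asarray(t, dtype=np.float64).reshape(s)
                    for t, s in zip(obj["log_tables"], _M3_SHAPES)
                ]
            )

        fams = d["families"]
        return cls(
            beta_b=d["beta_b"],
            beta_u=d["beta_u"],
            components_b=[comp(o, f) for o, f in zip(d["components_b"], fams)],
            components_u=[comp(o, f) for o, f in zip(d["components_u"], fams)],
            families=list(fams),
            feature_names=list(d.get("feature_names", [])),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TwoClassModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _build_design(X: np.ndarray, families: Sequence[str]) -> np.ndarray:
    cols = []
    col = 0
    for fam in families:
        if fam == GAUSSIAN:
            cols.append(X[:, col])
            cols.append(X[:, col] ** 2)
            col += 1
        elif fam == BERNOULLI:
            cols.append(X[:, col])
            col += 1
        elif fam != MARKOV3:
            raise ValueError(f"unknown family {fam!r}")
    if col != X.shape[1]:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns but spec describes {col}"
        )
    return np.column_stack(cols) if cols else np.empty((X.shape[0], 0))


def train_mcl(
    X: np.ndarray,
    labels: Sequence[str],
    weights: np.ndarray | None,
    families: Sequence[str],
    *,
    seqs: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
    prior_scale: float = 1.0,
    gtol: float = 1e-6,
    max_iter: int = 500,
    init_rng: np.random.Generator | None = None,
) -> TwoClassModel:
    """Fit the two-class model by weighted discriminative MCL.

    ``X`` holds one column per Gaussian/Bernoulli feature (in ``families``
    order, sequence excluded); ``seqs`` supplies raw sequences if a markov3
    family is present.  ``weights`` are positive example weights (default 1).
    ``init_rng``, if given, draws a random starting point; the default start
    is zero.  Raises :class:`ConvergenceError` if the scaled gradient norm at
    the returned point exceeds ``gtol`` and :class:`ValueError` on non-finite
    inputs or a single-class training set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    y = np.asarray([1.0 if l in ("B", "1", 1, True) else 0.0 for l in labels])
    if len(y) != n:
        raise ValueError("labels/X length mismatch")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(weights <= 0):
        raise ValueError("example weights must be positive")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    wsum_pos = weights[y == 1].sum()
    wsum_neg = weights[y == 0].sum()
    if wsum_pos <= 0 or wsum_neg <= 0:
        raise ValueError("both classes must be present with positive total weight")

    families = list(families)
    has_seq = MARKOV3 in families
    if families.count(MARKOV3) > 1:
        raise ValueError("at most one sequence component is supported")
    design = _build_design(X, families)
    # weight-aware standardization keeps duplicating an example exactly
    # equivalent to doubling its weight
    wn = weights / weights.sum()
    mu = wn @ design
    sd = np.sqrt(wn @ (design - mu) ** 2)
    sd[sd == 0] = 1.0
    Z = (design - mu) / sd
    d_lin = Z.shape[1]

    if has_seq:
        if seqs is None or len(seqs) != n:
            raise ValueError("markov3 family requires one sequence per example")
        counts, ctx_counts = markov3_counts(seqs)
    lam = 1.0 / (prior_scale**2)
    wtot = weights.sum()

    n_par = 1 + d_lin + (2 * M3_DIM if has_seq else 0)

    def unpack(theta):
        b = theta[0]
        w = theta[1 : 1 + d_lin]
        if has_seq:
            tb = theta[1 + d_lin : 1 + d_lin + M3_DIM]
            tu = theta[1 + d_lin + M3_DIM :]
            return b, w, tb, tu
        return b, w, None, None

    def objective(theta):
        b, w, tb, tu = unpack(theta)
        d = b + Z @ w
        penalty = lam * 0.5 * (w @ w)
        if has_seq:
            lp_b = _normalize_logits(tb)
            lp_u = _normalize_logits(tu)
            d = d + counts @ (lp_b - lp_u)
            penalty += lam * 0.5 * (tb @ tb + tu @ tu)
        # weighted logistic negative log-likelihood, scaled by total weight
        nll = -np.sum(weights * (y * log_expit(d) + (1 - y) * log_expit(-d)))
        g = weights * (expit(d) - y)  # dNLL/dd
        grad = np.empty(n_par)
        grad[0] = g.sum()
        grad[1 : 1 + d_lin] = Z.T @ g + lam * w
        if has_seq:
            # d d/d tb = counts - ctx_counts expanded by p_b
            p_b = np.exp(lp_b).reshape(-1, 4)
            p_u = np.exp(lp_u).reshape(-1, 4)
            gc = counts.T @ g  # (340,)
            gctx = ctx_counts.T @ g  # (85,)
            grad_tb = gc - (gctx[:, None] * p_b).ravel() + lam * tb
            grad_tu = -(gc - (gctx[:, None] * p_u).ravel()) + lam * tu
            grad[1 + d_lin : 1 + d_lin + M3_DIM] = grad_tb
            grad[1 + d_lin + M3_DIM :] = grad_tu
        return (nll + penalty) / wtot, grad / wtot

    theta0 = np.zeros(n_par)
    if init_rng is not None:
        theta0 = init_rng.normal(scale=0.1, size=n_par)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-15, "maxls": 60},
    )
    _, grad = objective(res.x)
    gnorm = float(np.max(np.abs(grad)))
    if gnorm > gtol * 10:
        raise ConvergenceError(
            f"MCL optimizer did not converge: |grad|={gnorm:.3g} after "
            f"{res.nit} iterations ({res.message})"
        )

    b_std, w_std, tb, tu = unpack(res.x)
    # undo standardization: raw coefficient and bias shift
    a_raw = w_std / sd
    bias_raw = float(b_std - np.sum(w_std * mu / sd))

    comps_b: list = []
    comps_u: list = []
    delta_beta = bias_raw
    k = 0
    for fam in families:
        if fam == GAUSSIAN:
            a1, a2 = a_raw[k], a_raw[k + 1]
            k += 2
            eta2_0 = -(abs(a2) / 2.0 + 0.5)
            cb = GaussianComponent(eta1=a1 / 2.0, eta2=eta2_0 + a2 / 2.0)
            cu = GaussianComponent(eta1=-a1 / 2.0, eta2=eta2_0 - a2 / 2.0)
            delta_beta += cb.log_partition() - cu.log_partition()
        elif fam == BERNOULLI:
            a = a_raw[k]
            k += 1
            cb = BernoulliComponent(logit=a / 2.0)
            cu = BernoulliComponent(logit=-a / 2.0)
            delta_beta += cb.log_partition() - cu.log_partition()
        else:
            cb = Markov3Component(
                [
                    _normalize_logits(tb)[o : o + s].reshape(shape)
                    for o, s, shape in zip(_M3_OFFSETS[:-1], _M3_SIZES, _M3_SHAPES)
                ]
            )
            cu = Markov3Component(
                [
                    _normalize_logits(tu)[o : o + s].reshape(shape)
                    for o, s, shape in zip(_M3_OFFSETS[:-1], _M3_SIZES, _M3_SHAPES)
                ]
            )
        comps_b.append(cb)
        comps_u.append(cu)

    model = TwoClassModel(
        beta_b=delta_beta / 2.0,
        beta_u=-delta_beta / 2.0,
        components_b=comps_b,
        components_u=comps_u,
        families=families,
        feature_names=list(feature_names or []),
        fit_info={
            "objective": float(res.fun),
            "grad_norm": gnorm,
            "n_iter": int(res.nit),
            "prior_scale": prior_scale,
        },
    )
    return model
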