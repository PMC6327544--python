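"""Generate a synthetic study fixture and inspect what it contains.

The fixture bundles everything a cell type-specific TF binding analysis
consumes: a genome, per-cell-type ChIP-seq peak lists (conservative nested in
relaxed), accessibility fold-enrichment tracks with peak lists, the motif, and
the ground-truth binding sites.
"""

from tfbind import SimConfig, generate

config = SimConfig(seed=1, n_chroms=2, chrom_length=100_000, n_sites=30, n_decoys=30)
data = generate(config)

print(f"chromosomes: {data.sizes}")
for ct in data.cell_types:
    cons = data.chip_conservative[ct]
    shared = {(p.chrom, p.start) for p in data.chip_conservative[data.cell_types[0]]}
    overlap = sum((p.chrom, p.start) in shared for p in cons)
    track = data.accessibility[ct]["chr1"]
    print(
        f"{ct}: {len(cons)} ChIP peaks ({overlap} shared with {data.cell_types[0]}), "
        f"accessibility mean {track.mean():.2f}, max {track.max():.2f}"
    )
print(f"decoy open regions (accessible, motif-free, unbound): {len(data.decoy_sites)}")
print(f"motif: {data.pwm.name}, length {len(data.pwm)} bp")

# Each conservative peak (+-150 bp around a true site) nests inside its
# relaxed counterpart (+-200 bp), mirroring IDR-thresholded vs raw peak calls.
ct = data.cell_types[0]
c, r = data.chip_conservative[ct][0], data.chip_relaxed[ct][0]
print(f"first peak: conservative [{c.start},{c.end}) inside relaxed [{r.start},{r.end})")

data.write("scratch/example_fixture")
print("fixture files written to scratch/example_fixture/")
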