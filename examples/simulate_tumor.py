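"""Generate a synthetic uveal melanoma with known clonal architecture.

Builds a class-2-like tumor — clonal GNAQ with loss of chromosome 3 and a
BAP1 mutation confined to a 60% subclone — plus a neutral mutation tail,
and prints the emitted tables and the generative truth.
"""

from umclone import SimulationConfig, generate_sample

config = SimulationConfig(
    purity=0.8,
    mean_depth=120,
    n_clonal_mutations=100,
    subclone_ccfs=[0.6],
    subclone_mutation_counts=[80],
    neutral_mu_over_beta=50.0,
    cna_spec=[("LOH3", 1, 0, 0), ("8q+", 2, 1, 0)],
    driver_spec=[("GNAQ", 0), ("BAP1", 1)],
    seed=11,
)
mutations, segments, purity, truth = generate_sample(config)

print(f"{len(mutations)} mutations, {len(segments)} copy-number segments, purity {purity}")
print(mutations.head(4).to_string(index=False))
print(segments.to_string(index=False))
n_neutral = sum(truth.neutral.values())
print(f"clonal cluster CCF {truth.clone_ccfs[0]}, subclone CCF {truth.clone_ccfs[1]}")
print(f"neutral-tail mutations: {n_neutral}")
print(f"true VAF of BAP1 (one copy left under LOH3, 60% of tumor cells, purity 0.8):"
      f" {truth.vaf_of['BAP1']:.3f}")
# The BAP1 VAF illustrates the copy-number adjustment: 0.6*0.8/(0.8*1+0.2*2) = 0.40,
# the same expected VAF as a clonal heterozygous diploid mutation — only the
# copy-number-aware CCF transform can tell the two apart.
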