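# Methods

## CCF model

A somatic mutation carried by a fraction CCF of tumor cells, on `m` of the
`n_t` tumor copies of its locus, in a sample of purity ρ whose normal cells
carry `n_n` copies, has expected variant allele frequency

    E[VAF] = m · ρ · CCF / (ρ · n_t + (1 − ρ) · n_n)

`ccf_from_vaf` is the exact algebraic inverse and is deliberately not
clipped: CCFs above 1 indicate an inconsistency (wrong multiplicity, purity
or copy number) that should stay visible downstream. Choices:

* **Normal copy number** is 2 for autosomes and 1 for male X/Y (pass
  `sex="male"`); the default is female, so chrX loci (e.g. *EIF1AX*) are
  treated as diploid.
* **Subclonal segments** (clonal fraction `c < 1`): the denominator uses
  the mixture-averaged tumor copy number `c·(major+minor) + (1−c)·2`. This
  is a single consistent adjustment; it does not attempt to phase the
  mutation into or out of the aberrant subpopulation.
* **Multiplicity** is the nearest integer to
  `VAF·(ρ·n_t + (1−ρ)·n_n)/ρ`, clamped to `[1, major_cn]`. Mutations
  without a covering segment are assumed diploid with `m = 1` and a
  warning is logged.
* **Intervals**: a Wilson 95% score interval on the binomial VAF is pushed
  through the (linear) CCF transform. The Wilson form behaves well at the
  extreme allele fractions LOH loci produce.

## Dirichlet-process clustering

Mutations are clustered on the CCF scale with a truncated stick-breaking
DP mixture (truncation K = 10 — uveal melanomas rarely show more than 3–4
clusters) sampled by Gibbs:

* emission: `alt_i ~ Binomial(depth_i, c_i · π_k)` where
  `c_i = m·ρ/(ρ·n_t + (1−ρ)·n_n)` maps the cluster location `π_k` (a CCF)
  to mutation i's expected VAF;
* base measure Uniform(0, 1.25) on locations — wider than [0, 1] so
  super-clonal artifacts form their own visible cluster instead of piling
  against the boundary;
* concentration α ~ Gamma(1, 1), resampled each sweep from its conjugate
  conditional given the sticks;
* locations live on a fixed grid (step 0.0125 across [0, 1.25]); the
  non-conjugate location update is then an exact discrete draw, every
  sweep is a handful of vectorized array operations, and runs are exactly
  reproducible given a seed. Grid resolution is an order of magnitude
  finer than the ±0.05 accuracy the downstream stages need.

Defaults `n_iter = 1500`, `burn_in = 500` mix well on the few-hundred-
mutation inputs this pipeline targets; both are exposed.

**Summarization.** The mixture labels switch freely between sweeps, so
clusters are summarized through the posterior co-assignment matrix
(probability that two mutations share a component), which is invariant to
relabeling. Mutations are scanned in descending posterior-mean CCF; each
joins the cluster with the highest mean co-assignment probability provided
it is at least 1/2, otherwise it founds a new cluster. An exact 50/50
split therefore goes to the higher-CCF cluster. Cluster location means and
95% intervals are posterior summaries of the members' component locations;
size intervals come from per-iteration counts under a nearest-center map,
and the same map defines a cluster's *occupancy* — the fraction of sweeps
in which it stood apart at all.

**Filtering and counting.** Clusters located below 0.10 on the CCF scale
are not trusted as independent subclones (their mutations may be spread
across several true clones); their members are reassigned to the smallest
surviving cluster, and the top cluster is never dissolved. The number of
*discrete* clusters counts those with ≥ 2 members and occupancy ≥ 0.4 —
the deterministic replacement for the original two-reviewer count, with
borderline occupancy resolved upward to mirror "the higher cluster number
was selected". `consolidate_clusters` applies the same discreteness rule
before tree building, folding stray singleton/low-occupancy groups into
their nearest neighbour so that transient posterior fragments do not
become tree nodes.

## Pigeonhole trees

The highest-CCF cluster is taken as the MRCA (all its mutations in 100% of
tumor cells) and drawn as the child of the normal cell; its node CCF is 1
by construction. Remaining clusters attach, in descending CCF, anywhere
the pigeonhole constraint holds: at every node, the children's CCFs may
not sum past the parent's CCF plus a tolerance (default 0.05, absorbing
CI-level noise; configurable). All admissible parent assignments are
enumerated exhaustively (the canonical tree is the shallowest valid one;
above 8 clusters a greedy shallowest-valid placement is used instead —
nesting under the previous cluster is always admissible for descending
CCFs, so this cannot fail). A cluster with several admissible parents is
reported with `ambiguous_parents` covering all of them, and the SVG
renderer draws it dashed under each alternative rather than pretending the
data decide.

CNAs enter with their clonal fraction and attach to the clone whose CCF
interval contains it (nearest mean on ties or no hit). An aberration on
the MRCA node is called **MRCA** only when the top cluster is compatible
with 100% of tumor cells — its 95% CCF interval reaches 1.0 and its mean
is ≥ 0.9 — the operational reading of "present in all tumor cells" under
sampling noise; aberrations on lower nodes are **subclonal**, and labels
missing from the input are **absent**.

In the SVG life-history plot, node disc area is proportional to the
percentage of cells in the clone, branch length (vertical drop) to the
number of mutations acquired on the branch, and branch width to the
percentage of cells carrying them.

## Neutral-evolution test

Under neutral growth after the MRCA, the cumulative number of subclonal
mutations at allele frequency ≥ f follows `M(f) = μ/β·(1/f − 1/f_max)`
with μ the mutation rate and β the effective division rate. The test:

* VAFs ≥ 0.25 are clonal (public); the rest subclonal (private);
* the empirical M(f) is evaluated at the observed VAFs inside the window
  0.12–0.24 (the "reliably called" subclonal range; a fixed grid gives
  identical verdicts on dense data);
* M(f) is regressed on `x = 1/f − 1/f_max` **without intercept**, since
  M(f_max) = 0 by construction; the slope estimates μ/β;
* R² is the conventional `1 − SS_res/SS_tot` with SS_tot about the mean
  of M;
* a sample is evaluable with ≥ 12 window mutations, and neutral iff
  evaluable and R² is strictly greater than 0.98.

The fit is performed on raw VAFs, not CCFs; window, cutoff, floor and
threshold are all configurable.

## Synthetic tumors

The generator emulates the architecture the pipeline is built to detect:
a clonal (CCF = 1) cluster holding the configured Gq/BSE drivers, up to a
few subclones whose CCFs are supplied directly (no growth dynamics are
simulated; a parent-index list defines the true tree, defaulting to all
subclones under the MRCA, validated against the pigeonhole constraint),
canonical CNAs (LOH3, 6p+, 8q+) emitted as segments carrying their
clone's CCF as clonal fraction, and a neutral tail drawn in VAF space by
inverse-CDF from the 1/f² density on [f_min, f_max] with a Poisson total
count of mean `μ/β·(1/f_min − 1/f_max)`. Reads are Poisson-depth
(conditioned ≥ 1 — zero-depth sites are unobservable) with binomial alt
counts at the expected VAF from the CCF model; purity enters through that
expected VAF. Identical configurations and seeds reproduce byte-identical
tables.

Defaults describe a WGS-like sample: purity 0.8, mean depth 100×, 100
clonal passengers, neutral μ/β = 50 with the tail on [0.05, 0.5] (the
diploid heterozygous ceiling) — about 200 mutations in the 12–24% fit
window, a dense tail of the kind the power-law test needs to behave
stably. The ground truth records each mutation's cluster, CCF, VAF and
tail membership plus the clone tree, including the full set of
pigeonhole-admissible parents per subclone, since a CCF-only method can
identify the tree only up to that set.

What the generator does **not** model — sequencing error, mapping
artifacts, germline contamination leakage, overdispersed (non-binomial)
read counts, multi-region sampling, subclonal copy-number mixtures beyond
the single clonal-fraction field — bounds what passing tests show:
recovery results certify the inference machinery under its own
generative assumptions, not robustness to real-data noise.

## Problem sizes and numerical notes

Recovery and invariant tests run 20-seed batches of 200–260-mutation
tumors at the default 1500-sweep chain, and the acceptance computation
uses 50 replicate neutral tumors (~900 mutations each); these sizes give
stable Monte-Carlo summaries while keeping a full run in the
tens-of-seconds range. Degenerate inputs are handled explicitly: empty
mutation tables and all-zero depths are errors; an M(f) series whose
frequencies all equal f_max has no defined fit; a single mutation yields a
single cluster; clusters are never filtered down to zero (the top cluster
always survives). Ties are deterministic throughout: equal-CCF clusters
order by size, 50/50 posterior splits go to the higher-CCF cluster, and
attachment order is descending CCF.
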