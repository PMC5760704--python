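"""Synthetic uveal-melanoma tumor generator with known clonal architecture.

Emulates the genomic structure typical of primary uveal melanoma: a clonal
(CCF = 1) mutation cluster carrying the initiating Gq-pathway driver and a
BSE driver (BAP1 / SF3B1 / EIF1AX), zero to three subclonal clusters obeying
the pigeonhole constraint, the canonical copy-number alterations (LOH3, 6p+,
8q+) assigned to clones, and a neutral subclonal tail whose cumulative VAF
distribution follows M(f) = mu/beta * (1/f - 1/fmax). Reads are drawn with
Poisson depth and binomial allele sampling, with normal-cell contamination
folded into the expected VAF.

Every generated sample comes with a :class:`GroundTruth` recording each
mutation's cluster, CCF and neutral-tail membership plus the clone tree, so
downstream estimators can be scored exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from umclone.ccf import effective_tumor_cn, expected_vaf

# Canonical driver loci (GRCh37 gene starts; used as stable placement labels).
DRIVER_LOCI: dict[str, tuple[str, int]] = {
    "GNAQ": ("9", 80409488),
    "GNA11": ("19", 3118942),
    "CYSLTR2": ("13", 49280522),
    "PLCB4": ("20", 9389472),
    "BAP1": ("3", 52436624),
    "SF3B1": ("2", 198266834),
    "EIF1AX": ("X", 20159693),
    "SRSF2": ("17", 74732881),
    "RBM10": ("X", 47004617),
    "SF3A1": ("22", 30733041),
    "SRSF7": ("2", 38974667),
}

# Canonical CNA regions (chrom, 0-based start, end).
CNA_REGIONS: dict[str, tuple[str, int, int]] = {
    "LOH3": ("3", 0, 198022430),
    "6p+": ("6", 0, 59800000),
    "8q+": ("8", 45200000, 146364022),
}

# Diploid chromosomes used for passenger placement (kept clear of CNA regions).
_PASSENGER_CHROMS = [("1", 249250621), ("5", 180915260), ("7", 159138663)]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic tumor.

    Clone index 0 is the clonal population (CCF = 1, the MRCA lineage);
    subclones are indexed 1..k in the order of ``subclone_ccfs``.

    Attributes
    ----------
    purity:
        Tumor cell fraction of the sample, in (0, 1].
    mean_depth:
        Mean sequencing depth; per-site depth is Poisson, conditioned >= 1.
    n_clonal_mutations:
        Clonal passenger mutations (drivers are added on top).
    subclone_ccfs:
        CCFs of subclonal clusters, sorted descending, each in (0, 1).
    subclone_mutation_counts:
        Passenger mutations per subclone (same length as ``subclone_ccfs``).
    subclone_parents:
        Parent clone index per subclone (0 = MRCA). Defaults to all
        subclones being children of the MRCA.
    neutral_mu_over_beta:
        Mutation rate per effective cell division of the neutral tail;
        0 disables the tail.
    neutral_fmin, neutral_fmax:
        VAF window on which the neutral tail is generated; the default
        ceiling 0.5 is the diploid heterozygous maximum.
    cna_spec:
        List of ``(label, major_cn, minor_cn, clone_index)``; labels must be
        canonical (:data:`CNA_REGIONS`).
    driver_spec:
        List of ``(gene, clone_index)``; genes must be in
        :data:`DRIVER_LOCI`.
    seed:
        Seed for all randomness; identical configs reproduce identical
        tables byte for byte.
    """

    purity: float = 0.8
    mean_depth: float = 100.0
    n_clonal_mutations: int = 100
    subclone_ccfs: list[float] = field(default_factory=list)
    subclone_mutation_counts: list[int] = field(default_factory=list)
    subclone_parents: list[int] | None = None
    neutral_mu_over_beta: float = 50.0
    neutral_fmin: float = 0.05
    neutral_fmax: float = 0.5
    cna_spec: list[tuple[str, int, int, int]] = field(default_factory=list)
    driver_spec: list[tuple[str, int]] = field(default_factory=list)
    sample_name: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ConfigError(f"purity must be in (0, 1], got {self.purity}")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if any(not 0 < c < 1 for c in self.subclone_ccfs):
            raise ConfigError("subclone CCFs must lie in (0, 1)")
        if sorted(self.subclone_ccfs, reverse=True) != list(self.subclone_ccfs):
            raise ConfigError("subclone_ccfs must be sorted descending")
        if len(self.subclone_mutation_counts) != len(self.subclone_ccfs):
            raise ConfigError("subclone_mutation_counts must match subclone_ccfs")
        if self.subclone_parents is None:
            self.subclone_parents = [0] * len(self.subclone_ccfs)
        if len(self.subclone_parents) != len(self.subclone_ccfs):
            raise ConfigError("subclone_parents must match subclone_ccfs")
        ccfs = self.clone_ccfs
        for i, p in enumerate(self.subclone_parents, start=1):
            if not 0 <= p < i:
                raise ConfigError(f"subclone {i} has invalid parent index {p}")
            if ccfs[i] > ccfs[p]:
                raise ConfigError(f"subclone {i} CCF exceeds its parent's")
        # pigeonhole: each node's children may not jointly exceed it
        for parent in range(len(ccfs)):
            kids = [ccfs[i] for i in range(1, len(ccfs)) if self.subclone_parents[i - 1] == parent]
            if sum(kids) > ccfs[parent] + 1e-9:
                raise ConfigError(f"children of clone {parent} sum to more than its CCF")
        if self.neutral_mu_over_beta < 0:
            raise ConfigError("neutral_mu_over_beta must be >= 0")
        if not 0 < self.neutral_fmin < self.neutral_fmax <= 0.5:
            raise ConfigError("need 0 < neutral_fmin < neutral_fmax <= 0.5")
        n_clones = len(ccfs)
        for gene, clone in self.driver_spec:
            if gene not in DRIVER_LOCI:
                raise ConfigError(f"unknown driver gene {gene!r}")
            if not 0 <= clone < n_clones:
                raise ConfigError(f"driver {gene} assigned to nonexistent clone {clone}")
        for label, major, minor, clone in self.cna_spec:
            if label not in CNA_REGIONS:
                raise ConfigError(f"unknown CNA label {label!r}")
            if minor > major or major < 1:
                raise ConfigError(f"CNA {label}: invalid copy numbers {major}/{minor}")
            if not 0 <= clone < n_clones:
                raise ConfigError(f"CNA {label} assigned to nonexistent clone {clone}")

    @property
    def clone_ccfs(self) -> list[float]:
        """CCFs of all clones, clone 0 first (always 1.0)."""
        return [1.0] + list(self.subclone_ccfs)


@dataclass
class GroundTruth:
    """Exact generative record of a synthetic sample.

    ``cluster_of`` maps a mutation label to its clone index, with -1 for
    neutral-tail mutations. ``parents`` gives the configured clone tree
    (parent of clone 0 is the normal cell, encoded as -1);
    ``valid_parent_sets`` lists, per subclone, every parent placement
    consistent with the pigeonhole constraint — the tree a CCF-only method
    can hope to recover is identifiable only up to these sets.
    """

    cluster_of: dict[str, int]
    ccf_of: dict[str, float]
    vaf_of: dict[str, float]
    neutral: dict[str, bool]
    clone_ccfs: list[float]
    parents: list[int]
    valid_parent_sets: list[set[int]]

    def to_json(self, **kwargs) -> str:
        d = {
            "cluster_of": self.cluster_of,
            "ccf_of": self.ccf_of,
            "vaf_of": self.vaf_of,
            "neutral": self.neutral,
            "clone_ccfs": self.clone_ccfs,
            "parents": self.parents,
            "valid_parent_sets": [sorted(s) for s in self.valid_parent_sets],
        }
        return json.dumps(d, **kwargs)


def neutral_inverse_cdf(u, fmin: float, fmax: float):
    """Map uniform deviates to VAFs under the 1/f^2 density on [fmin, fmax].

    ``u = 0`` gives ``fmax`` and ``u = 1`` gives ``fmin``.
    """
    if fmin >= fmax:
        raise ValueError(f"invalid window: fmin {fmin} >= fmax {fmax}")
    u = np.asarray(u, dtype=float)
    return 1.0 / (u * (1.0 / fmin - 1.0 / fmax) + 1.0 / fmax)


def sample_neutral_tail(
    mu_over_beta: float,
    fmin: float,
    fmax: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw true VAFs of a neutrally evolving mutation tail.

    Under neutral growth the number of subclonal mutations at allele
    frequency >= f is M(f) = mu/beta * (1/f - 1/fmax), i.e. VAFs have
    density proportional to 1/f^2 on [fmin, fmax]. The total count is
    Poisson with mean mu/beta * (1/fmin - 1/fmax); individual VAFs are
    drawn by inverting the cumulative distribution.
    """
    if fmin >= fmax:
        raise ValueError(f"invalid window: fmin {fmin} >= fmax {fmax}")
    if mu_over_beta < 0:
        raise ValueError("mu_over_beta must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mu_over_beta == 0:
        return np.empty(0)
    n = rng.poisson(mu_over_beta * (1.0 / fmin - 1.0 / fmax))
    return neutral_inverse_cdf(rng.uniform(size=n), fmin, fmax)


def simulate_reads(
    true_vaf: float,
    mean_depth: float,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Sample (ref_count, alt_count) at a site with the given true VAF.

    Depth is Poisson(mean_depth) conditioned to be at least 1 (a zero-depth
    site would never enter a mutation table); alt reads are binomial.
    """
    if not 0 <= true_vaf <= 1:
        raise ValueError(f"true_vaf must be in [0, 1], got {true_vaf}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    depth = 0
    while depth < 1:
        depth = rng.poisson(mean_depth)
    alt = rng.binomial(depth, true_vaf)
    return depth - alt, alt


def enumerate_valid_parent_sets(clone_ccfs: list[float], tol: float = 1e-9) -> list[set[int]]:
    """Brute-force pigeonhole enumeration of admissible subclone parents.

    For clones ordered by descending CCF with clone 0 at CCF 1, tries every
    parent vector (each subclone attached to any higher-CCF clone) and keeps
    those where no clone's children sum to more than the clone itself.
    Returns, per subclone, the set of parents seen across all valid trees.
    """
    k = len(clone_ccfs) - 1
    valid: list[set[int]] = [set() for _ in range(k)]
    for parents in itertools.product(*(range(i) for i in range(1, k + 1))):
        ok = True
        for node in range(len(clone_ccfs)):
            s = sum(clone_ccfs[i + 1] for i in range(k) if parents[i] == node)
            if s > clone_ccfs[node] + tol:
                ok = False
                break
        if ok:
            for i in range(k):
                valid[i].add(parents[i])
    return valid


def _draw_positions(
    rng: np.random.Generator, n: int, used: set[tuple[str, int]]
) -> list[tuple[str, int]]:
    """Unique positions on diploid passenger chromosomes."""
    out: list[tuple[str, int]] = []
    while len(out) < n:
        chrom, length = _PASSENGER_CHROMS[rng.integers(0, len(_PASSENGER_CHROMS))]
        site = (chrom, int(rng.integers(1, length)))
        if site not in used:
            used.add(site)
            out.append(site)
    return out


def generate_sample(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, float, GroundTruth]:
    """Generate one synthetic tumor sample.

    Returns
    -------
    mutations:
        TSV-ready table with columns ``sample, chrom, pos, ref, alt,
        ref_count, alt_count, label`` (1-based VCF-convention positions).
    segments:
        BED-like table ``chrom, start, end, major_cn, minor_cn,
        clonal_fraction`` (0-based half-open).
    purity:
        The configured purity, passed through.
    truth:
        :class:`GroundTruth` for scoring.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.purity
    clone_ccfs = config.clone_ccfs

    # --- segments: canonical CNAs at their clone's CCF, diploid elsewhere ---
    seg_rows = []
    cna_by_chrom: dict[str, tuple[str, int, int, int, int, float]] = {}
    for label, major, minor, clone in config.cna_spec:
        chrom, start, end = CNA_REGIONS[label]
        cf = clone_ccfs[clone]
        seg_rows.append((chrom, start, end, major, minor, cf))
        cna_by_chrom[chrom] = (label, start, end, major, minor, cf)
    for chrom, length in _PASSENGER_CHROMS:
        seg_rows.append((chrom, 0, length, 1, 1, 1.0))
    # diploid backbone for driver chromosomes without a CNA
    for gene, _ in config.driver_spec:
        chrom, _pos = DRIVER_LOCI[gene]
        if chrom not in cna_by_chrom and chrom not in {c for c, _ in _PASSENGER_CHROMS}:
            seg_rows.append((chrom, 0, 250_000_000, 1, 1, 1.0))
    segments = pd.DataFrame(
        sorted(set(seg_rows)),
        columns=["chrom", "start", "end", "major_cn", "minor_cn", "clonal_fraction"],
    )

    # --- mutations ---
    rows = []  # (chrom, pos, label, clone, true_ccf, true_vaf, is_neutral)

    def locus_state(chrom: str, pos: int) -> tuple[float, int]:
        """(effective total tumor CN, max multiplicity) at a locus."""
        if chrom in cna_by_chrom:
            _label, start, end, major, minor, cf = cna_by_chrom[chrom]
            if start < pos <= end:
                return effective_tumor_cn(major, minor, cf), major
        return 2.0, 1

    for gene, clone in config.driver_spec:
        chrom, pos = DRIVER_LOCI[gene]
        ccf = clone_ccfs[clone]
        nt, _mmax = locus_state(chrom, pos)
        vaf = expected_vaf(ccf, rho, nt, 2, 1)
        rows.append((chrom, pos, gene, clone, ccf, vaf, False))

    used: set[tuple[str, int]] = set()
    n_pass = [config.n_clonal_mutations] + list(config.subclone_mutation_counts)
    for clone, count in enumerate(n_pass):
        ccf = clone_ccfs[clone]
        vaf = expected_vaf(ccf, rho, 2.0, 2, 1)
        for i, (chrom, pos) in enumerate(_draw_positions(rng, count, used)):
            rows.append((chrom, pos, f"c{clone}_p{i}", clone, ccf, vaf, False))

    tail = sample_neutral_tail(
        config.neutral_mu_over_beta, config.neutral_fmin, config.neutral_fmax, rng
    )
    for i, (v, (chrom, pos)) in enumerate(zip(tail, _draw_positions(rng, len(tail), used))):
        rows.append((chrom, pos, f"neutral_{i}", -1, float("nan"), float(v), True))

    ref_idx = rng.integers(0, 4, size=len(rows))
    alt_off = rng.integers(1, 4, size=len(rows))
    mut_rows = []
    for (chrom, pos, label, _clone, _ccf, vaf, _neu), ri, ao in zip(rows, ref_idx, alt_off):
        ref_count, alt_count = simulate_reads(vaf, config.mean_depth, rng)
        mut_rows.append(
            (
                config.sample_name,
                chrom,
                pos,
                _BASES[ri],
                _BASES[(ri + ao) % 4],
                ref_count,
                alt_count,
                label,
            )
        )
    mutations = pd.DataFrame(
        mut_rows,
        columns=["sample", "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "label"],
    )

    truth = GroundTruth(
        cluster_of={r[2]: r[3] for r in rows},
        ccf_of={r[2]: r[4] for r in rows},
        vaf_of={r[2]: r[5] for r in rows},
        neutral={r[2]: r[6] for r in rows},
        clone_ccfs=clone_ccfs,
        parents=[-1] + [p for p in (config.subclone_parents or [])],
        valid_parent_sets=enumerate_valid_parent_sets(clone_ccfs),
    )
    return mutations, segments, rho, truth
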