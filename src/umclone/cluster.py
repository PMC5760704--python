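"""Dirichlet-process mixture clustering of somatic mutations by CCF.

Mutations are clustered on the cancer-cell-fraction scale with a truncated
stick-breaking Dirichlet-process mixture sampled by Gibbs. The emission
model ties a cluster's CCF location ``pi`` to the observed read counts
through the purity/copy-number transform: for mutation i on a segment with
effective tumor copy number ``n_t`` and multiplicity ``m``,

    alt_i ~ Binomial(depth_i, c_i * pi),
    c_i = m * rho / (rho * n_t + (1 - rho) * n_n)

so the per-mutation coefficient ``c_i`` maps a CCF to an expected VAF.
The base measure on locations is Uniform(0, 1.25) — deliberately wider
than [0, 1] so super-clonal inconsistencies surface instead of being
squashed against the boundary — and the concentration parameter carries a
Gamma(1, 1) prior resampled every sweep.

After sampling, mutations are assigned to their maximum-posterior cluster,
clusters located below a cutoff on the CCF scale are dissolved into the
smallest surviving cluster (such mutations may be spread across several
true clones), and the number of discrete clusters is counted with a
deterministic occupancy rule replacing the original human dual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from umclone.ccf import effective_tumor_cn, estimate_multiplicity, normal_copy_number

#: Stick-breaking truncation level; uveal melanoma rarely exceeds 3-4 clusters.
TRUNCATION_K = 10
#: Upper edge of the uniform base measure on cluster CCF locations.
CCF_MAX = 1.25
#: Grid resolution for the (non-conjugate) location updates.
GRID_STEP = 0.0125


@dataclass
class Cluster:
    """A posterior mutation cluster.

    ``n_mutations_point`` is the size of the maximum-posterior membership;
    ``n_mutations_ci95`` is the 2.5-97.5 percentile range of the cluster's
    size across retained Gibbs iterations. ``occupancy`` is the fraction of
    retained iterations in which the cluster was occupied at all.
    """

    id: int
    mean_ccf: float
    ccf_ci95: tuple[float, float]
    n_mutations_point: int
    n_mutations_ci95: tuple[float, float]
    members: list[int] = field(default_factory=list)
    occupancy: float = 1.0


@dataclass
class PosteriorTrace:
    """Retained Gibbs iterations, relabeled by descending CCF location.

    ``assignments[t, i]`` is the rank (0 = highest CCF) of mutation i's
    cluster at retained iteration t; ``locations[t, r]`` the CCF location
    of rank r (NaN where fewer clusters were occupied);
    ``mutation_locations[t, i]`` the location of the cluster mutation i sat
    in; ``alpha[t]`` the concentration parameter.
    """

    assignments: np.ndarray
    locations: np.ndarray
    mutation_locations: np.ndarray
    alpha: np.ndarray
    burn_in: int
    seed: int
    mutation_ids: list[str] | None = None

    @property
    def n_retained(self) -> int:
        return self.assignments.shape[0]


def mutation_coefficients(
    mutations: pd.DataFrame,
    segments: pd.DataFrame | None,
    purity: float,
    sex: str = "female",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-mutation (alt, depth, coefficient) arrays for the emission model.

    Looks up each mutation's covering copy-number segment (BED-convention
    half-open intervals against 1-based positions), estimates multiplicity,
    and returns the linear VAF-per-CCF coefficient ``c_i``. Mutations with
    no covering segment are treated as diploid with multiplicity 1.
    """
    alt = mutations["alt_count"].to_numpy(dtype=float)
    depth = alt + mutations["ref_count"].to_numpy(dtype=float)
    coeff = np.empty(len(mutations))
    for j, row in enumerate(mutations.itertuples(index=False)):
        nn = normal_copy_number(row.chrom, sex)
        major, minor, cf = 1, 1, 1.0
        if segments is not None and len(segments):
            hit = segments[
                (segments["chrom"].astype(str) == str(row.chrom))
                & (segments["start"] < row.pos)
                & (segments["end"] >= row.pos)
            ]
            if len(hit):
                seg = hit.iloc[0]
                major, minor, cf = int(seg.major_cn), int(seg.minor_cn), float(seg.clonal_fraction)
        vaf = alt[j] / depth[j] if depth[j] > 0 else 0.0
        m = estimate_multiplicity(vaf, purity, major, minor, cf, nn)
        nt = effective_tumor_cn(major, minor, cf)
        coeff[j] = m * purity / (purity * nt + (1 - purity) * nn)
    return alt, depth, coeff


def _gumbel_argmax(rng: np.random.Generator, logp: np.ndarray, axis: int = -1) -> np.ndarray:
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=axis)


def gibbs_sample_counts(
    alt: np.ndarray,
    depth: np.ndarray,
    coeff: np.ndarray,
    n_iter: int = 1500,
    burn_in: int = 500,
    seed: int = 0,
    truncation: int = TRUNCATION_K,
    mutation_ids: list[str] | None = None,
) -> PosteriorTrace:
    """Gibbs sampler for the truncated stick-breaking DP mixture.

    Cluster locations live on a fixed CCF grid spanning the Uniform(0,
    ``CCF_MAX``) base measure, which makes the non-conjugate location
    update an exact discrete draw and the whole sweep a handful of
    vectorized array operations. Identical inputs and seed reproduce the
    trace exactly.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    coeff = np.asarray(coeff, dtype=float)
    n = alt.size
    if n < 1:
        raise ValueError("need at least one mutation")
    if np.all(depth == 0):
        raise ValueError("all mutations have zero depth")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    K = truncation

    grid = np.arange(0.0, CCF_MAX + GRID_STEP / 2, GRID_STEP)
    grid[0] = GRID_STEP / 10  # avoid log(0) while keeping near-zero support
    G = grid.size
    # log-likelihood of every mutation at every grid CCF, computed once
    p = np.clip(coeff[:, None] * grid[None, :], 1e-12, 1 - 1e-12)
    loglik_grid = alt[:, None] * np.log(p) + (depth - alt)[:, None] * np.log1p(-p)

    pi_idx = rng.integers(0, G, size=K)  # cluster locations as grid indices
    z = rng.integers(0, K, size=n)
    alpha = 1.0
    n_retained = n_iter - burn_in
    out_assign = np.empty((n_retained, n), dtype=np.int16)
    out_loc = np.full((n_retained, K), np.nan)
    out_mloc = np.empty((n_retained, n), dtype=np.float32)
    out_alpha = np.empty(n_retained)

    for it in range(n_iter):
        # stick-breaking weights given assignments
        counts = np.bincount(z, minlength=K)
        tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
        v = rng.beta(1.0 + counts, alpha + tail)
        v[-1] = 1.0
        log1mv = np.log1p(-np.clip(v, 0, 1 - 1e-12))
        logw = np.log(np.clip(v, 1e-300, 1)) + np.concatenate([[0.0], np.cumsum(log1mv[:-1])])

        # concentration parameter: Gamma(1,1) prior, conjugate given sticks
        alpha = rng.gamma(1.0 + K - 1, 1.0 / (1.0 - np.sum(log1mv[:-1])))

        # assignments
        logpost = logw[None, :] + loglik_grid[:, pi_idx]
        z = _gumbel_argmax(rng, logpost)

        # locations: exact discrete draw on the grid; empty clusters from prior
        cluster_ll = np.zeros((K, G))
        np.add.at(cluster_ll, z, loglik_grid)
        occupied = np.bincount(z, minlength=K) > 0
        cluster_ll[~occupied] = 0.0  # uniform prior => flat log-weights
        pi_idx = _gumbel_argmax(rng, cluster_ll)

        if it >= burn_in:
            t = it - burn_in
            occ = np.unique(z)
            order = occ[np.argsort(-grid[pi_idx[occ]], kind="stable")]
            rank = np.empty(K, dtype=np.int16)
            rank[order] = np.arange(order.size, dtype=np.int16)
            out_assign[t] = rank[z]
            out_loc[t, : order.size] = grid[pi_idx[order]]
            out_mloc[t] = grid[pi_idx[z]]
            out_alpha[t] = alpha

    return PosteriorTrace(
        assignments=out_assign,
        locations=out_loc,
        mutation_locations=out_mloc,
        alpha=out_alpha,
        burn_in=burn_in,
        seed=seed,
        mutation_ids=mutation_ids,
    )


def gibbs_sample(
    mutations: pd.DataFrame,
    segments: pd.DataFrame | None,
    purity: float,
    n_iter: int = 1500,
    burn_in: int = 500,
    seed: int = 0,
    truncation: int = TRUNCATION_K,
    sex: str = "female",
) -> PosteriorTrace:
    """Cluster a mutation table: convenience wrapper building the emission
    coefficients from segments and purity, then running
    :func:`gibbs_sample_counts`."""
    alt, depth, coeff = mutation_coefficients(mutations, segments, purity, sex)
    ids = mutations["label"].tolist() if "label" in mutations.columns else None
    return gibbs_sample_counts(
        alt, depth, coeff, n_iter=n_iter, burn_in=burn_in, seed=seed,
        truncation=truncation, mutation_ids=ids,
    )


def coassignment_matrix(trace: PosteriorTrace) -> np.ndarray:
    """Posterior probability that each pair of mutations shares a cluster."""
    A = trace.assignments
    n_ret, n = A.shape
    S = np.zeros((n, n), dtype=np.float32)
    for r in range(int(A.max()) + 1):
        M = (A == r).astype(np.float32)
        S += M.T @ M
    return S / n_ret


def assign_clusters(trace: PosteriorTrace) -> list[Cluster]:
    """Summarize a trace into clusters with maximum-posterior memberships.

    Cluster identity across Gibbs iterations is resolved through the
    posterior co-assignment matrix (the probability that two mutations sit
    in the same mixture component), which is invariant to label switching.
    Mutations are scanned in descending order of posterior mean CCF and
    each joins the existing cluster to which its mean co-assignment
    probability is highest, provided it is at least 1/2 — its
    maximum-posterior cluster — or founds a new cluster otherwise. An
    exact tie (a mutation split 50/50 between two clusters) goes to the
    higher-CCF cluster.

    A cluster's location statistics are posterior summaries of the mean
    component location of its members; its size interval comes from
    per-iteration counts of mutations nearest to the cluster's center, and
    ``occupancy`` is the fraction of retained iterations in which the
    cluster was occupied at all under that nearest-center map.
    """
    if trace.n_retained < 1:
        raise ValueError("trace has no retained iterations")
    S = coassignment_matrix(trace)
    mloc = trace.mutation_locations.astype(float)  # n_ret x n
    n = S.shape[0]
    post_mean = mloc.mean(axis=0)

    order = np.argsort(-post_mean, kind="stable")
    groups: list[list[int]] = []
    for i in order:
        if groups:
            sims = np.array([S[i, g].mean() for g in groups])
            best = int(np.argmax(sims))  # ties -> earlier (higher-CCF) cluster
            if sims[best] >= 0.5:
                groups[best].append(int(i))
                continue
        groups.append([int(i)])

    # posterior samples of each cluster's location: per-iteration mean over members
    loc_samples = [mloc[:, g].mean(axis=1) for g in groups]
    centers = np.array([ls.mean() for ls in loc_samples])

    # per-iteration sizes under the nearest-center map (0 when the cluster
    # collapsed into another that iteration)
    nearest = np.argmin(np.abs(mloc[:, :, None] - centers[None, None, :]), axis=2)
    clusters: list[Cluster] = []
    order_c = np.argsort(-centers, kind="stable")
    for new_id, ci in enumerate(order_c):
        g = groups[ci]
        sizes = (nearest == ci).sum(axis=1)
        clusters.append(
            Cluster(
                id=new_id,
                mean_ccf=float(centers[ci]),
                ccf_ci95=(
                    float(np.percentile(loc_samples[ci], 2.5)),
                    float(np.percentile(loc_samples[ci], 97.5)),
                ),
                n_mutations_point=len(g),
                n_mutations_ci95=(
                    float(np.percentile(sizes, 2.5)),
                    float(np.percentile(sizes, 97.5)),
                ),
                members=sorted(g),
                occupancy=float(np.mean(sizes > 0)),
            )
        )
    return clusters


def filter_low_ccf_clusters(
    clusters: list[Cluster], threshold: float = 0.10
) -> list[Cluster]:
    """Dissolve clusters located below ``threshold`` on the CCF scale.

    Mutations in such clusters may be spread across multiple true clones,
    so the cluster is not trusted as an independent subclone; its members
    are reassigned to the smallest surviving cluster by mean CCF. The
    top cluster is never dissolved.
    """
    if not clusters:
        raise ValueError("no clusters to filter")
    ordered = sorted(clusters, key=lambda c: -c.mean_ccf)
    survivors = [ordered[0]] + [c for c in ordered[1:] if c.mean_ccf >= threshold]
    dissolved = [c for c in ordered[1:] if c.mean_ccf < threshold]
    if not dissolved:
        return ordered
    sink = survivors[-1]  # smallest surviving cluster by mean CCF
    new_members = list(sink.members)
    for c in dissolved:
        new_members.extend(c.members)
    out = []
    for i, c in enumerate(survivors):
        members = new_members if c is sink else list(c.members)
        out.append(
            Cluster(
                id=i,
                mean_ccf=c.mean_ccf,
                ccf_ci95=c.ccf_ci95,
                n_mutations_point=len(members),
                n_mutations_ci95=c.n_mutations_ci95,
                members=members,
                occupancy=c.occupancy,
            )
        )
    return out


def consolidate_clusters(
    clusters: list[Cluster], min_members: int = 2, min_occupancy: float = 0.4
) -> list[Cluster]:
    """Keep only discrete clusters; fold the rest into their neighbours.

    Mutations drifting between mixture modes leave scattered singleton or
    low-occupancy groups in the posterior summary. Those are not discrete
    clusters in the sense of the counting rule, so their members are
    reassigned to the surviving cluster with the nearest mean CCF. The
    highest-CCF cluster always survives.
    """
    if not clusters:
        raise ValueError("no clusters to consolidate")
    ordered = sorted(clusters, key=lambda c: -c.mean_ccf)
    keep = [
        c
        for c in ordered
        if c.n_mutations_point >= min_members and c.occupancy >= min_occupancy
    ]
    if not keep or ordered[0] not in keep:
        keep = [ordered[0]] + keep
    drop = [c for c in ordered if c not in keep]
    extra: dict[int, list[int]] = {id(c): [] for c in keep}
    for c in drop:
        sink = min(keep, key=lambda k: abs(k.mean_ccf - c.mean_ccf))
        extra[id(sink)].extend(c.members)
    out = []
    for i, c in enumerate(keep):
        members = sorted(c.members + extra[id(c)])
        out.append(
            Cluster(
                id=i,
                mean_ccf=c.mean_ccf,
                ccf_ci95=c.ccf_ci95,
                n_mutations_point=len(members),
                n_mutations_ci95=c.n_mutations_ci95,
                members=members,
                occupancy=c.occupancy,
            )
        )
    return out


def count_discrete_clusters(clusters: list[Cluster]) -> int:
    """Number of discrete clusters after filtering.

    Only clusters with at least two members count; a borderline cluster —
    occupied in 40-60% of retained iterations — is resolved upward
    (counted), the deterministic analogue of taking the higher of two
    reviewers' counts.
    """
    return sum(1 for c in clusters if c.n_mutations_point >= 2 and c.occupancy >= 0.4)
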