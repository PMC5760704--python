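"""End-to-end orchestration: simulate -> ccf -> cluster -> tree -> neutrality.

Each stage is a pure function over data frames so results are exactly
recomputable from the persisted stage outputs; :func:`run_sample` wires
them together, writes every intermediate (CCF table, clusters, tree JSON +
SVG, neutrality row) and returns a one-row summary per sample.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from umclone import io as um_io
from umclone.ccf import estimate_ccf
from umclone.cluster import (
    assign_clusters,
    consolidate_clusters,
    count_discrete_clusters,
    filter_low_ccf_clusters,
    gibbs_sample,
)
from umclone.neutrality import NeutralityConfig, classify_neutral
from umclone.simulate import CNA_REGIONS, DRIVER_LOCI
from umclone.tree import build_tree, classify_aberrations, render_life_history_svg

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable).

    All published thresholds are surfaced here — the clonal cutoff 0.25,
    the 0.12-0.24 neutrality window, the 12-mutation evaluability floor,
    the 0.98 R^2 bound and the 0.10 low-CCF cluster filter — because they
    were tuned for whole-genome uveal melanoma data and may need revisiting
    on other inputs.
    """

    mutations: str = ""
    segments: str = ""
    purity: float = 1.0
    outdir: str = "."
    sample: str | None = None
    sex: str = "female"
    n_iter: int = 1500
    burn_in: int = 500
    low_ccf_threshold: float = 0.10
    tree_tolerance: float = 0.05
    neutrality: NeutralityConfig = field(default_factory=NeutralityConfig)
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        neu = d.pop("neutrality", None)
        cfg = cls(**d)
        if neu:
            cfg.neutrality = NeutralityConfig(**neu)
        return cfg


def ccf_stage(mutations: pd.DataFrame, segments: pd.DataFrame | None, purity: float,
              sex: str = "female") -> pd.DataFrame:
    """Augment a mutation table with multiplicity, CCF and its 95% interval."""
    out = mutations.copy()
    m, ccf, lo, hi = [], [], [], []
    for row in mutations.itertuples(index=False):
        major, minor, cf, covered = 1, 1, 1.0, False
        if segments is not None and len(segments):
            hit = segments[
                (segments["chrom"].astype(str) == str(row.chrom))
                & (segments["start"] < row.pos)
                & (segments["end"] >= row.pos)
            ]
            if len(hit):
                seg = hit.iloc[0]
                major, minor, cf = int(seg.major_cn), int(seg.minor_cn), float(seg.clonal_fraction)
                covered = True
        est = estimate_ccf(
            str(row.label), int(row.alt_count), int(row.ref_count), purity,
            major_cn=major, minor_cn=minor, clonal_fraction=cf,
            chrom=str(row.chrom), sex=sex, covered=covered,
        )
        m.append(est.multiplicity)
        ccf.append(est.ccf)
        lo.append(est.ccf_ci[0])
        hi.append(est.ccf_ci[1])
    out["multiplicity"] = m
    out["ccf"] = ccf
    out["ccf_lo"] = lo
    out["ccf_hi"] = hi
    return out


def clusters_to_frame(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster": c.id,
                "mean_ccf": c.mean_ccf,
                "ccf_lo": c.ccf_ci95[0],
                "ccf_hi": c.ccf_ci95[1],
                "n_mutations": c.n_mutations_point,
                "n_lo": c.n_mutations_ci95[0],
                "n_hi": c.n_mutations_ci95[1],
                "occupancy": c.occupancy,
            }
            for c in clusters
        ]
    )


def _known_aberration_labels(mutations: pd.DataFrame, segments: pd.DataFrame):
    """Driver genes present in the mutation table and canonical CNAs present
    in the segment table (matched by region and a non-diploid copy state)."""
    drivers = [g for g in DRIVER_LOCI if g in set(mutations["label"])]
    cnas = {}
    if segments is not None:
        for label, (chrom, start, end) in CNA_REGIONS.items():
            hit = segments[
                (segments["chrom"].astype(str) == chrom)
                & (segments["start"] < end)
                & (segments["end"] > start)
                & ((segments["major_cn"] != 1) | (segments["minor_cn"] != 1))
            ]
            if len(hit):
                cnas[label] = float(hit.iloc[0]["clonal_fraction"])
    return drivers, cnas


def run_sample(config: RunConfig,
               mutations: pd.DataFrame | None = None,
               segments: pd.DataFrame | None = None) -> dict:
    """Run the full per-sample analysis and write the report bundle.

    Emits ``ccf.tsv``, ``clusters.tsv``, ``assignments.tsv``, ``tree.json``,
    ``tree.svg`` and ``neutrality.tsv`` under ``config.outdir`` and returns
    the summary dict (also written as ``summary.tsv``).
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if mutations is None:
        mutations = um_io.read_mutations(config.mutations, config.sample)
    if segments is None and config.segments:
        segments = um_io.read_segments(config.segments)
    sample = str(mutations["sample"].iloc[0])
    logger.info("[%s] %d mutations, purity %.2f", sample, len(mutations), config.purity)

    ccf_table = ccf_stage(mutations, segments, config.purity, config.sex)
    um_io.write_tsv(ccf_table, outdir / "ccf.tsv", seed=config.seed)
    logger.info("[%s] ccf stage done (%.1fs)", sample, time.time() - t0)

    trace = gibbs_sample(
        mutations, segments, config.purity,
        n_iter=config.n_iter, burn_in=config.burn_in, seed=config.seed, sex=config.sex,
    )
    clusters = consolidate_clusters(
        filter_low_ccf_clusters(assign_clusters(trace), config.low_ccf_threshold)
    )
    n_clusters = count_discrete_clusters(clusters)
    um_io.write_tsv(clusters_to_frame(clusters), outdir / "clusters.tsv", seed=config.seed)
    assign_df = pd.DataFrame(
        {
            "label": mutations["label"],
            "cluster": _membership_vector(clusters, len(mutations)),
        }
    )
    um_io.write_tsv(assign_df, outdir / "assignments.tsv", seed=config.seed)
    logger.info("[%s] clustering done: %d clusters (%.1fs)", sample, n_clusters, time.time() - t0)

    drivers, cnas = _known_aberration_labels(mutations, segments)
    driver_to_cluster = {}
    labels = mutations["label"].tolist()
    for g in drivers:
        idx = labels.index(g)
        for c in clusters:
            if idx in c.members:
                driver_to_cluster[g] = c.id
    tree = build_tree(
        clusters, cna_fractions=cnas, tolerance=config.tree_tolerance,
        driver_labels=driver_to_cluster,
    )
    (outdir / "tree.json").write_text(tree.to_json(indent=2))
    render_life_history_svg(tree, str(outdir / "tree.svg"))
    calls = classify_aberrations(tree, drivers, list(cnas))
    logger.info("[%s] tree done (%.1fs)", sample, time.time() - t0)

    vafs = (
        mutations["alt_count"] / (mutations["alt_count"] + mutations["ref_count"])
    ).to_numpy()
    neu = classify_neutral(vafs, config.neutrality)
    neu_df = pd.DataFrame(
        [
            {
                "sample": sample,
                "n_window": neu.n_window,
                "slope_mu_over_beta": neu.slope_mu_over_beta,
                "r_squared": neu.r_squared,
                "evaluable": neu.evaluable,
                "neutral": neu.neutral,
            }
        ]
    )
    um_io.write_tsv(neu_df, outdir / "neutrality.tsv", seed=config.seed)
    um_io.write_tsv(
        pd.DataFrame([(f, m) for f, m in neu.mf_series], columns=["f", "M"]),
        outdir / "mf_series.tsv", seed=config.seed,
    )

    summary = {
        "sample": sample,
        "n_mutations": len(mutations),
        "n_clusters": n_clusters,
        "mrca_aberrations": ",".join(c.label for c in calls if c.status == "MRCA"),
        "subclonal_aberrations": ",".join(c.label for c in calls if c.status == "subclone"),
        "n_window": neu.n_window,
        "r_squared": neu.r_squared,
        "neutral": neu.neutral,
    }
    um_io.write_tsv(pd.DataFrame([summary]), outdir / "summary.tsv", seed=config.seed)
    logger.info("[%s] finished in %.1fs", sample, time.time() - t0)
    return summary


def _membership_vector(clusters, n: int) -> list[int]:
    out = [-1] * n
    for c in clusters:
        for i in c.members:
            out[i] = c.id
    return out
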