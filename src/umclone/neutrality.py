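"""Neutral-tumor-evolution test via the 1/f power law.

Under neutral growth after the most recent common ancestor, passenger
mutations accumulate at a constant rate per effective division and the
cumulative number of subclonal mutations with allele frequency at least f
follows

    M(f) = mu/beta * (1/f - 1/fmax)

A sample is scored by regressing the empirical M(f), built from VAFs inside
a fixed subclonal window, against (1/f - 1/fmax) with zero intercept; the
goodness of fit R^2 decides the verdict. Defaults follow the published
protocol: window 12-24% VAF, clonal cutoff 0.25, at least 12 window
mutations for evaluability, and neutrality declared for R^2 strictly
greater than 0.98.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class NeutralityConfig:
    """Thresholds of the neutrality test.

    fmin/fmax bound the VAF window of "reliably called" subclonal mutations
    (the published choice 0.12-0.24 accounts for purity and detection
    limits); ``clonal_cutoff`` separates public from private mutations;
    ``min_mutations`` is the evaluability floor; ``r2_threshold`` is the
    strict lower bound for a neutral verdict.
    """

    fmin: float = 0.12
    fmax: float = 0.24
    clonal_cutoff: float = 0.25
    min_mutations: int = 12
    r2_threshold: float = 0.98

    def __post_init__(self) -> None:
        if not 0 < self.fmin < self.fmax < self.clonal_cutoff <= 0.5:
            raise ValueError("need 0 < fmin < fmax < clonal_cutoff <= 0.5")
        if self.min_mutations < 1:
            raise ValueError("min_mutations must be >= 1")


@dataclass
class NeutralityResult:
    """Outcome of the neutrality test on one sample."""

    n_window: int
    evaluable: bool
    mf_series: list[tuple[float, float]] = field(default_factory=list)
    slope_mu_over_beta: float = float("nan")
    r_squared: float = float("nan")
    neutral: bool = False


def split_clonal_subclonal(
    vafs, clonal_cutoff: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Partition VAFs into clonal (public, >= cutoff) and subclonal (private)."""
    v = np.asarray(vafs, dtype=float)
    mask = v >= clonal_cutoff
    return v[mask], v[~mask]


def cumulative_mf(subclonal_vafs, fmin: float, fmax: float) -> list[tuple[float, float]]:
    """Empirical cumulative mutation count M(f) at each observed window VAF.

    For every observed VAF f inside [fmin, fmax], in descending order,
    M(f) counts the window VAFs v with f <= v <= fmax. M at the highest
    frequency fmax is 0 unless some VAF sits exactly there.
    """
    if fmin >= fmax:
        raise ValueError(f"invalid window: fmin {fmin} >= fmax {fmax}")
    v = np.asarray(subclonal_vafs, dtype=float)
    win = np.sort(v[(v >= fmin) & (v <= fmax)])[::-1]
    return [(float(f), float(np.sum((win >= f)))) for f in win]


def fit_power_law(
    mf_series: list[tuple[float, float]], fmax: float
) -> tuple[float, float]:
    """Zero-intercept least-squares fit of M(f) against x = 1/f - 1/fmax.

    Returns ``(slope, r_squared)``; the slope estimates mu/beta. R^2 is the
    conventional 1 - SSres/SStot with SStot taken about the mean of M.
    """
    if not mf_series:
        raise ValueError("empty M(f) series")
    f = np.array([p[0] for p in mf_series], dtype=float)
    m = np.array([p[1] for p in mf_series], dtype=float)
    x = 1.0 / f - 1.0 / fmax
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("degenerate fit: all frequencies equal fmax")
    slope = float(np.dot(x, m)) / sxx
    resid = m - slope * x
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def classify_neutral(vafs, config: NeutralityConfig | None = None) -> NeutralityResult:
    """Run the full neutrality test on a sample's VAFs.

    A sample is evaluable only if at least ``min_mutations`` VAFs fall in
    the fit window; an evaluable sample is called neutral iff R^2 strictly
    exceeds the threshold.
    """
    cfg = config or NeutralityConfig()
    _clonal, sub = split_clonal_subclonal(vafs, cfg.clonal_cutoff)
    series = cumulative_mf(sub, cfg.fmin, cfg.fmax)
    n_window = len(series)
    if n_window < cfg.min_mutations:
        return NeutralityResult(n_window=n_window, evaluable=False, mf_series=series)
    slope, r2 = fit_power_law(series, cfg.fmax)
    return NeutralityResult(
        n_window=n_window,
        evaluable=True,
        mf_series=series,
        slope_mu_over_beta=slope,
        r_squared=r2,
        neutral=bool(r2 > cfg.r2_threshold),
    )
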