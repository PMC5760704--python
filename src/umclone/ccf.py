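"""Cancer cell fraction (CCF) estimation from variant allele frequencies.

The observed variant allele frequency (VAF) of a somatic mutation in a bulk
tumor sample is diluted by normal-cell contamination and distorted by copy
number. For a mutation carried on ``m`` of the tumor's ``n_t`` local copies,
in a sample of purity ``rho`` where normal cells carry ``n_n`` copies,

    E[VAF] = m * rho * CCF / (rho * n_t + (1 - rho) * n_n)

Inverting this relation converts an observed VAF into the fraction of tumor
cells carrying the mutation — the quantity that is clustered downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Germline copy number assumed for autosomes.
AUTOSOMAL_NORMAL_CN = 2
#: Germline copy number for male X/Y; used only when ``sex="male"`` is passed.
MALE_SEX_CHROM_CN = 1


@dataclass(frozen=True)
class CCFEstimate:
    """Point estimate and 95% interval of a mutation's cancer cell fraction.

    Attributes
    ----------
    mutation_id:
        Identifier of the mutation (row label of the input table).
    multiplicity:
        Estimated integer number of tumor copies bearing the variant,
        between 1 and the major copy number of the covering segment.
    ccf:
        Point estimate of the fraction of tumor cells carrying the mutation.
        Not clipped: values above 1 are reported raw so that super-clonal
        inconsistencies stay visible downstream.
    ccf_ci:
        95% interval ``(low, high)`` obtained by propagating a Wilson score
        interval on the VAF through the CCF transform.
    """

    mutation_id: str
    multiplicity: int
    ccf: float
    ccf_ci: tuple[float, float]


def normal_copy_number(chrom: str, sex: str = "female") -> int:
    """Germline copy number of a chromosome: 2 for autosomes, 1 for male X/Y."""
    c = str(chrom).removeprefix("chr")
    if sex == "male" and c in ("X", "Y"):
        return MALE_SEX_CHROM_CN
    return AUTOSOMAL_NORMAL_CN


def effective_tumor_cn(major_cn: int, minor_cn: int, clonal_fraction: float = 1.0) -> float:
    """Average total tumor copy number over a segment.

    For subclonal segments (``clonal_fraction < 1``) the aberrant and the
    residual diploid populations are mixed in proportion, giving a single
    consistent denominator for the VAF/CCF transform.
    """
    nt = major_cn + minor_cn
    if clonal_fraction >= 1.0:
        return float(nt)
    return clonal_fraction * nt + (1.0 - clonal_fraction) * AUTOSOMAL_NORMAL_CN


def expected_vaf(
    ccf: float,
    purity: float,
    tumor_total_cn: float,
    normal_cn: float = 2,
    multiplicity: int = 1,
) -> float:
    """Expected VAF of a mutation at a given CCF.

    Parameters
    ----------
    ccf:
        Fraction of tumor cells carrying the mutation.
    purity:
        Tumor cell fraction of the sample, in (0, 1].
    tumor_total_cn:
        Total copy number of the locus in tumor cells (>= 1; may be a
        clonal-fraction-weighted average for subclonal segments).
    normal_cn:
        Copy number in contaminating normal cells.
    multiplicity:
        Tumor copies bearing the variant (>= 1).
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if tumor_total_cn < 1:
        raise ValueError(f"tumor_total_cn must be >= 1, got {tumor_total_cn}")
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    denom = purity * tumor_total_cn + (1.0 - purity) * normal_cn
    return multiplicity * purity * ccf / denom


def ccf_from_vaf(
    vaf: float,
    purity: float,
    tumor_total_cn: float,
    normal_cn: float = 2,
    multiplicity: int = 1,
) -> float:
    """Algebraic inverse of :func:`expected_vaf`.

    The returned value is deliberately not clipped to [0, 1]; a CCF above 1
    flags an inconsistency (wrong multiplicity, purity or copy number) that
    downstream stages should see.
    """
    if multiplicity < 1:
        raise ValueError(f"multiplicity must be >= 1, got {multiplicity}")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    denom = purity * tumor_total_cn + (1.0 - purity) * normal_cn
    return vaf * denom / (multiplicity * purity)


def estimate_multiplicity(
    vaf: float,
    purity: float,
    major_cn: int,
    minor_cn: int,
    clonal_fraction: float = 1.0,
    normal_cn: float = 2,
) -> int:
    """Nearest-integer multiplicity consistent with the observed VAF.

    Rounds ``vaf * (rho*n_t + (1-rho)*n_n) / rho`` — the mutant copy number a
    fully clonal mutation would need to produce this VAF — and clamps it to
    ``[1, major_cn]``, since a mutation can at most occupy every copy of the
    parental allele it sits on.
    """
    nt = effective_tumor_cn(major_cn, minor_cn, clonal_fraction)
    raw = vaf * (purity * nt + (1.0 - purity) * normal_cn) / purity
    m = int(round(raw))
    return max(1, min(m, max(major_cn, 1)))


def vaf_ci_wilson(alt_count: int, depth: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial VAF."""
    if depth <= 0:
        return (0.0, 1.0)
    from scipy.stats import norm

    z = norm.ppf(0.5 + conf / 2.0)
    p = alt_count / depth
    z2 = z * z
    center = (p + z2 / (2 * depth)) / (1 + z2 / depth)
    half = z / (1 + z2 / depth) * np.sqrt(p * (1 - p) / depth + z2 / (4 * depth * depth))
    return (max(0.0, center - half), min(1.0, center + half))


def estimate_ccf(
    mutation_id: str,
    alt_count: int,
    ref_count: int,
    purity: float,
    major_cn: int = 1,
    minor_cn: int = 1,
    clonal_fraction: float = 1.0,
    normal_cn: float | None = None,
    chrom: str | None = None,
    sex: str = "female",
    covered: bool = True,
) -> CCFEstimate:
    """Full per-mutation CCF estimate with multiplicity and a 95% interval.

    When ``covered`` is False (no copy-number segment spans the mutation) a
    diploid locus with multiplicity 1 is assumed and a warning is logged.
    """
    depth = alt_count + ref_count
    if depth <= 0:
        raise ValueError(f"mutation {mutation_id}: zero read depth")
    if normal_cn is None:
        normal_cn = normal_copy_number(chrom, sex) if chrom is not None else AUTOSOMAL_NORMAL_CN
    vaf = alt_count / depth
    if not covered:
        logger.warning(
            "mutation %s has no covering copy-number segment; assuming diploid, m=1",
            mutation_id,
        )
        major_cn, minor_cn, clonal_fraction = 1, 1, 1.0
        m = 1
    else:
        m = estimate_multiplicity(vaf, purity, major_cn, minor_cn, clonal_fraction, normal_cn)
    nt = effective_tumor_cn(major_cn, minor_cn, clonal_fraction)
    ccf = ccf_from_vaf(vaf, purity, nt, normal_cn, m)
    lo_v, hi_v = vaf_ci_wilson(alt_count, depth)
    ci = (
        ccf_from_vaf(lo_v, purity, nt, normal_cn, m),
        ccf_from_vaf(hi_v, purity, nt, normal_cn, m),
    )
    return CCFEstimate(mutation_id=mutation_id, multiplicity=m, ccf=ccf, ccf_ci=ci)
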