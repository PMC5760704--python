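"""Readers and writers for mutation tables, segment tables and results.

Mutation tables are TSV with columns ``sample, chrom, pos, ref, alt,
ref_count, alt_count, label`` (1-based positions, VCF convention) or a VCF
with a per-sample AD (allelic depth) FORMAT field. Segment tables are
BED-like TSV, 0-based half-open, with ``chrom, start, end, major_cn,
minor_cn, clonal_fraction`` — the output contract of a Battenberg-style
subclonal copy-number caller.

Malformed rows are reported individually with their line numbers; reading
fails only when no valid rows remain.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

MUTATION_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "ref_count", "alt_count", "label"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn", "clonal_fraction"]


class InputError(ValueError):
    """Raised when an input file cannot yield any valid records."""


def _report(diagnostics: list[str], path, kind: str) -> None:
    for d in diagnostics:
        logger.warning("%s: %s", path, d)


def read_mutations(path: str | Path, sample: str | None = None) -> pd.DataFrame:
    """Read a mutation table from TSV or VCF (detected by extension).

    Duplicate ``(chrom, pos, alt)`` rows are rejected with a diagnostic.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        df = _read_mutations_vcf(path, sample)
    else:
        df = _read_mutations_tsv(path)
    dup = df.duplicated(subset=["chrom", "pos", "alt"], keep="first")
    if dup.any():
        for _, row in df[dup].iterrows():
            logger.warning("%s: duplicate record %s:%s %s rejected", path, row.chrom, row.pos, row.alt)
        df = df[~dup].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path}: no valid mutation records")
    return df


def _read_mutations_tsv(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in MUTATION_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    rows, diags = [], []
    for i, row in raw.iterrows():
        line = i + 2  # header is line 1
        try:
            pos = int(row["pos"])
            rc, ac = int(row["ref_count"]), int(row["alt_count"])
            if pos < 1 or rc < 0 or ac < 0:
                raise ValueError("negative or zero coordinate/count")
            if rc + ac == 0:
                raise ValueError("zero total depth")
        except (TypeError, ValueError) as e:
            diags.append(f"line {line}: {e}")
            continue
        rows.append(
            (row["sample"], str(row["chrom"]), pos, row["ref"], row["alt"], rc, ac, row["label"])
        )
    _report(diags, path, "mutation")
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def _read_mutations_vcf(path: Path, sample: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if not vcf.samples:
        raise InputError(f"{path}: VCF has no sample columns")
    if sample is None:
        sidx, sample = 0, vcf.samples[0]
    else:
        if sample not in vcf.samples:
            raise InputError(f"{path}: sample {sample!r} not in VCF")
        sidx = vcf.samples.index(sample)
    rows, diags = [], []
    for i, var in enumerate(vcf):
        ad = var.format("AD")
        if ad is None:
            diags.append(f"record {i}: no AD field")
            continue
        ref_count, alt_count = int(ad[sidx][0]), int(ad[sidx][1])
        if ref_count + alt_count <= 0:
            diags.append(f"record {i}: zero depth")
            continue
        label = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        rows.append(
            (sample, str(var.CHROM), int(var.POS), var.REF, var.ALT[0], ref_count, alt_count, label)
        )
    _report(diags, path, "mutation")
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like copy-number segment table (0-based half-open)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in SEGMENT_COLUMNS if c not in raw.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    rows, diags = [], []
    for i, row in raw.iterrows():
        line = i + 2
        try:
            start, end = int(row["start"]), int(row["end"])
            major, minor = int(row["major_cn"]), int(row["minor_cn"])
            cf = float(row["clonal_fraction"])
            if start >= end:
                raise ValueError(f"start {start} >= end {end}")
            if minor > major or major < 0 or not 0 < cf <= 1:
                raise ValueError("invalid copy state or clonal fraction")
        except (TypeError, ValueError) as e:
            diags.append(f"line {line}: {e}")
            continue
        rows.append((str(row["chrom"]), start, end, major, minor, cf))
    _report(diags, path, "segment")
    if not rows:
        raise InputError(f"{path}: no valid segment records")
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write a result table as TSV, recording the seed in a header comment."""
    path = Path(path)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)
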