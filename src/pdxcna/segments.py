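"""Segment-table and metadata I/O, and projection of segments onto the bin grid.

Segmented log2(CN ratio) profiles arrive as SEG-like TSV (one row per
segment: sample, chromosome, start, end, log2 ratio). Each sample is
projected onto the fixed 1 Mb grid; a bin overlapped by more than one
segment takes the value of the overlapping segment with the greatest
absolute log2 ratio (ties broken toward the earlier genomic start).
Any overlap of at least one base pair counts; there is no
length-weighting. Bins with no overlapping segment are masked missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinGrid

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample_id", "chromosome", "start", "end", "log2_ratio"]
META_COLUMNS = ["sample_id", "cohort", "model_id", "role", "passage", "platform"]

ROLES = {"PT", "PDX"}
DNA_PLATFORMS = {"SNP", "WES", "WGS"}


class SegmentIOError(ValueError):
    """Raised for malformed segment or metadata tables."""


def read_segments(
    path,
    column_map: dict[str, str] | None = None,
    one_based_inclusive: bool = False,
) -> pd.DataFrame:
    """Read and validate a SEG-like TSV.

    Parameters
    ----------
    column_map : optional mapping from file column names to the canonical
        names ``sample_id, chromosome, start, end, log2_ratio`` — SEG
        dialects differ (``ID``, ``chrom``, ``loc.start``, ``seg.mean`` ...).
    one_based_inclusive : set for files in 1-based inclusive coordinates;
        they are converted to 0-based half-open (start-1, end unchanged).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if column_map:
        df = df.rename(columns=column_map)
    return validate_segments(df, one_based_inclusive=one_based_inclusive)


def validate_segments(
    df: pd.DataFrame, one_based_inclusive: bool = False
) -> pd.DataFrame:
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentIOError(f"segment table missing columns: {missing}")
    df = df[SEGMENT_COLUMNS].copy()
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            rows = df.index[vals.isna()].tolist()
            raise SegmentIOError(f"non-numeric {col} in rows {rows}")
        df[col] = vals.astype(np.int64)
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    if not np.isfinite(ratios).all():
        rows = df.index[~np.isfinite(ratios)].tolist()
        raise SegmentIOError(f"non-finite log2_ratio in rows {rows}")
    df["log2_ratio"] = ratios.astype(float)
    if one_based_inclusive:
        df["start"] = df["start"] - 1
    bad = df.index[df["start"] >= df["end"]].tolist()
    if bad:
        raise SegmentIOError(f"segments with start >= end in rows {bad}")
    return df.reset_index(drop=True)


def read_sample_metadata(path, exclude_rna: bool = True) -> pd.DataFrame:
    """Read the sample-metadata TSV.

    Expression-derived profiles (platform RNA) are dropped by default,
    because expression-based CN inference confounds the discordance
    calculus the pipeline implements.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_metadata(df, exclude_rna=exclude_rna)


def validate_metadata(df: pd.DataFrame, exclude_rna: bool = True) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentIOError(f"metadata table missing columns: {missing}")
    df = df[META_COLUMNS].copy()
    bad_roles = set(df["role"].unique()) - ROLES
    if bad_roles:
        raise SegmentIOError(f"unknown sample roles: {sorted(bad_roles)}")
    df["passage"] = pd.to_numeric(df["passage"], errors="coerce")
    pdx = df["role"] == "PDX"
    if df.loc[pdx, "passage"].isna().any():
        bad = df.loc[pdx & df["passage"].isna(), "sample_id"].tolist()
        raise SegmentIOError(f"PDX samples without passage number: {bad}")
    if (df.loc[pdx, "passage"] < 0).any():
        raise SegmentIOError("negative passage numbers")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SegmentIOError(f"duplicate sample ids: {dups}")
    if exclude_rna:
        rna = ~df["platform"].isin(DNA_PLATFORMS)
        if rna.any():
            logger.warning(
                "excluding %d non-DNA (e.g. RNA) samples: %s",
                rna.sum(),
                df.loc[rna, "sample_id"].tolist(),
            )
            df = df[~rna]
    return df.reset_index(drop=True)


@dataclass
class BinnedSample:
    """One sample's per-bin log2(CN ratio) vector on the shared grid."""

    sample_id: str
    values: np.ndarray  # float, undefined where mask is False
    mask: np.ndarray  # True where a log2 ratio is present
    meta: dict | None = None

    def __post_init__(self):
        if len(self.values) != len(self.mask):
            raise SegmentIOError("values and mask lengths differ")


def bin_sample(segments: pd.DataFrame, grid: BinGrid, sample_id: str,
               meta: dict | None = None) -> BinnedSample:
    """Project one sample's segments onto the grid.

    Multi-segment bins take the value of the segment with maximum
    |log2_ratio|; equal magnitudes resolve to the segment with the
    smaller genomic start. Implemented by writing segments in order of
    (|value| ascending, start descending) so the last writer wins.
    """
    seg = segments[segments["sample_id"] == sample_id]
    if len(seg) == 0:
        raise SegmentIOError(f"no segments for sample {sample_id!r}")
    n = grid.n_bins
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    w = grid.bin_width
    order = np.lexsort((-seg["start"].values, np.abs(seg["log2_ratio"].values)))
    multi_hit = np.zeros(n, dtype=bool)
    for chrom, start, end, v in seg.iloc[order][
        ["chromosome", "start", "end", "log2_ratio"]
    ].itertuples(index=False):
        try:
            lo, hi = grid.chrom_range(chrom)
        except KeyError:
            logger.warning("dropping segment on chromosome %s: not in grid", chrom)
            continue
        first = lo + max(0, int(start) // w)
        last = min(hi, lo + int(np.ceil(end / w)))
        if first >= last:
            continue
        sl = slice(first, last)
        multi_hit[sl] |= mask[sl]
        values[sl] = v
        mask[sl] = True
    if multi_hit.any():
        logger.debug(
            "sample %s: %d bins overlapped by multiple segments (max-|value| rule applied)",
            sample_id,
            int(multi_hit.sum()),
        )
    return BinnedSample(sample_id=sample_id, values=values, mask=mask, meta=meta)


def bin_samples(
    segments: pd.DataFrame, grid: BinGrid, meta: pd.DataFrame
) -> dict[str, BinnedSample]:
    """Bin every metadata sample that has segments; warn on absent ones."""
    out: dict[str, BinnedSample] = {}
    have = set(segments["sample_id"].unique())
    for row in meta.itertuples(index=False):
        if row.sample_id not in have:
            logger.warning("sample %s has metadata but no segments", row.sample_id)
            continue
        out[row.sample_id] = bin_sample(
            segments, grid, row.sample_id, meta=row._asdict()
        )
    return out


def to_wide_table(samples: dict[str, BinnedSample], grid: BinGrid) -> pd.DataFrame:
    """Bins x samples matrix of binned log2 ratios (NaN = missing), for inspection."""
    df = grid.to_frame()
    for sid, s in samples.items():
        col = np.where(s.mask, s.values, np.nan)
        df[sid] = col
    return df
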