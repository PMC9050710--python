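"""Genome partition into fixed-width bins with chromosome-arm membership.

The 1 Mb bin grid is the coordinate system for every downstream
computation: segment projection, discordance calling, arm-level
aneuploidy calls and gene-level prevalence all address the genome by
bin ordinal. Arm membership is decided by bin midpoint so that a bin
spanning a centromere boundary is never assigned to two arms; bins
whose midpoint falls in no arm (centromeric gap) are retained in the
grid — they count toward genome-fraction denominators — but are
excluded from arm calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 1_000_000

UNASSIGNED = ""

ARM_COLUMNS = ["chromosome", "start", "end", "arm"]


class GenomeModelError(ValueError):
    """Raised for invalid arm tables or grid construction inputs."""


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    """Natural chromosome order: numeric first, then X, Y, then lexicographic."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (0, int(c))
    if c in ("X", "x"):
        return (1, 23)
    if c in ("Y", "y"):
        return (1, 24)
    return (2, c)


def read_arm_table(path) -> pd.DataFrame:
    """Read a BED-like arm table (chromosome, start, end, arm), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise GenomeModelError(f"arm table missing columns: {missing}")
    return validate_arm_table(df[ARM_COLUMNS])


def validate_arm_table(arms: pd.DataFrame) -> pd.DataFrame:
    """Validate arm intervals: non-empty, non-overlapping, p before q."""
    if len(arms) == 0:
        raise GenomeModelError("arm table is empty")
    arms = arms.copy()
    arms["chromosome"] = arms["chromosome"].astype(str)
    arms["start"] = arms["start"].astype(np.int64)
    arms["end"] = arms["end"].astype(np.int64)
    if (arms["start"] >= arms["end"]).any():
        bad = arms[arms["start"] >= arms["end"]]
        raise GenomeModelError(f"arm intervals with start >= end:\n{bad}")
    if not arms["arm"].isin(["p", "q"]).all():
        raise GenomeModelError("arm labels must be 'p' or 'q'")
    for chrom, grp in arms.groupby("chromosome", sort=False):
        g = grp.sort_values("start")
        if (g["end"].values[:-1] > g["start"].values[1:]).any():
            raise GenomeModelError(f"overlapping arm intervals on chromosome {chrom}")
        if list(g["arm"]) not in (["p"], ["q"], ["p", "q"]):
            raise GenomeModelError(
                f"chromosome {chrom}: expected p arm before q arm, got {list(g['arm'])}"
            )
    order = sorted(arms["chromosome"].unique(), key=_chrom_sort_key)
    arms["_k"] = arms["chromosome"].map({c: i for i, c in enumerate(order)})
    arms = arms.sort_values(["_k", "start"]).drop(columns="_k").reset_index(drop=True)
    return arms


def load_hg19_arms(include_sex: bool = False) -> pd.DataFrame:
    """Bundled hg19 autosome arm coordinates (UCSC centromere boundaries).

    ``include_sex`` is accepted for interface symmetry; the bundled table
    contains autosomes only, so requesting sex chromosomes raises.
    """
    if include_sex:
        raise GenomeModelError(
            "bundled hg19 arm table covers autosomes only; "
            "supply a custom arm table to include sex chromosomes"
        )
    with resources.files("pdxcna.data").joinpath("hg19_arms.tsv").open() as fh:
        return read_arm_table(fh)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width genome partition.

    Attributes
    ----------
    chromosome, start, end : arrays, one entry per bin (half-open coords).
    arm : array of arm labels like ``"1p"``; ``""`` marks bins whose
        midpoint falls outside every arm (e.g. centromeric gap).
    bin_width : nominal width; the last bin of each chromosome may be shorter.
    """

    chromosome: np.ndarray
    start: np.ndarray
    end: np.ndarray
    arm: np.ndarray
    bin_width: int
    _chrom_offsets: dict = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """(first bin index, one-past-last bin index) for a chromosome."""
        return self._chrom_offsets[str(chrom)]

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_offsets)

    def arm_indices(self) -> dict[str, np.ndarray]:
        """Mapping arm label -> bin indices, arm-assigned bins only."""
        out: dict[str, np.ndarray] = {}
        for a in pd.unique(self.arm):
            if a == UNASSIGNED:
                continue
            out[a] = np.flatnonzero(self.arm == a)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chromosome,
                "start": self.start,
                "end": self.end,
                "arm": self.arm,
            }
        )


def build_bin_grid(arms: pd.DataFrame, bin_width: int = DEFAULT_BIN_WIDTH) -> BinGrid:
    """Tile each chromosome with half-open bins of ``bin_width`` anchored at 0.

    Bins tile [0, chromosome_end) where chromosome_end is the largest arm
    end; arm membership is assigned by bin midpoint.
    """
    arms = validate_arm_table(arms)
    if bin_width <= 0:
        raise GenomeModelError("bin_width must be positive")
    chroms, starts, ends, labels = [], [], [], []
    for chrom in arms["chromosome"].unique():
        grp = arms[arms["chromosome"] == chrom]
        chrom_end = int(grp["end"].max())
        bin_starts = np.arange(0, chrom_end, bin_width, dtype=np.int64)
        bin_ends = np.minimum(bin_starts + bin_width, chrom_end)
        mid = (bin_starts + bin_ends) // 2
        lab = np.full(len(bin_starts), UNASSIGNED, dtype=object)
        for _, row in grp.iterrows():
            inside = (mid >= row["start"]) & (mid < row["end"])
            lab[inside] = f"{chrom}{row['arm']}"
        chroms.append(np.full(len(bin_starts), str(chrom), dtype=object))
        starts.append(bin_starts)
        ends.append(bin_ends)
        labels.append(lab)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    chromosome = np.concatenate(chroms)
    arm = np.concatenate(labels)
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for c in pd.unique(chromosome):
        n = int((chromosome == c).sum())
        offsets[str(c)] = (pos, pos + n)
        pos += n
    n_unassigned = int((arm == UNASSIGNED).sum())
    if n_unassigned:
        logger.info("%d bins unassigned to any arm (centromeric gaps)", n_unassigned)
    return BinGrid(
        chromosome=chromosome,
        start=start,
        end=end,
        arm=arm,
        bin_width=int(bin_width),
        _chrom_offsets=offsets,
    )
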