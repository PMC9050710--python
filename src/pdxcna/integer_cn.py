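"""Ploidy-adjusted integer copy-number discordance.

This module consumes per-bin integer CN call tables of the kind an
impurity-aware HMM caller (e.g. ichorCNA) emits — integer CN per bin,
cellular prevalence for subclonal calls, and sample-level ploidy and
tumor fraction — and applies the downstream discordance calculus. The
HMM itself is never run here.

Every profile is rescaled to a diploid frame before comparison:

    adjusted CN = CN / ploidy * 2

so a triploid genome's clonal baseline lands at 2.0 like a diploid's.
Rounded adjusted CN > 2 is a gain and < 2 a loss; a bin is discordant
when exactly one sample carries a gain or loss the other lacks *and*
the unrounded adjusted CNs differ by at least 0.5.

Subclonal calls resolve by cellular prevalence: above 90% they are
treated as clonal, below 10% as neutral, and intermediate prevalences
(10–90%, inclusive) drop the bin from the comparison entirely.

When paired samples' estimated ploidies fail to converge (differ by
more than 0.2), the rerun policy decides which sample an external
caller should re-fit at a restricted starting ploidy; the policy is a
pure function that only emits directives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinGrid
from .threshold import (
    MIN_ARM_BINS,
    BinStatus,
    DiscordanceError,
    PairDiscordance,
    _collect_arm_calls,
)

logger = logging.getLogger(__name__)

CLONAL_PREVALENCE = 0.9  # strictly above: treat subclonal call as clonal
NEUTRAL_PREVALENCE = 0.1  # strictly below: treat subclonal call as neutral
ADJUSTED_GAP = 0.5
PLOIDY_CONVERGENCE = 0.2
MIN_TUMOR_FRACTION = 0.05
MIN_CLONAL_ALTERED = 0.05


@dataclass
class IntegerCNSample:
    """Per-bin integer CN calls with sample-level ploidy and tumor fraction.

    ``cn`` is NaN where the caller produced no call; ``prevalence`` is
    NaN for clonal calls and holds the cellular prevalence for
    subclonal ones.
    """

    sample_id: str
    cn: np.ndarray
    prevalence: np.ndarray
    ploidy: float
    tumor_fraction: float
    meta: dict | None = None

    def __post_init__(self):
        if self.ploidy <= 0:
            raise DiscordanceError(f"{self.sample_id}: ploidy must be positive")
        if not 0 <= self.tumor_fraction <= 1:
            raise DiscordanceError(f"{self.sample_id}: tumor fraction outside [0,1]")
        prev = self.prevalence[~np.isnan(self.prevalence)]
        if ((prev < 0) | (prev > 1)).any():
            raise DiscordanceError(
                f"{self.sample_id}: cellular prevalence outside [0,1]"
            )
        if len(self.cn) != len(self.prevalence):
            raise DiscordanceError("cn and prevalence lengths differ")


@dataclass(frozen=True)
class RerunDirective:
    """Instruction for the external caller: re-fit this sample at this starting ploidy."""

    sample_id: str
    restricted_start_ploidy: float


def round_half_away(x):
    """Round half away from zero (2.5 -> 3), elementwise; avoids bankers' rounding."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def ploidy_adjust(cn, ploidy: float):
    """Rescale integer CN to a diploid frame: cn / ploidy * 2."""
    if ploidy <= 0:
        raise DiscordanceError("ploidy must be positive")
    return np.asarray(cn, dtype=float) / ploidy * 2.0


def resolve_subclonal(sample: IntegerCNSample) -> np.ndarray:
    """Resolve subclonal calls to a per-bin clonal CN vector.

    Returns a float array: the called CN for clonal (and >90%-prevalence
    subclonal) bins, round(ploidy) for <10%-prevalence bins, and NaN for
    intermediate-prevalence bins (excluded from discordance) as well as
    bins with no call.
    """
    resolved = sample.cn.astype(float).copy()
    prev = sample.prevalence
    sub = ~np.isnan(prev) & ~np.isnan(resolved)
    neutral_cn = float(round_half_away(sample.ploidy))
    resolved[sub & (prev < NEUTRAL_PREVALENCE)] = neutral_cn
    excluded = sub & (prev >= NEUTRAL_PREVALENCE) & (prev <= CLONAL_PREVALENCE)
    resolved[excluded] = np.nan
    # prevalence > 0.9: keep the called cn (already in `resolved`)
    return resolved


def _adjusted_state(adj):
    """Gain/loss/neutral from rounded adjusted CN (>2 gain, <2 loss)."""
    rounded = round_half_away(adj)
    return np.where(rounded > 2, 1, np.where(rounded < 2, -1, 0)).astype(np.int8)


def int_bin_discordant(a_adj, b_adj):
    """Discordance codes for paired ploidy-adjusted CNs (BinStatus values)."""
    a_adj = np.asarray(a_adj, dtype=float)
    b_adj = np.asarray(b_adj, dtype=float)
    sa = _adjusted_state(a_adj)
    sb = _adjusted_state(b_adj)
    unique_event = ((sa != 0) | (sb != 0)) & (sa != sb)
    disc = unique_event & (np.abs(a_adj - b_adj) >= ADJUSTED_GAP)
    out = np.zeros(np.broadcast(a_adj, b_adj).shape, dtype=np.int8)
    out[disc & (a_adj > b_adj)] = BinStatus.A_GREATER
    out[disc & (b_adj > a_adj)] = BinStatus.B_GREATER
    return out


def clonal_altered_fraction(sample: IntegerCNSample) -> float:
    """Fraction of called bins that are clonally altered after adjustment + rounding."""
    called = ~np.isnan(sample.cn)
    if not called.any():
        raise DiscordanceError(f"{sample.sample_id}: no CN calls")
    resolved = resolve_subclonal(sample)
    adj = ploidy_adjust(resolved, sample.ploidy)
    altered = _adjusted_state(np.where(np.isnan(adj), 2.0, adj)) != 0
    altered &= ~np.isnan(adj)
    return float(altered.sum() / called.sum())


def int_sample_pass(sample: IntegerCNSample) -> bool:
    """Sample-level exclusion: needs >=5% tumor fraction and >=5% clonally altered bins."""
    if sample.tumor_fraction < MIN_TUMOR_FRACTION:
        return False
    return clonal_altered_fraction(sample) >= MIN_CLONAL_ALTERED


def int_pair_discordance(
    a: IntegerCNSample,
    b: IntegerCNSample,
    grid: BinGrid,
    comparison_type: str = "PT_PDX",
    enforce_filters: bool = True,
    min_arm_bins: int = MIN_ARM_BINS,
) -> PairDiscordance:
    """Genome-fraction and arm-level discordance between two integer-CN profiles.

    Bins excluded by the intermediate-prevalence rule (in either sample)
    are not evaluable and drop out of the denominator, mirroring the
    missing-data handling of the thresholds calculus.
    """
    if len(a.cn) != grid.n_bins or len(b.cn) != grid.n_bins:
        raise DiscordanceError("samples not aligned to grid")
    if enforce_filters:
        for s in (a, b):
            if not int_sample_pass(s):
                raise DiscordanceError(
                    f"sample {s.sample_id} fails tumor-fraction / clonal-CNA filters"
                )
    a_res = resolve_subclonal(a)
    b_res = resolve_subclonal(b)
    a_adj = ploidy_adjust(a_res, a.ploidy)
    b_adj = ploidy_adjust(b_res, b.ploidy)
    evaluable = ~np.isnan(a_adj) & ~np.isnan(b_adj)
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise DiscordanceError(
            f"no bins evaluable in both {a.sample_id} and {b.sample_id}"
        )
    status = np.full(grid.n_bins, BinStatus.NOT_EVALUABLE, dtype=np.int8)
    status[evaluable] = int_bin_discordant(a_adj[evaluable], b_adj[evaluable])
    n_disc = int((np.abs(status[evaluable].astype(int)) == 1).sum())
    arms = _collect_arm_calls(status, grid, min_arm_bins)
    return PairDiscordance(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        comparison_type=comparison_type,
        bin_status=status,
        fraction_discordant=n_disc / n_eval,
        n_evaluable_bins=n_eval,
        discordant_arms=arms,
    )


def ploidy_rerun_policy(
    model_samples: list[IntegerCNSample], seed: int = 0
) -> list[RerunDirective]:
    """Decide which samples of one model need re-fitting for ploidy convergence.

    Triggered when any two samples' ploidies differ by more than 0.2:

    * PT + one PDX: rerun the PT at the PDX's estimated ploidy.
    * two PDXs: rerun the lower-tumor-fraction one at its partner's
      ploidy; on a tumor-fraction tie, the higher-ploidy one.
    * more than two samples: restrict to the most common rounded ploidy
      (tie broken uniformly at random with the recorded seed); every
      sample more than 0.2 away from it gets a directive.

    The directive carries the *target* ploidy; snapping to the external
    caller's allowed starting-ploidy grid is the runner's concern.
    """
    if len(model_samples) < 2:
        raise DiscordanceError("rerun policy needs at least two samples")
    ploidies = np.array([s.ploidy for s in model_samples])
    if ploidies.max() - ploidies.min() <= PLOIDY_CONVERGENCE:
        return []
    roles = [
        (s.meta or {}).get("role", "PDX") for s in model_samples
    ]
    if len(model_samples) == 2:
        s1, s2 = model_samples
        if set(roles) == {"PT", "PDX"}:
            pt, pdx = (s1, s2) if roles[0] == "PT" else (s2, s1)
            return [RerunDirective(pt.sample_id, pdx.ploidy)]
        # two PDXs (or indeterminate roles): lower tumor fraction reruns
        if s1.tumor_fraction < s2.tumor_fraction:
            victim, partner = s1, s2
        elif s2.tumor_fraction < s1.tumor_fraction:
            victim, partner = s2, s1
        else:
            victim, partner = (s1, s2) if s1.ploidy > s2.ploidy else (s2, s1)
        return [RerunDirective(victim.sample_id, partner.ploidy)]
    rounded = round_half_away(ploidies).astype(int)
    counts = pd.Series(rounded).value_counts()
    top = counts[counts == counts.max()].index.to_numpy()
    if len(top) > 1:
        rng = np.random.default_rng(seed)
        target = float(rng.choice(np.sort(top)))
        logger.info("ploidy tie among %s; picked %s (seed %d)", sorted(top), target, seed)
    else:
        target = float(top[0])
    return [
        RerunDirective(s.sample_id, target)
        for s in model_samples
        if abs(s.ploidy - target) > PLOIDY_CONVERGENCE
    ]


def read_integer_cn(
    bins_path, grid: BinGrid, sample_id: str, ploidy: float,
    tumor_fraction: float, meta: dict | None = None,
) -> IntegerCNSample:
    """Read one sample's per-bin integer-CN TSV (chromosome, start, end, cn, prevalence).

    A record spanning several bins fills all bins it covers; callers of
    this kind emit bin-aligned rows, so this is a passthrough in
    practice. An empty ``prevalence`` field means a clonal call.
    """
    df = pd.read_csv(bins_path, sep="\t", dtype={"chromosome": str})
    for col in ("chromosome", "start", "end", "cn"):
        if col not in df.columns:
            raise DiscordanceError(f"integer-CN table missing column {col!r}")
    cn = np.full(grid.n_bins, np.nan)
    prev = np.full(grid.n_bins, np.nan)
    w = grid.bin_width
    for row in df.itertuples(index=False):
        try:
            lo, hi = grid.chrom_range(row.chromosome)
        except KeyError:
            continue
        first = lo + max(0, int(row.start) // w)
        last = min(hi, lo + int(np.ceil(int(row.end) / w)))
        if first >= last:
            continue
        cn[first:last] = row.cn
        p = getattr(row, "prevalence", np.nan)
        prev[first:last] = float(p) if p == p else np.nan
    return IntegerCNSample(
        sample_id=sample_id, cn=cn, prevalence=prev,
        ploidy=float(ploidy), tumor_fraction=float(tumor_fraction), meta=meta,
    )
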