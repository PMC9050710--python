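"""Thresholds-based copy-number discordance between paired samples.

A bin is called a gain when its log2(CN ratio) is >= +0.3 and a loss
when <= -0.3. Two samples disagree at a bin when exactly one of them
carries a gain or loss that the other lacks, *and* the pair clears a
borderline guard: either their log2 ratios differ by at least 0.3, or
the non-altered sample sits close to neutral (|value| < 0.1). The four
clauses below are symmetric in the two samples, so the relation is
symmetric with the direction reversed.

The genome fraction discordant is the number of discordant bins over
the number of bins where both samples have values. A chromosome arm is
discordant when at least 75% of its evaluable bins are discordant and
every discordant bin has the same sample on the high side — the arm
proxy for an aneuploidy difference.

Samples whose profile is nearly flat (< 5% of bins with |log2 ratio|
>= 0.3) are presumed to lack tumor content and are excluded before
pairing; the filter can be disabled to reproduce the sensitivity
analysis without purity exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .genome import UNASSIGNED, BinGrid
from .segments import BinnedSample

GAIN_THRESHOLD = 0.3
GAP_THRESHOLD = 0.3
NEAR_NEUTRAL = 0.1
ARM_FRACTION = 0.75
PURITY_MIN_ALTERED = 0.05
MIN_ARM_BINS = 10


class BinStatus(IntEnum):
    """Per-bin comparison status; sign encodes which sample is higher."""

    NOT_EVALUABLE = -2
    B_GREATER = -1
    CONCORDANT = 0
    A_GREATER = 1


class DiscordanceError(ValueError):
    pass


def call_state(v):
    """Gain/loss/neutral call per bin: +1 gain (v >= 0.3), -1 loss (v <= -0.3), 0 neutral."""
    v = np.asarray(v, dtype=float)
    return np.where(v >= GAIN_THRESHOLD, 1, np.where(v <= -GAIN_THRESHOLD, -1, 0)).astype(
        np.int8
    )


def bin_discordant(a, b):
    """Vectorized discordance call for paired log2 ratios.

    Returns int8 codes: 0 concordant, +1 discordant with a greater,
    -1 discordant with b greater (``BinStatus`` values).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, g, nn = GAIN_THRESHOLD, GAP_THRESHOLD, NEAR_NEUTRAL
    c1 = (a >= t) & (b < t) & (((a - b) >= g) | (b < nn))
    c2 = (a <= -t) & (b > -t) & (((a - b) <= -g) | (b > -nn))
    c3 = (b >= t) & (a < t) & (((b - a) >= g) | (a < nn))
    c4 = (b <= -t) & (a > -t) & (((b - a) <= -g) | (a > -nn))
    out = np.zeros(np.broadcast(a, b).shape, dtype=np.int8)
    out[c1 | c4] = BinStatus.A_GREATER
    out[c2 | c3] = BinStatus.B_GREATER
    return out


def genome_altered_fraction(sample: BinnedSample) -> float:
    """Fraction of a sample's bins with |log2 ratio| >= 0.3 (its CNA burden)."""
    if not sample.mask.any():
        raise DiscordanceError(f"sample {sample.sample_id}: all bins masked")
    v = sample.values[sample.mask]
    return float((np.abs(v) >= GAIN_THRESHOLD).mean())


def purity_pass(sample: BinnedSample, min_altered: float = PURITY_MIN_ALTERED) -> bool:
    """True when the sample shows enough CNA signal to be analyzable.

    Exclusion is strict: a sample fails only when *less than* 5% of its
    bins are altered, so exactly 5% passes.
    """
    return genome_altered_fraction(sample) >= min_altered


@dataclass
class PairDiscordance:
    """Result of comparing two binned samples."""

    sample_a: str
    sample_b: str
    comparison_type: str
    bin_status: np.ndarray  # BinStatus codes per grid bin
    fraction_discordant: float
    n_evaluable_bins: int
    discordant_arms: list = field(default_factory=list)  # (chromosome, arm, direction)

    @property
    def n_discordant_arms(self) -> int:
        return len(self.discordant_arms)


def arm_discordant(statuses: np.ndarray, min_bins: int = MIN_ARM_BINS):
    """Arm-level call from one arm's bin statuses.

    Returns ``"a_greater"`` / ``"b_greater"`` when >= 75% of the arm's
    evaluable bins are discordant and all discordant bins agree on which
    sample is higher; ``None`` otherwise or when the arm has fewer than
    ``min_bins`` evaluable bins.
    """
    statuses = np.asarray(statuses)
    evaluable = statuses != BinStatus.NOT_EVALUABLE
    n_eval = int(evaluable.sum())
    if n_eval < min_bins:
        return None
    disc = statuses[evaluable]
    disc = disc[disc != BinStatus.CONCORDANT]
    if len(disc) / n_eval < ARM_FRACTION:
        return None
    if (disc == BinStatus.A_GREATER).all():
        return "a_greater"
    if (disc == BinStatus.B_GREATER).all():
        return "b_greater"
    return None


def _collect_arm_calls(status: np.ndarray, grid: BinGrid, min_arm_bins: int) -> list:
    arms = []
    for label, idx in grid.arm_indices().items():
        direction = arm_discordant(status[idx], min_bins=min_arm_bins)
        if direction is not None:
            chrom = grid.chromosome[idx[0]]
            arms.append((str(chrom), label[len(str(chrom)):], direction))
    return arms


def pair_discordance(
    a: BinnedSample,
    b: BinnedSample,
    grid: BinGrid,
    comparison_type: str = "PT_PDX",
    enforce_purity: bool = True,
    min_arm_bins: int = MIN_ARM_BINS,
) -> PairDiscordance:
    """Full per-bin, genome-fraction and arm-level comparison of two samples."""
    if len(a.values) != grid.n_bins or len(b.values) != grid.n_bins:
        raise DiscordanceError("samples not aligned to grid")
    if enforce_purity:
        for s in (a, b):
            if not purity_pass(s):
                raise DiscordanceError(
                    f"sample {s.sample_id} fails the low-purity filter "
                    "(pass enforce_purity=False to skip)"
                )
    evaluable = a.mask & b.mask
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise DiscordanceError(
            f"no bins evaluable in both {a.sample_id} and {b.sample_id}"
        )
    status = np.full(grid.n_bins, BinStatus.NOT_EVALUABLE, dtype=np.int8)
    status[evaluable] = bin_discordant(a.values[evaluable], b.values[evaluable])
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
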