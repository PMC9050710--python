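"""Synthetic paired PT/PDX cohorts with known copy-number ground truth.

The generator plants clonal and subclonal CNAs on a configurable
genome, propagates them through PDX lineages with per-passage drift,
and emits the same three inputs the pipeline reads from real studies —
SEG-like segment tables, per-bin integer-CN call tables with cellular
prevalence / ploidy / tumor fraction, and a sample-metadata table —
plus the ground truth needed to score every downstream stage.

Model of one cohort:

* each model starts from a primary tumor whose genome carries
  ``Poisson(shared_cna_rate)`` planted events (whole-arm with
  probability ``arm_event_prob``, focal otherwise);
* a single PDX lineage inherits the PT genome and accumulates
  ``Poisson(private_cna_rate_per_passage)`` further events per drift
  step; engraftment counts as the first step, so a passage-p sample has
  undergone p + 1 steps and later passages strictly contain earlier
  ones' events;
* an event is a gain (one extra copy, log2 3/2) or a loss (one lost
  copy, log2 1/2), clonal unless a ``subclonal_prob`` coin makes it
  subclonal with cellular prevalence drawn from ``prevalence_dist``;
* the observed log2 ratio passes the prevalence and purity mixtures in
  linear-ratio space — observed = log2(purity * 2^t_eff + 1 - purity)
  with t_eff = log2(prev * 2^t + 1 - prev) — then gains additive
  Gaussian noise per bin.

Event boundaries are aligned to the 1 Mb bin lattice so planted
discordance fractions are exactly countable. Randomness flows from a
single seed; each model uses a deterministic substream, so regenerating
any model reproduces it bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import BinGrid, build_bin_grid
from .integer_cn import IntegerCNSample, round_half_away


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a mid-size DNA-sequenced PDX cohort: 20 models
    sampled at engraftment (P0), first passage and fourth passage, a
    10-chromosome / 1,000-bin genome, ~8 truncal events per tumor, one
    private event per drift step, moderate PT purity (0.7) against
    near-pure PDXs (0.95), and 0.05 log2 units of measurement noise.
    """

    seed: int = 0
    n_models: int = 20
    passages_per_model: tuple = (0, 1, 4)
    n_chromosomes: int = 10
    arm_lengths: tuple = (50_000_000, 50_000_000)  # (p, q) in bp
    bin_width: int = 1_000_000
    shared_cna_rate: float = 8.0  # truncal events per genome
    private_cna_rate_per_passage: float = 1.0
    arm_event_prob: float = 0.25
    focal_length_dist: tuple = (3_000_000, 20_000_000)  # min, max bp
    gain_log2: float = float(np.log2(1.5))  # 3 copies on a diploid background
    loss_log2: float = -1.0  # 1 copy
    purity_pt: float = 0.7
    purity_pdx: float = 0.95
    noise_sd: float = 0.05
    subclonal_prob: float = 0.1
    prevalence_dist: tuple = (0.05, 0.95)
    cohort: str = "sim"
    include_pt: bool = True

    def __post_init__(self):
        if self.n_models < 1 or self.n_chromosomes < 1:
            raise SimulationError("need at least one model and one chromosome")
        if self.shared_cna_rate < 0 or self.private_cna_rate_per_passage < 0:
            raise SimulationError("event rates must be non-negative")
        for p in (self.purity_pt, self.purity_pdx):
            if not 0 < p <= 1:
                raise SimulationError("purities must lie in (0, 1]")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if not 0 <= self.subclonal_prob <= 1:
            raise SimulationError("subclonal_prob must lie in [0, 1]")
        lo, hi = self.focal_length_dist
        if not 0 < lo <= hi:
            raise SimulationError("invalid focal length range")
        if hi > max(self.arm_lengths):
            raise SimulationError("focal events longer than the longest arm")


def make_arm_table(cfg: SimConfig) -> pd.DataFrame:
    """Arm coordinates of the synthetic genome: chromosomes "1"..n, contiguous p|q."""
    lp, lq = cfg.arm_lengths
    rows = []
    for c in range(1, cfg.n_chromosomes + 1):
        rows.append({"chromosome": str(c), "start": 0, "end": lp, "arm": "p"})
        rows.append({"chromosome": str(c), "start": lp, "end": lp + lq, "arm": "q"})
    return pd.DataFrame(rows)


@dataclass
class _TruthState:
    """Per-bin clonal truth of one genome."""

    t: np.ndarray  # clonal log2 ratio of the event (0 = neutral)
    cn: np.ndarray  # integer copy number of the event carrier clone
    prevalence: np.ndarray  # cellular prevalence (1 = clonal)

    @classmethod
    def neutral(cls, n_bins: int) -> "_TruthState":
        return cls(
            t=np.zeros(n_bins),
            cn=np.full(n_bins, 2.0),
            prevalence=np.ones(n_bins),
        )

    def copy(self) -> "_TruthState":
        return _TruthState(self.t.copy(), self.cn.copy(), self.prevalence.copy())

    def t_eff(self) -> np.ndarray:
        """Effective log2 ratio at purity 1: prevalence-weighted linear mixture."""
        return np.log2(self.prevalence * np.exp2(self.t) + (1 - self.prevalence))


def _draw_event(rng, grid: BinGrid, cfg: SimConfig):
    """One planted event: (first_bin, last_bin, log2 value, cn, prevalence)."""
    if rng.random() < cfg.arm_event_prob:
        arms = grid.arm_indices()
        label = sorted(arms)[rng.integers(len(arms))]
        idx = arms[label]
        first, last = int(idx[0]), int(idx[-1]) + 1
    else:
        lo_bp, hi_bp = cfg.focal_length_dist
        w = cfg.bin_width
        min_bins = max(1, lo_bp // w)
        max_bins = max(min_bins, hi_bp // w)
        length = int(rng.integers(min_bins, max_bins + 1))
        chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
        lo, hi = grid.chrom_range(chrom)
        length = min(length, hi - lo)
        first = int(rng.integers(lo, hi - length + 1))
        last = first + length
    t = cfg.gain_log2 if rng.random() < 0.5 else cfg.loss_log2
    cn = max(0.0, float(round_half_away(2.0 * 2.0 ** t)))
    if rng.random() < cfg.subclonal_prob:
        prevalence = float(rng.uniform(*cfg.prevalence_dist))
    else:
        prevalence = 1.0
    return first, last, t, cn, prevalence


def _apply_events(state: _TruthState, rng, n_events: int, grid: BinGrid,
                  cfg: SimConfig) -> None:
    for _ in range(n_events):
        first, last, t, cn, prev = _draw_event(rng, grid, cfg)
        state.t[first:last] = t
        state.cn[first:last] = cn
        state.prevalence[first:last] = prev


def _eq3_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent transcription of the four discordance clauses, for truth scoring."""
    c1 = (a >= 0.3) & (b < 0.3) & (((a - b) >= 0.3) | (b < 0.1))
    c2 = (a <= -0.3) & (b > -0.3) & (((a - b) <= -0.3) | (b > -0.1))
    c3 = (b >= 0.3) & (a < 0.3) & (((b - a) >= 0.3) | (a < 0.1))
    c4 = (b <= -0.3) & (a > -0.3) & (((b - a) <= -0.3) | (a > -0.1))
    out = np.zeros(len(a), dtype=np.int8)
    out[c1 | c4] = 1
    out[c2 | c3] = -1
    return out


@dataclass
class GroundTruth:
    """Planted truth, queryable per sample and per pair."""

    grid: BinGrid
    t_eff: dict = field(default_factory=dict)
    cn: dict = field(default_factory=dict)
    prevalence: dict = field(default_factory=dict)

    def truth_fraction(self, sample_a: str, sample_b: str) -> float:
        """Ground-truth discordant-bin fraction at purity 1, noise 0."""
        codes = _eq3_codes(self.t_eff[sample_a], self.t_eff[sample_b])
        return float((codes != 0).mean())

    def truth_arms(self, sample_a: str, sample_b: str,
                   min_bins: int = 10) -> list:
        """Ground-truth discordant arm set under the 75% uniform-direction rule."""
        codes = _eq3_codes(self.t_eff[sample_a], self.t_eff[sample_b])
        arms = []
        for label, idx in self.grid.arm_indices().items():
            c = codes[idx]
            if len(c) < min_bins:
                continue
            disc = c[c != 0]
            if len(disc) / len(c) >= 0.75 and len(set(disc.tolist())) == 1:
                arms.append((label, "a_greater" if disc[0] == 1 else "b_greater"))
        return arms


@dataclass
class SimResult:
    """Everything one simulated cohort produces."""

    config: SimConfig
    arms: pd.DataFrame
    grid: BinGrid
    segments: pd.DataFrame
    meta: pd.DataFrame
    integer_cn: dict  # sample_id -> IntegerCNSample
    truth: GroundTruth


def _emit_sample(sample_id, state: _TruthState, purity, rng, cfg, grid,
                 segments_rows, integer_cn, truth):
    t_eff = state.t_eff()
    observed = np.log2(purity * np.exp2(t_eff) + (1 - purity))
    if cfg.noise_sd > 0:
        observed = observed + rng.normal(0.0, cfg.noise_sd, size=len(observed))
    segments_rows.append(
        pd.DataFrame(
            {
                "sample_id": sample_id,
                "chromosome": grid.chromosome,
                "start": grid.start,
                "end": grid.end,
                "log2_ratio": observed,
            }
        )
    )
    prevalence = np.where(state.prevalence < 1.0, state.prevalence, np.nan)
    integer_cn[sample_id] = IntegerCNSample(
        sample_id=sample_id,
        cn=state.cn.copy(),
        prevalence=prevalence,
        ploidy=float(state.cn.mean()),
        tumor_fraction=float(purity),
    )
    truth.t_eff[sample_id] = t_eff
    truth.cn[sample_id] = state.cn.copy()
    truth.prevalence[sample_id] = state.prevalence.copy()


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate one cohort of paired PT/PDX profiles with ground truth."""
    arms = make_arm_table(cfg)
    grid = build_bin_grid(arms, bin_width=cfg.bin_width)
    truth = GroundTruth(grid=grid)
    segments_rows: list[pd.DataFrame] = []
    integer_cn: dict[str, IntegerCNSample] = {}
    meta_rows = []
    passages = sorted(cfg.passages_per_model)
    for m in range(cfg.n_models):
        rng = np.random.default_rng([cfg.seed, m])
        model_id = f"M{m:03d}"
        pt_state = _TruthState.neutral(grid.n_bins)
        n_shared = int(rng.poisson(cfg.shared_cna_rate))
        _apply_events(pt_state, rng, n_shared, grid, cfg)
        if cfg.include_pt:
            sid = f"{cfg.cohort}_{model_id}_PT"
            _emit_sample(sid, pt_state, cfg.purity_pt, rng, cfg, grid,
                         segments_rows, integer_cn, truth)
            meta_rows.append(
                {"sample_id": sid, "cohort": cfg.cohort, "model_id": model_id,
                 "role": "PT", "passage": np.nan, "platform": "WGS"}
            )
        # one lineage per model: engraftment is drift step 0, passage k adds step k
        state = pt_state.copy()
        next_snapshot = 0
        for step in range(passages[-1] + 1):
            n_private = int(rng.poisson(cfg.private_cna_rate_per_passage))
            _apply_events(state, rng, n_private, grid, cfg)
            while next_snapshot < len(passages) and passages[next_snapshot] == step:
                p = passages[next_snapshot]
                sid = f"{cfg.cohort}_{model_id}_P{p}"
                _emit_sample(sid, state, cfg.purity_pdx, rng, cfg, grid,
                             segments_rows, integer_cn, truth)
                meta_rows.append(
                    {"sample_id": sid, "cohort": cfg.cohort, "model_id": model_id,
                     "role": "PDX", "passage": p, "platform": "WGS"}
                )
                next_snapshot += 1
    segments = pd.concat(segments_rows, ignore_index=True)
    meta = pd.DataFrame(meta_rows)
    return SimResult(
        config=cfg, arms=arms, grid=grid, segments=segments,
        meta=meta, integer_cn=integer_cn, truth=truth,
    )


def truth_fraction(truth: GroundTruth, sample_a: str, sample_b: str) -> float:
    """Functional alias for :meth:`GroundTruth.truth_fraction`."""
    return truth.truth_fraction(sample_a, sample_b)


def simulate_study(cfg: SimConfig, n_cohorts: int) -> list[SimResult]:
    """Several cohorts from one base configuration, each on its own substream."""
    return [
        simulate_cohort(
            replace(cfg, cohort=f"{cfg.cohort}{i:02d}", seed=cfg.seed + 1000 * (i + 1))
        )
        for i in range(n_cohorts)
    ]


def simulate_gene_annotation(grid: BinGrid, n_genes: int = 500,
                             seed: int = 0) -> pd.DataFrame:
    """Synthetic gene annotation: random 10 kb – 2 Mb intervals on the grid's genome."""
    rng = np.random.default_rng([seed, 7919])
    chroms = grid.chromosomes
    rows = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = grid.chrom_range(chrom)
        chrom_len = int(grid.end[hi - 1])
        length = int(rng.integers(10_000, 2_000_000))
        start = int(rng.integers(0, max(1, chrom_len - length)))
        rows.append(
            {"chromosome": chrom, "start": start, "end": start + length,
             "gene_id": f"G{i:04d}"}
        )
    return pd.DataFrame(rows)


def simulate_gene_sets(gene_ids, n_sets: int = 10, set_size: int = 50,
                       seed: int = 0) -> dict[str, set]:
    """Hallmark-like gene sets sampled without replacement from the annotation."""
    rng = np.random.default_rng([seed, 104729])
    gene_ids = list(gene_ids)
    if set_size > len(gene_ids):
        raise SimulationError("set_size exceeds the number of genes")
    return {
        f"SET_{i:02d}": set(rng.choice(gene_ids, size=set_size, replace=False))
        for i in range(n_sets)
    }


def simulate_arm_prevalence(tumor_types, arms, seed: int = 0) -> pd.DataFrame:
    """Synthetic per-tumor-type arm-alteration prevalence table (stand-in for
    patient-cohort aneuploidy calls; values uniform on [0.05, 0.7])."""
    rng = np.random.default_rng([seed, 65537])
    rows = [
        {"tumor_type": tt, "arm": arm,
         "prevalence": float(np.round(rng.uniform(0.05, 0.7), 3))}
        for tt in tumor_types
        for arm in arms
    ]
    return pd.DataFrame(rows)


def write_cohort(result: SimResult, outdir) -> dict:
    """Write the cohort in the pipeline's on-disk input formats; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "segments": os.path.join(outdir, "segments.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "arms": os.path.join(outdir, "arms.tsv"),
        "sample_stats": os.path.join(outdir, "sample_stats.tsv"),
        "integer_cn_dir": os.path.join(outdir, "integer_cn"),
    }
    result.segments.to_csv(paths["segments"], sep="\t", index=False)
    result.meta.to_csv(paths["metadata"], sep="\t", index=False)
    result.arms.to_csv(paths["arms"], sep="\t", index=False)
    stats_rows = [
        {"sample_id": sid, "ploidy": s.ploidy, "tumor_fraction": s.tumor_fraction}
        for sid, s in result.integer_cn.items()
    ]
    pd.DataFrame(stats_rows).to_csv(paths["sample_stats"], sep="\t", index=False)
    os.makedirs(paths["integer_cn_dir"], exist_ok=True)
    grid = result.grid
    for sid, s in result.integer_cn.items():
        df = pd.DataFrame(
            {
                "chromosome": grid.chromosome,
                "start": grid.start,
                "end": grid.end,
                "cn": s.cn,
                "prevalence": s.prevalence,
            }
        )
        df.to_csv(os.path.join(paths["integer_cn_dir"], f"{sid}.tsv"),
                  sep="\t", index=False)
    return paths
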