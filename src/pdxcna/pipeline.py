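"""End-to-end orchestration: from segment tables to the full report bundle.

``run_pipeline`` wires the stages together — grid construction, segment
binning, purity exclusion, pairing, discordance, cohort aggregation,
passage-stratified tests, trios, gene-level prevalence/enrichment and
the aneuploidy power analysis — and writes one TSV per result table
plus a JSON run manifest recording thresholds, seed and per-sample
exclusions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import genes as genes_mod
from . import pairing, power, threshold
from .genome import build_bin_grid, load_hg19_arms, read_arm_table
from .segments import bin_samples, read_sample_metadata, read_segments

logger = logging.getLogger(__name__)

METHOD_DEFAULTS = {
    "gain_loss_log2": threshold.GAIN_THRESHOLD,
    "arm_fraction": threshold.ARM_FRACTION,
    "purity_min_altered": threshold.PURITY_MIN_ALTERED,
    "min_arm_bins": threshold.MIN_ARM_BINS,
    "min_pairs_per_cohort": pairing.MIN_PAIRS_PER_COHORT,
    "top_gene_quantile": genes_mod.TOP_GENE_QUANTILE,
    "min_gene_proportion": genes_mod.MIN_GENE_PROPORTION,
    "recurrent_prevalence": power.RECURRENT_PREVALENCE,
}


@dataclass
class RunConfig:
    """Inputs, switches and output location for one pipeline run."""

    segments: str
    metadata: str
    outdir: str
    arms: str = "hg19"  # path to an arm TSV, or "hg19" for the bundled autosomes
    genes: str | None = None  # BED-like gene annotation
    gene_sets: str | None = None  # GMT
    cancer_genes: str | None = None  # one-column gene list
    prevalence_table: str | None = None  # tumor_type / arm / prevalence TSV
    seed: int = 0
    enforce_purity: bool = True
    min_pairs_per_cohort: int = pairing.MIN_PAIRS_PER_COHORT
    min_arm_bins: int = threshold.MIN_ARM_BINS
    one_based_inclusive: bool = False

    def __post_init__(self):
        if self.min_pairs_per_cohort != pairing.MIN_PAIRS_PER_COHORT:
            logger.warning(
                "min_pairs_per_cohort overridden to %d (default %d)",
                self.min_pairs_per_cohort, pairing.MIN_PAIRS_PER_COHORT,
            )
        if self.min_arm_bins != threshold.MIN_ARM_BINS:
            logger.warning(
                "min_arm_bins overridden to %d (default %d)",
                self.min_arm_bins, threshold.MIN_ARM_BINS,
            )


@dataclass
class ReportBundle:
    """In-memory results mirror of the written TSVs."""

    pairs: pd.DataFrame
    cohort_summary: pd.DataFrame
    trios: pd.DataFrame
    passage_strata: pd.DataFrame
    gene_prevalence: pd.DataFrame
    enrichment: pd.DataFrame
    power_table: pd.DataFrame
    excluded_samples: pd.DataFrame
    manifest: dict
    stats: dict = field(default_factory=dict)


def _pair_rows(pairs, results) -> pd.DataFrame:
    rows = []
    for pair, pd_res in zip(pairs, results):
        rows.append(
            {
                "sample_a": pair.sample_a,
                "sample_b": pair.sample_b,
                "cohort": pair.cohort,
                "model_id": pair.model_id,
                "comparison_type": pair.comparison_type,
                "passage_diff": pair.passage_diff,
                "n_evaluable_bins": pd_res.n_evaluable_bins,
                "fraction_discordant": pd_res.fraction_discordant,
                "n_discordant_arms": pd_res.n_discordant_arms,
                "discordant_arms": ";".join(
                    f"{c}{a}:{d}" for c, a, d in pd_res.discordant_arms
                ),
            }
        )
    return pd.DataFrame(rows)


def compute_pair_results(pairs, binned, grid, min_arm_bins=threshold.MIN_ARM_BINS):
    """Threshold discordance for every pair whose two samples survived filtering."""
    kept, results = [], []
    for pair in pairs:
        if pair.sample_a not in binned or pair.sample_b not in binned:
            continue
        res = threshold.pair_discordance(
            binned[pair.sample_a], binned[pair.sample_b], grid,
            comparison_type=pair.comparison_type,
            enforce_purity=False,  # purity filtering already applied sample-wise
            min_arm_bins=min_arm_bins,
        )
        kept.append(pair)
        results.append(res)
    return kept, results


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    os.makedirs(cfg.outdir, exist_ok=True)
    arms = load_hg19_arms() if cfg.arms == "hg19" else read_arm_table(cfg.arms)
    grid = build_bin_grid(arms)
    segments = read_segments(cfg.segments, one_based_inclusive=cfg.one_based_inclusive)
    meta = read_sample_metadata(cfg.metadata)
    binned = bin_samples(segments, grid, meta)

    excluded = []
    if cfg.enforce_purity:
        for sid in list(binned):
            if not threshold.purity_pass(binned[sid]):
                excluded.append({"sample_id": sid, "reason": "low_purity"})
                del binned[sid]
    excluded_df = pd.DataFrame(excluded, columns=["sample_id", "reason"])
    meta = meta[meta["sample_id"].isin(binned)].reset_index(drop=True)

    all_pairs = pairing.build_pt_pdx_pairs(meta) + pairing.build_pdx_pdx_pairs(meta)
    kept_pairs, results = compute_pair_results(
        all_pairs, binned, grid, min_arm_bins=cfg.min_arm_bins
    )
    pairs_df = _pair_rows(kept_pairs, results)
    if len(pairs_df):
        pairs_df = pairing.filter_cohorts(pairs_df, min_pairs=cfg.min_pairs_per_cohort)
    cohort_summary = (
        pairing.summarize_cohort(pairs_df) if len(pairs_df) else pd.DataFrame()
    )

    # passage-difference strata on minimum-passage PDX chains
    min_pairs = pairing.build_min_passage_pairs(meta)
    mp_kept, mp_results = compute_pair_results(
        min_pairs, binned, grid, min_arm_bins=cfg.min_arm_bins
    )
    mp_df = _pair_rows(mp_kept, mp_results)
    strata_df = pd.DataFrame()
    if len(mp_df):
        mp_df["stratum"] = mp_df["passage_diff"].map(pairing.passage_diff_group)
        groups = {
            g: grp["fraction_discordant"].to_numpy()
            for g, grp in mp_df.groupby("stratum")
            if len(grp) >= 2
        }
        if len(groups) >= 2:
            strata_df = pairing.compare_passage_groups(groups)

    # trios: PT vs earliest and latest passage
    trio_rows = []
    for trio in pairing.build_trios(meta):
        if not {trio.pt, trio.early_pdx, trio.late_pdx} <= set(binned):
            continue
        early = threshold.pair_discordance(
            binned[trio.pt], binned[trio.early_pdx], grid,
            enforce_purity=False, min_arm_bins=cfg.min_arm_bins,
        )
        late = threshold.pair_discordance(
            binned[trio.pt], binned[trio.late_pdx], grid,
            enforce_purity=False, min_arm_bins=cfg.min_arm_bins,
        )
        trio_rows.append(
            {
                "cohort": trio.cohort, "model_id": trio.model_id, "pt": trio.pt,
                "early_passage": trio.early_passage, "late_passage": trio.late_passage,
                "pt_vs_early": early.fraction_discordant,
                "pt_vs_late": late.fraction_discordant,
            }
        )
    trios_df = pd.DataFrame(trio_rows)
    stats: dict = {}
    if len(trios_df) >= 2:
        try:
            stats["trio_signed_rank"] = pairing.trio_signed_rank(trios_df)
        except ValueError as exc:  # all-zero differences on degenerate input
            logger.warning("trio test skipped: %s", exc)

    # PT CNA burden vs PT-PDX discordance
    pt_pdx = pairs_df[pairs_df["comparison_type"] == pairing.PT_PDX] if len(pairs_df) else pd.DataFrame()
    if len(pt_pdx) >= 3:
        burden = np.array(
            [threshold.genome_altered_fraction(binned[s]) for s in pt_pdx["sample_a"]]
        )
        frac = pt_pdx["fraction_discordant"].to_numpy()
        if burden.std() > 0 and frac.std() > 0:  # correlation undefined otherwise
            stats["pt_burden_correlation"] = pairing.pt_burden_correlation(burden, frac)

    # gene-level analysis per cohort on PT-PDX pairs
    gene_prev_df = pd.DataFrame()
    enrichment_df = pd.DataFrame()
    if cfg.genes is not None:
        if not os.path.exists(cfg.genes):
            raise FileNotFoundError(f"gene annotation not found: {cfg.genes}")
        gene_bed = genes_mod.read_gene_bed(cfg.genes)
        gene_sets = None
        if cfg.gene_sets is not None:
            if not os.path.exists(cfg.gene_sets):
                raise FileNotFoundError(f"gene-set file not found: {cfg.gene_sets}")
            gene_sets = genes_mod.read_gmt(cfg.gene_sets)
        by_cohort = {}
        enr_frames = []
        for cohort in pt_pdx["cohort"].unique() if len(pt_pdx) else []:
            idx = [
                i for i, p in enumerate(kept_pairs)
                if p.cohort == cohort and p.comparison_type == pairing.PT_PDX
            ]
            prev = genes_mod.bin_prevalence([results[i] for i in idx], grid)
            gp = genes_mod.project_to_genes(prev, gene_bed, grid)
            by_cohort[cohort] = gp
            if gene_sets:
                selected = genes_mod.select_discordant_genes(gp)
                if selected:
                    enr = genes_mod.hallmark_enrichment(selected, gene_sets)
                    enr.insert(0, "cohort", cohort)
                    enr_frames.append(enr)
                else:
                    logger.info("cohort %s: no genes pass selection; excluded", cohort)
        if by_cohort:
            gene_prev_df = pd.DataFrame(by_cohort)
            gene_prev_df.index.name = "gene_id"
        if enr_frames:
            enrichment_df = pd.concat(enr_frames, ignore_index=True)
        if len(gene_prev_df):
            cgc = (
                genes_mod.read_gene_list(cfg.cancer_genes)
                if cfg.cancer_genes
                else None
            )
            stats["recurrent_genes"] = genes_mod.recurrent_cancer_genes(
                gene_prev_df, cancer_genes=cgc
            ).to_dict(orient="records")

    # power analysis: cohorts stand in for tumor types
    power_df = pd.DataFrame()
    if cfg.prevalence_table is not None:
        prev_table = power.read_prevalence_table(cfg.prevalence_table)
        n_avail = (
            pt_pdx.groupby("cohort")["sample_a"].size().to_dict() if len(pt_pdx) else {}
        )
        power_df = power.power_table(prev_table, n_avail)
        if len(power_df):
            stats["power_summary"] = power.powered_fraction(power_df)

    manifest = {
        "seed": cfg.seed,
        "thresholds": METHOD_DEFAULTS,
        "config": {k: v for k, v in asdict(cfg).items()},
        "n_samples_binned": len(binned),
        "n_samples_excluded": len(excluded_df),
        "n_pairs": int(len(pairs_df)),
        "stats": _jsonable(stats),
    }

    bundle = ReportBundle(
        pairs=pairs_df, cohort_summary=cohort_summary, trios=trios_df,
        passage_strata=strata_df, gene_prevalence=gene_prev_df,
        enrichment=enrichment_df, power_table=power_df,
        excluded_samples=excluded_df, manifest=manifest, stats=stats,
    )
    _write_bundle(bundle, cfg.outdir)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else str(f)
    return obj


def _write_bundle(bundle: ReportBundle, outdir: str) -> None:
    tables = {
        "pairs.tsv": bundle.pairs,
        "cohort_summary.tsv": bundle.cohort_summary,
        "trios.tsv": bundle.trios,
        "passage_strata.tsv": bundle.passage_strata,
        "gene_prevalence.tsv": bundle.gene_prevalence,
        "enrichment.tsv": bundle.enrichment,
        "power.tsv": bundle.power_table,
        "excluded_samples.tsv": bundle.excluded_samples,
    }
    for name, df in tables.items():
        path = os.path.join(outdir, name)
        index = name == "gene_prevalence.tsv"
        df.to_csv(path, sep="\t", index=index)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
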