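"""Gene-level discordance prevalence and gene-set over-representation.

Per cohort, each 1 Mb bin gets the proportion of pairs discordant at
that bin; genes inherit the unweighted mean proportion of the bins they
overlap (masked bins ignored). The most discordant genes — the top 2.5%
by proportion, intersected with proportion > 0.25 — are tested for
over-representation in hallmark-style gene sets with a hypergeometric
test, Benjamini-Hochberg corrected across sets, alongside an
enrichment score

    ES = log( (x/N) / (g/G) )

where x of the N selected genes fall in a set of size g drawn from a
universe of G genes (the union of all sets); the natural log is used,
so ES > 0 marks over- and ES < 0 under-representation. An empty
intersection (x = 0) is reported as ES = -inf with p = 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import BinGrid
from .threshold import BinStatus, PairDiscordance

logger = logging.getLogger(__name__)

TOP_GENE_QUANTILE = 0.025
MIN_GENE_PROPORTION = 0.25
RECURRENT_PT_PDX_PROPORTION = 0.25
RECURRENT_EARLY_LATE_PROPORTION = 0.10
MIN_RECURRENT_COHORTS = 5


class GeneAnalysisError(ValueError):
    pass


def read_gene_bed(path) -> pd.DataFrame:
    """BED-like gene annotation: chromosome, start, end, gene_id (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str},
    )
    if (df["start"] >= df["end"]).any():
        raise GeneAnalysisError("gene intervals with start >= end")
    return df


def read_gmt(path) -> dict[str, set]:
    """GMT gene-set file: set name, description, then member genes per line."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    if not sets:
        raise GeneAnalysisError(f"no gene sets parsed from {path}")
    return sets


def read_gene_list(path) -> list[str]:
    """One-column gene list (e.g. a cancer-gene-census export)."""
    with open(path) as fh:
        genes = [ln.strip() for ln in fh if ln.strip()]
    return genes


def bin_prevalence(pairs: list[PairDiscordance], grid: BinGrid) -> pd.DataFrame:
    """Per-bin proportion of pairs discordant at that bin.

    Returns a frame aligned to the grid with columns ``proportion``
    (NaN where no pair was evaluable) and ``n_pairs_evaluable``.
    """
    if not pairs:
        raise GeneAnalysisError("no pairs supplied")
    n = grid.n_bins
    n_eval = np.zeros(n, dtype=int)
    n_disc = np.zeros(n, dtype=int)
    for p in pairs:
        ev = p.bin_status != BinStatus.NOT_EVALUABLE
        n_eval += ev
        n_disc += ev & (p.bin_status != BinStatus.CONCORDANT)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n_eval > 0, n_disc / np.maximum(n_eval, 1), np.nan)
    out = grid.to_frame()
    out["proportion"] = prop
    out["n_pairs_evaluable"] = n_eval
    return out


def project_to_genes(prevalence: pd.DataFrame, genes: pd.DataFrame,
                     grid: BinGrid) -> pd.Series:
    """Gene-level discordance proportion: mean over the gene's overlapping bins.

    Bins with no evaluable pair are ignored; a gene overlapping only
    such bins gets no value and is dropped.
    """
    prop = prevalence["proportion"].to_numpy(dtype=float)
    w = grid.bin_width
    values = {}
    for row in genes.itertuples(index=False):
        try:
            lo, hi = grid.chrom_range(row.chromosome)
        except KeyError:
            continue
        first = lo + max(0, int(row.start) // w)
        last = min(hi, lo + int(np.ceil(int(row.end) / w)))
        if first >= last:
            continue
        vals = prop[first:last]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            values[row.gene_id] = float(vals.mean())
    return pd.Series(values, name="proportion", dtype=float)


def select_discordant_genes(
    gene_prevalence: pd.Series,
    top_quantile: float = TOP_GENE_QUANTILE,
    min_proportion: float = MIN_GENE_PROPORTION,
) -> list[str]:
    """Top 2.5% most discordant genes (ties at the cut kept) with proportion > 0.25.

    Returns an empty list when no gene clears ``min_proportion`` — the
    cohort is then excluded from enrichment.
    """
    if len(gene_prevalence) == 0:
        return []
    cut = float(gene_prevalence.quantile(1 - top_quantile))
    selected = gene_prevalence[
        (gene_prevalence >= cut) & (gene_prevalence > min_proportion)
    ]
    return sorted(selected.index)


def hallmark_enrichment(selected: list[str], gene_sets: dict[str, set]) -> pd.DataFrame:
    """Hypergeometric over-representation of selected genes per gene set.

    The universe G is the union of all set members. N is the number of
    selected genes (clipped to G with a warning if some selected genes
    fall outside the universe, since the sampling model cannot draw
    more than the population).
    """
    if not selected:
        raise GeneAnalysisError("empty gene selection")
    if not gene_sets:
        raise GeneAnalysisError("empty gene-set collection")
    universe = set().union(*gene_sets.values())
    G = len(universe)
    sel = set(selected)
    outside = sel - universe
    if outside:
        logger.warning(
            "%d selected genes outside the gene-set universe", len(outside)
        )
    N = min(len(sel), G)
    rows = []
    for name, members in sorted(gene_sets.items()):
        g = len(members)
        x = len(sel & members)
        if x > 0:
            es = float(np.log((x / len(sel)) / (g / G)))
            p = float(stats.hypergeom.sf(x - 1, G, g, N))
        else:
            es = -np.inf
            p = 1.0
        rows.append(
            {"gene_set": name, "x": x, "n_selected": len(sel),
             "set_size": g, "universe_size": G, "es": es, "p_value": p}
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def recurrent_cancer_genes(
    gene_prevalence_by_cohort: pd.DataFrame,
    cancer_genes: list[str] | None = None,
    proportion_threshold: float = RECURRENT_PT_PDX_PROPORTION,
    min_cohorts: int = MIN_RECURRENT_COHORTS,
) -> pd.DataFrame:
    """Genes commonly discordant across cohorts.

    ``gene_prevalence_by_cohort`` is genes x cohorts (NaN allowed). A
    gene is flagged per cohort when its proportion exceeds
    ``proportion_threshold`` (0.25 for PT-PDX, 0.10 for early-vs-late
    comparisons) and reported when flagged in at least ``min_cohorts``
    cohorts; optionally restricted to a curated cancer-gene list.
    """
    df = gene_prevalence_by_cohort
    if cancer_genes is not None:
        df = df.loc[df.index.intersection(cancer_genes)]
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "n_cohorts", "cohorts"])
    hits = df > proportion_threshold
    counts = hits.sum(axis=1)
    keep = counts[counts >= min_cohorts].sort_values(ascending=False)
    rows = [
        {
            "gene_id": gene,
            "n_cohorts": int(n),
            "cohorts": ",".join(sorted(df.columns[hits.loc[gene]])),
        }
        for gene, n in keep.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "n_cohorts", "cohorts"])
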