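"""Comparison sets, cohort aggregation and group statistics.

Pairing scheme: within each model, every primary tumor (PT) is compared
to each of its xenografts (PDXs), and every PDX to every other PDX of
the same model at a different passage. For passage-resolution analyses,
each PDX is paired with the later-passage PDX at the minimum possible
passage difference, and models carrying a PT plus PDXs at two or more
passages yield "trios" contrasting PT-vs-earliest against PT-vs-latest.
Cohorts contribute a comparison type only when they have at least five
pairs of that type.

Group statistics are the field's standard nonparametric tests, called
from scipy rather than re-derived: Mann-Whitney U between
passage-difference strata, a one-sided Wilcoxon signed-rank test on
trios, and Pearson correlation between a PT's CNA burden and its
pair's discordance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MIN_PAIRS_PER_COHORT = 5

PT_PDX = "PT_PDX"
PDX_PDX = "PDX_PDX"


@dataclass(frozen=True)
class SamplePair:
    sample_a: str
    sample_b: str
    cohort: str
    model_id: str
    comparison_type: str
    passage_diff: int | None = None

    def key(self) -> tuple:
        return (self.cohort, self.model_id, *sorted((self.sample_a, self.sample_b)))


def _models(meta: pd.DataFrame):
    return meta.groupby(["cohort", "model_id"], sort=True)


def build_pt_pdx_pairs(meta: pd.DataFrame) -> list[SamplePair]:
    """Cartesian PT x PDX within each model."""
    pairs = []
    for (cohort, model), grp in _models(meta):
        pts = grp[grp["role"] == "PT"]
        pdxs = grp[grp["role"] == "PDX"]
        for pt in pts.itertuples(index=False):
            for pdx in pdxs.itertuples(index=False):
                pairs.append(
                    SamplePair(pt.sample_id, pdx.sample_id, cohort, model, PT_PDX)
                )
    return pairs


def build_pdx_pdx_pairs(meta: pd.DataFrame) -> list[SamplePair]:
    """All unordered PDX pairs within a model with unequal passage numbers."""
    pairs = []
    for (cohort, model), grp in _models(meta):
        pdxs = list(grp[grp["role"] == "PDX"].itertuples(index=False))
        for s1, s2 in itertools.combinations(pdxs, 2):
            if s1.passage == s2.passage:
                continue
            a, b = (s1, s2) if s1.passage < s2.passage else (s2, s1)
            pairs.append(
                SamplePair(
                    a.sample_id, b.sample_id, cohort, model, PDX_PDX,
                    passage_diff=int(abs(s1.passage - s2.passage)),
                )
            )
    return pairs


def build_min_passage_pairs(meta: pd.DataFrame) -> list[SamplePair]:
    """Each PDX paired with later-passage PDX(s) at the minimum passage difference.

    Ties (several later samples equally close) keep all tied partners;
    a PDX with no later-passage partner contributes no pair.
    """
    pairs = []
    seen = set()
    for (cohort, model), grp in _models(meta):
        pdxs = list(grp[grp["role"] == "PDX"].itertuples(index=False))
        for s in pdxs:
            later = [o for o in pdxs if o.passage > s.passage]
            if not later:
                continue
            dmin = min(o.passage - s.passage for o in later)
            for o in later:
                if o.passage - s.passage == dmin:
                    p = SamplePair(
                        s.sample_id, o.sample_id, cohort, model, PDX_PDX,
                        passage_diff=int(dmin),
                    )
                    if p.key() not in seen:
                        seen.add(p.key())
                        pairs.append(p)
    return pairs


def passage_diff_group(d: int) -> str:
    """Stratify a passage difference: 1-2 low, 3-5 intermediate, >=6 high."""
    if d < 1:
        raise ValueError("passage difference must be >= 1")
    if d <= 2:
        return "low"
    if d <= 5:
        return "intermediate"
    return "high"


@dataclass(frozen=True)
class Trio:
    cohort: str
    model_id: str
    pt: str
    early_pdx: str
    late_pdx: str
    early_passage: int
    late_passage: int


def build_trios(meta: pd.DataFrame) -> list[Trio]:
    """One trio per PT in models with PDXs at >=2 distinct passages.

    When more than two passages exist, the earliest- and latest-passage
    PDXs are used (maximum contrast); replicate PDXs at the chosen
    passage resolve to the lexicographically first sample id.
    """
    trios = []
    for (cohort, model), grp in _models(meta):
        pts = grp[grp["role"] == "PT"]
        pdxs = grp[grp["role"] == "PDX"].sort_values(["passage", "sample_id"])
        if len(pts) == 0 or pdxs["passage"].nunique() < 2:
            continue
        early = pdxs.iloc[0]
        late = pdxs.iloc[-1]
        for pt in pts.itertuples(index=False):
            trios.append(
                Trio(
                    cohort, model, pt.sample_id,
                    early.sample_id, late.sample_id,
                    int(early.passage), int(late.passage),
                )
            )
    return trios


def filter_cohorts(
    pairs_df: pd.DataFrame, min_pairs: int = MIN_PAIRS_PER_COHORT
) -> pd.DataFrame:
    """Drop (cohort, comparison_type) groups with fewer than ``min_pairs`` pairs."""
    counts = pairs_df.groupby(["cohort", "comparison_type"])["sample_a"].transform("size")
    return pairs_df[counts >= min_pairs].reset_index(drop=True)


DEFAULT_EXCEEDANCE_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


def summarize_cohort(
    pairs_df: pd.DataFrame,
    thresholds=DEFAULT_EXCEEDANCE_THRESHOLDS,
) -> pd.DataFrame:
    """Per-(cohort, comparison_type) summary of pair-level discordance.

    ``pairs_df`` needs columns cohort, comparison_type,
    fraction_discordant and (optionally) n_discordant_arms. Returns one
    row per group with median/mean/range, quartile box statistics
    (whiskers at Q1 - 1.5 IQR and Q3 + 1.5 IQR) and an exceedance table:
    for each threshold t, the fraction of pairs with
    fraction_discordant > t (a 1 - eCDF).
    """
    rows = []
    for (cohort, ctype), grp in pairs_df.groupby(["cohort", "comparison_type"]):
        f = grp["fraction_discordant"].to_numpy(dtype=float)
        q1, q3 = np.percentile(f, [25, 75])
        iqr = q3 - q1
        row = {
            "cohort": cohort,
            "comparison_type": ctype,
            "n_pairs": len(f),
            "median_fraction": float(np.median(f)),
            "mean_fraction": float(np.mean(f)),
            "min_fraction": float(f.min()),
            "max_fraction": float(f.max()),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(q1 - 1.5 * iqr),
            "whisker_high": float(q3 + 1.5 * iqr),
        }
        if "n_discordant_arms" in grp:
            row["median_arms"] = float(grp["n_discordant_arms"].median())
        for t in thresholds:
            row[f"exceed_{t:g}"] = float((f > t).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def exceedance(fractions, thresholds=DEFAULT_EXCEEDANCE_THRESHOLDS) -> pd.Series:
    """1 - eCDF of pair discordance fractions at the given thresholds."""
    f = np.asarray(fractions, dtype=float)
    return pd.Series({t: float((f > t).mean()) for t in thresholds})


def compare_passage_groups(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests between passage-difference strata."""
    names = list(groups)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        a, b = np.asarray(groups[g1]), np.asarray(groups[g2])
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"groups {g1}/{g2} too small for a rank test")
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "group_a": g1, "group_b": g2, "n_a": len(a), "n_b": len(b),
                "median_a": float(np.median(a)), "median_b": float(np.median(b)),
                "U": float(u), "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def trio_signed_rank(trios_df: pd.DataFrame) -> dict:
    """One-sided Wilcoxon signed-rank test: PT-vs-late > PT-vs-early.

    ``trios_df`` needs columns pt_vs_early and pt_vs_late (discordance
    fractions per model).
    """
    early = trios_df["pt_vs_early"].to_numpy(dtype=float)
    late = trios_df["pt_vs_late"].to_numpy(dtype=float)
    if len(early) < 2:
        raise ValueError("need at least two trios")
    res = stats.wilcoxon(late, early, alternative="greater")
    return {
        "n": len(early),
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_early": float(np.median(early)),
        "median_late": float(np.median(late)),
    }


def pt_burden_correlation(pt_altered_fraction, pair_fraction) -> dict:
    """Pearson correlation of PT CNA burden with PT-PDX discordance."""
    r, p = stats.pearsonr(
        np.asarray(pt_altered_fraction, dtype=float),
        np.asarray(pair_fraction, dtype=float),
    )
    return {"r": float(r), "p_value": float(p), "n": len(np.asarray(pair_fraction))}
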