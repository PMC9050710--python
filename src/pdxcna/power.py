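"""Sample-size power analysis for detecting prevalence decreases of
recurrent arm-level aneuploidies.

Given a baseline prevalence p0 of an arm-level alteration in patient
tumors of one tumor type (recurrent means p0 > 0.25), the minimum
number of PT-PDX comparisons needed to detect a 10% absolute decrease
(p = p0 - 0.1) with a one-sided one-sample proportion test at
significance alpha = 0.05 and power 1 - beta = 0.8 is

    n = p0 (1 - p0) * ( (z_{1-a} + z_{1-b} sqrt(p(1-p) / (p0(1-p0)))) / (p - p0) )^2

rounded up. A (tumor type, arm) row is powered when the available
number of comparisons reaches that n; the headline summary is the
fraction of recurrent aneuploidies that are *under*powered.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

RECURRENT_PREVALENCE = 0.25
PREVALENCE_DECREASE = 0.1
ALPHA = 0.05
BETA = 0.2


class PowerAnalysisError(ValueError):
    pass


def recurrent_arms(
    prevalence: pd.DataFrame, threshold: float = RECURRENT_PREVALENCE
) -> pd.DataFrame:
    """Rows of a (tumor_type, arm, prevalence) table with prevalence strictly above 0.25."""
    for col in ("tumor_type", "arm", "prevalence"):
        if col not in prevalence.columns:
            raise PowerAnalysisError(f"prevalence table missing column {col!r}")
    return prevalence[prevalence["prevalence"] > threshold].reset_index(drop=True)


def required_n(
    p0: float,
    decrease: float = PREVALENCE_DECREASE,
    alpha: float = ALPHA,
    beta: float = BETA,
) -> int:
    """Minimum sample size to detect an absolute prevalence decrease.

    One-sided one-sample proportion test; the non-integer solution is
    rounded up (sample sizes are integers, and rounding up is the
    conservative direction).
    """
    if not decrease < p0 < 1:
        raise PowerAnalysisError(
            f"p0 must lie in ({decrease}, 1) so the decreased prevalence is positive"
        )
    p = p0 - decrease
    z_a = stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(1 - beta)
    ratio = math.sqrt(p * (1 - p) / (p0 * (1 - p0)))
    n = p0 * (1 - p0) * ((z_a + z_b * ratio) / (p - p0)) ** 2
    return int(math.ceil(n))


def power_table(
    prevalence: pd.DataFrame,
    n_available: dict[str, int] | pd.Series,
    threshold: float = RECURRENT_PREVALENCE,
    decrease: float = PREVALENCE_DECREASE,
    alpha: float = ALPHA,
    beta: float = BETA,
) -> pd.DataFrame:
    """Per-(tumor_type, arm) power assessment against available pair counts.

    ``n_available`` maps tumor type to the number of PT-PDX comparisons
    in hand; missing tumor types count as zero.
    """
    rec = recurrent_arms(prevalence, threshold=threshold)
    avail = pd.Series(n_available, dtype=float)
    rows = []
    for row in rec.itertuples(index=False):
        p0 = float(row.prevalence)
        n_req = required_n(p0, decrease=decrease, alpha=alpha, beta=beta)
        n_have = int(avail.get(row.tumor_type, 0))
        rows.append(
            {
                "tumor_type": row.tumor_type,
                "arm": row.arm,
                "p0": p0,
                "p": p0 - decrease,
                "alpha": alpha,
                "beta": beta,
                "n_required": n_req,
                "n_available": n_have,
                "powered": n_have >= n_req,
            }
        )
    return pd.DataFrame(rows)


def powered_fraction(power_rows: pd.DataFrame) -> dict:
    """Summary: share of recurrent aneuploidies the dataset is underpowered for."""
    if len(power_rows) == 0:
        raise PowerAnalysisError("empty power table")
    under = ~power_rows["powered"].astype(bool)
    return {
        "n_arms": int(len(power_rows)),
        "n_underpowered": int(under.sum()),
        "fraction_underpowered": float(under.mean()),
    }


def read_prevalence_table(path) -> pd.DataFrame:
    """TSV of tumor_type, arm, prevalence (e.g. pan-cancer aneuploidy prevalences)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("tumor_type", "arm", "prevalence"):
        if col not in df.columns:
            raise PowerAnalysisError(f"prevalence table missing column {col!r}")
    if ((df["prevalence"] < 0) | (df["prevalence"] > 1)).any():
        raise PowerAnalysisError("prevalence values outside [0,1]")
    return df
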