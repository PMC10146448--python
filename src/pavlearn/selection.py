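"""Model comparison across subjects: AIC tables, Friedman and Wilcoxon tests.

The per-subject, per-valence summed AICs of competing learning models form a
subjects x models table; a Friedman rank test asks whether the models differ,
and pairwise Wilcoxon signed-rank tests (Bonferroni-corrected) identify which
pairs drive the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined on the given data."""


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float


@dataclass
class WilcoxonResult:
    stat: float
    p: float
    n_used: int
    method: str


def friedman_test(table: pd.DataFrame | np.ndarray) -> FriedmanResult:
    """Friedman rank test over a subjects (rows) x models (columns) table.

    Mid-ranks within each row with the standard tie correction; the statistic
    is referred to a chi-square distribution with k - 1 df.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 models")
    if not np.all(np.isfinite(arr)):
        raise ValueError("AIC table contains non-finite values")
    if all(len(np.unique(row)) == 1 for row in arr):
        raise DegenerateDataError("every row is constant; Friedman statistic undefined")
    chi2, p = scipy.stats.friedmanchisquare(*arr.T)
    return FriedmanResult(chi2=float(chi2), df=arr.shape[1] - 1, p=float(p))


def wilcoxon_signed_rank(x, y, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; the exact null distribution is used for
    n <= ``exact_max_n`` untied pairs, otherwise the normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return WilcoxonResult(stat=float(res.statistic), p=float(res.pvalue), n_used=n, method=method)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjust a p value for a family of m tests (capped at 1)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p)


def compare_models(aic_table: pd.DataFrame, reference: str = "rw") -> pd.DataFrame:
    """Omnibus Friedman test plus reference-vs-other Wilcoxon post hocs.

    Parameters
    ----------
    aic_table:
        Subjects x models table of summed AICs (one valence at a time).
    reference:
        Model compared pairwise against every other column; the Bonferroni
        family is the number of such pairs.

    Returns a tidy report with one 'friedman' row and one row per pair.
    """
    models = list(aic_table.columns)
    if reference not in models:
        raise ValueError(f"reference model {reference!r} not in table columns {models}")
    fr = friedman_test(aic_table)
    rows = [
        {
            "comparison": "friedman",
            "stat": fr.chi2,
            "df": fr.df,
            "p": fr.p,
            "p_adjusted": np.nan,
        }
    ]
    others = [m for m in models if m != reference]
    m_family = len(others)
    for other in others:
        w = wilcoxon_signed_rank(aic_table[reference], aic_table[other])
        rows.append(
            {
                "comparison": f"{reference}-{other}",
                "stat": w.stat,
                "df": w.n_used,
                "p": w.p,
                "p_adjusted": bonferroni(w.p, m_family),
            }
        )
    return pd.DataFrame(rows)
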