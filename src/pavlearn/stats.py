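"""Group-level inference: accuracy vs chance, ROI t tests, 2x2 repeated-measures
ANOVA (PE type x learning type), and Pearson trait correlations.

All tests are two-sided; directional readings are carried by the sign of the
statistic.  The Bonferroni family for the ROI one-sample t tests is the number
of ROIs (4 by default), applied within each condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .selection import DegenerateDataError, bonferroni
from .task import SessionRecord

ROIS = ("L_CMA", "R_CMA", "L_BLA", "R_BLA")
CONDITIONS = ("negPE_app", "posPE_app", "negPE_av", "posPE_av")

TREND_THRESHOLD = 0.1


@dataclass
class TTestResult:
    mean: float
    t: float
    df: int
    p: float


def one_sample_t(values: Sequence[float], popmean: float = 0.0) -> TTestResult:
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 observations")
    if np.allclose(x, x[0]):
        raise DegenerateDataError("zero variance; t statistic undefined")
    t, p = scipy.stats.ttest_1samp(x, popmean)
    return TTestResult(mean=float(x.mean()), t=float(t), df=len(x) - 1, p=float(p))


def accuracy_vs_chance(
    sessions_by_condition: Mapping[str, Sequence[Sequence[SessionRecord]]],
) -> pd.DataFrame:
    """One-sample t tests of correct-response ratios against chance (0.5).

    ``sessions_by_condition`` maps a condition label to a list of per-subject
    session lists; sessions of one subject are pooled before the ratio is
    formed.  Returns one row per condition with mean ratio, t, df and p.
    """
    rows = []
    for cond, per_subject in sessions_by_condition.items():
        ratios = []
        for sessions in per_subject:
            n_corr = sum(s.n_correct for s in sessions)
            n_valid = sum(
                sum(t.response != "missed" for t in s.trials) for s in sessions
            )
            ratios.append(n_corr / n_valid if n_valid else np.nan)
        res = one_sample_t(ratios, popmean=0.5)
        rows.append(
            {"condition": cond, "mean_ratio": res.mean, "t": res.t, "df": res.df, "p": res.p}
        )
    return pd.DataFrame(rows)


def roi_ttests(betas: pd.DataFrame, n_rois: int | None = None) -> pd.DataFrame:
    """One-sample t test of each (ROI, condition) beta column against zero.

    Column names are ``"<roi>:<condition>"``.  p values are Bonferroni
    corrected for the number of ROIs (the family is the ROIs within one
    condition, not the conditions).
    """
    if n_rois is None:
        n_rois = len({c.split(":")[0] for c in betas.columns})
    rows = []
    for col in betas.columns:
        roi, _, cond = col.partition(":")
        res = one_sample_t(betas[col].to_numpy())
        rows.append(
            {
                "roi": roi,
                "condition": cond,
                "mean_beta": res.mean,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "p_adjusted": bonferroni(res.p, n_rois),
            }
        )
    return pd.DataFrame(rows)


def rm_anova_2x2(cells: pd.DataFrame) -> pd.DataFrame:
    """Two-by-two fully-within repeated-measures ANOVA.

    ``cells`` has one row per subject and exactly four columns ordered as
    (A1B1, A1B2, A2B1, A2B2) — e.g. (negPE_app, negPE_av, posPE_app,
    posPE_av) for factors PE type (A) and learning type (B).  Each effect has
    1 numerator df, so its F equals the squared paired t of the corresponding
    within-subject contrast; subjects with missing cells are dropped.
    """
    if cells.shape[1] != 4:
        raise ValueError("need exactly 4 cell columns (A1B1, A1B2, A2B1, A2B2)")
    data = cells.dropna(axis=0)
    n_dropped = len(cells) - len(data)
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} subjects with missing cells")
    n = len(data)
    if n < 3:
        raise ValueError("need >= 3 complete subjects")
    a1b1, a1b2, a2b1, a2b2 = (data.iloc[:, j].to_numpy(dtype=float) for j in range(4))

    contrasts = {
        "A": (a1b1 + a1b2 - a2b1 - a2b2) / 2.0,
        "B": (a1b1 - a1b2 + a2b1 - a2b2) / 2.0,
        "AxB": a1b1 - a1b2 - a2b1 + a2b2,
    }
    rows = []
    for effect, c in contrasts.items():
        if np.allclose(c, c[0]) and np.allclose(c[0], 0.0):
            rows.append(
                {"effect": effect, "F": np.nan, "df1": 1, "df2": n - 1, "p": np.nan,
                 "note": "no variance"}
            )
            continue
        if np.allclose(c, c[0]):
            raise DegenerateDataError(f"constant nonzero contrast for effect {effect}")
        t, p = scipy.stats.ttest_1samp(c, 0.0)
        rows.append(
            {"effect": effect, "F": float(t) ** 2, "df1": 1, "df2": n - 1,
             "p": float(p), "note": ""}
        )
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def trait_correlation(betas: Sequence[float], trait: Sequence[float]) -> CorrelationResult:
    """Pearson correlation between ROI betas and a trait score (two-sided)."""
    x = np.asarray(betas, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateDataError("zero variance in one of the samples")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=len(x))


def trait_correlation_report(
    betas: pd.DataFrame, covariates: pd.DataFrame, beta_columns: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pearson r between every (beta column, covariate) pair, as a tidy table."""
    if beta_columns is None:
        beta_columns = betas.columns
    rows = []
    for bcol in beta_columns:
        for trait in covariates.columns:
            res = trait_correlation(betas[bcol], covariates[trait])
            rows.append({"beta": bcol, "trait": trait, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
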