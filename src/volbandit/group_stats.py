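"""Group-level statistics: mixed ANOVA, t-tests, CIs and correlations.

Deliberately thin wrappers around pingouin / scipy so the full analysis
pipeline (learning rates -> condition x group ANOVA, slope ANOVAs, contrast
CIs, covariate correlations) runs end-to-end; contracts are pinned by
fixture tests against hand-computed values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

# Welch correction kicks in automatically above this sample-variance ratio.
WELCH_VARIANCE_RATIO = 2.0


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    between: str,
    subject: str = "subject",
) -> pd.DataFrame:
    """Two-way mixed ANOVA; returns F, df, p and partial eta-squared per term."""
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} not in table")
    counts = data.groupby(subject)[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced within-factor levels across subjects")
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between, subject=subject)
    out = aov.rename(columns={"Source": "term", "p-unc": "p", "p_unc": "p"})
    # degenerate inputs (e.g. constant dv) make pingouin omit stat columns
    return out.reindex(columns=["term", "SS", "DF1", "DF2", "F", "p", "np2"])


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str = "subject") -> pd.DataFrame:
    """Fully within-subjects (repeated measures) ANOVA, one or two factors."""
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject, detailed=True)
    return aov.rename(columns={"Source": "term", "p-unc": "p", "p_unc": "p"})


def paired_ttest(x, y) -> dict:
    """Two-sided paired t-test with the 95% CI of the mean difference."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    res = stats.ttest_rel(x, y)
    d = x - y
    n = len(d)
    sem = d.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    return {
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "mean_diff": float(d.mean()),
        "ci95": (float(d.mean() - tcrit * sem), float(d.mean() + tcrit * sem)),
    }


def independent_ttest(x, y, welch: bool | None = None) -> dict:
    """Two-sample t-test; Welch correction applied automatically when the
    sample-variance ratio exceeds ``WELCH_VARIANCE_RATIO`` (or on request).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch is None:
        ratio = max(vx, vy) / min(vx, vy) if min(vx, vy) > 0 else np.inf
        welch = ratio > WELCH_VARIANCE_RATIO
    res = stats.ttest_ind(x, y, equal_var=not welch)
    nx, ny = len(x), len(y)
    if welch:
        se2x, se2y = vx / nx, vy / ny
        df = (se2x + se2y) ** 2 / (se2x**2 / (nx - 1) + se2y**2 / (ny - 1))
        se = np.sqrt(se2x + se2y)
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
    diff = x.mean() - y.mean()
    tcrit = stats.t.ppf(0.975, df)
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "welch": bool(welch),
        "mean_diff": float(diff),
        "ci95": (float(diff - tcrit * se), float(diff + tcrit * se)),
    }


def pearson_corr(x, y) -> dict:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.pearsonr(x, y)
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(x)}


def analysis_table(rates: pd.DataFrame, slopes: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per subject: group, condition-wise log alpha, delta, interval slopes.

    ``rates`` is long format with columns subject, group, condition,
    log_alpha; ``slopes`` (optional) is the long slope table.
    """
    wide = rates.pivot_table(index=["subject", "group"], columns="condition", values="log_alpha")
    wide = wide.rename(columns=lambda c: f"log_alpha_{c}").reset_index()
    if {"log_alpha_stable", "log_alpha_volatile"} <= set(wide.columns):
        wide["delta_log_alpha"] = wide["log_alpha_volatile"] - wide["log_alpha_stable"]
    if slopes is not None and len(slopes):
        sw = slopes.pivot_table(index="subject", columns="interval", values="sqrt_abs_slope")
        sw = sw.rename(columns=lambda c: f"sqrt_abs_slope_{c}").reset_index()
        wide = wide.merge(sw, on="subject", how="left")
    if wide["subject"].duplicated().any():
        raise ValueError("duplicated subject identifiers")
    return wide
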