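"""Post-switch adaptation: running averages of choices and regression slopes.

After each volatile-phase reversal of the short task (switches at trials
101, 121 and 141), the first ten values of a trailing 4-trial running
average of choices are regressed on trial index. The absolute slope is a
speed-of-adaptation measure; a square-root transform of the absolute slopes
is used for the interval ANOVA.

The running average is *trailing*: the value at trial t is the mean of the
choices on trials t-3..t, so it is defined from trial 4 onward and "trials
101-110" yields ten defined values immediately after a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
from scipy import stats

from .schedule import Schedule

SHORT_SWITCH_TRIALS = (101, 121, 141)
N_SLOPE_POINTS = 10
RUN_WINDOW = 4


@dataclass(frozen=True)
class IntervalSlope:
    interval: str  # e.g. "101-110"
    slope: float
    abs_slope: float
    sqrt_abs_slope: float


@dataclass
class SlopeResult:
    intervals: list
    missing: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.intervals])


def running_average(choices, window_len: int = RUN_WINDOW) -> np.ndarray:
    """Trailing mean of the last ``window_len`` choices.

    Returns an array aligned to trial position: entry ``t`` (0-based) is the
    mean of choices ``t-window_len+1 .. t``; the first ``window_len - 1``
    entries are NaN.
    """
    x = np.asarray(choices, dtype=float)
    if len(x) < window_len:
        raise ValueError(f"need >= {window_len} choices, got {len(x)}")
    out = np.full(len(x), np.nan)
    kernel = np.ones(window_len) / window_len
    out[window_len - 1 :] = np.convolve(x, kernel, mode="valid")
    return out


def _ols_slope(yvals: np.ndarray) -> float:
    x = np.arange(len(yvals), dtype=float)
    res = stats.linregress(x, yvals)
    return float(res.slope)


def post_switch_slopes(
    schedule: Schedule,
    switch_trials=SHORT_SWITCH_TRIALS,
    window_len: int = RUN_WINDOW,
) -> SlopeResult:
    """OLS slopes of the running average over each post-switch interval.

    The slope's sign follows the choice coding (1 = option A, the initially
    favoured option): a switch away from A produces a negative raw slope.
    """
    choices = schedule.choices
    if choices is None:
        raise ValueError("schedule has no complete choice column")
    ra = running_average(choices, window_len)
    intervals = []
    missing = []
    for s in switch_trials:
        label = f"{s}-{s + N_SLOPE_POINTS - 1}"
        seg = ra[s - 1 : s - 1 + N_SLOPE_POINTS]
        if len(seg) < N_SLOPE_POINTS or np.isnan(seg).any():
            missing.append(label)
            continue
        slope = _ols_slope(seg)
        intervals.append(
            IntervalSlope(
                interval=label,
                slope=slope,
                abs_slope=abs(slope),
                sqrt_abs_slope=float(np.sqrt(abs(slope))),
            )
        )
    if missing:
        warnings.warn(f"intervals with missing data: {missing}")
    return SlopeResult(intervals=intervals, missing=tuple(missing))


def slopes_frame(cohort_slopes: dict, groups: dict | None = None) -> pd.DataFrame:
    """Long-format table: subject, group, interval, sqrt_abs_slope, ..."""
    rows = []
    for subject, result in cohort_slopes.items():
        for s in result.intervals:
            rows.append(
                {
                    "subject": subject,
                    "group": groups.get(subject, "all") if groups else "all",
                    "interval": s.interval,
                    "slope": s.slope,
                    "abs_slope": s.abs_slope,
                    "sqrt_abs_slope": s.sqrt_abs_slope,
                }
            )
    return pd.DataFrame(rows)


def _repeated_contrast(df: pd.DataFrame, dv: str, level_a: str, level_b: str) -> dict:
    """F-test of the within-subject difference level_b - level_a.

    The per-subject difference is modeled with an effects-coded group factor;
    the intercept (unweighted grand mean of the difference) is tested against
    zero with error df = N - n_groups, matching a repeated contrast in a
    mixed-design ANOVA.
    """
    wide = df.pivot_table(index=["subject", "group"], columns="interval", values=dv)
    d = (wide[level_b] - wide[level_a]).dropna().reset_index()
    d.columns = ["subject", "group", "diff"]
    X = pd.get_dummies(d["group"], dtype=float)
    groups = list(X.columns)
    if len(groups) > 1:
        # sum-to-zero coding; intercept = unweighted mean across groups
        eff = X.iloc[:, :-1].sub(X.iloc[:, -1], axis=0)
        design = sm.add_constant(eff)
    else:
        design = sm.add_constant(pd.DataFrame(index=d.index))
    model = sm.OLS(d["diff"], design).fit()
    tval = float(model.tvalues.iloc[0])
    df_err = int(model.df_resid)
    F = tval**2
    p = float(stats.f.sf(F, 1, df_err))
    return {
        "contrast": f"{level_a} vs {level_b}",
        "F": float(F),
        "df1": 1,
        "df2": df_err,
        "p": p,
        "np2": float(F / (F + df_err)),
    }


def interval_anova(slopes: pd.DataFrame, dv: str = "sqrt_abs_slope") -> dict:
    """Mixed ANOVA (interval within, group between) plus repeated contrasts.

    Subjects missing any interval are dropped listwise (with a warning).
    Also reports Mauchly's sphericity test on the within factor.
    """
    counts = slopes.groupby("subject")["interval"].nunique()
    levels = sorted(slopes["interval"].unique())
    complete = counts[counts == len(levels)].index
    if len(complete) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(complete)} subject(s) with missing intervals"
        )
    data = slopes[slopes["subject"].isin(complete)].copy()
    n_groups = data["group"].nunique()

    if data[dv].nunique() <= 1:
        # constant dv: no variance to decompose, report NaN/0 statistics
        aov = pd.DataFrame(
            {"term": ["group", "interval", "Interaction"], "F": np.nan, "p": np.nan}
        )
    elif n_groups > 1:
        aov = pg.mixed_anova(
            data=data, dv=dv, within="interval", between="group", subject="subject"
        )
    else:
        aov = pg.rm_anova(data=data, dv=dv, within="interval", subject="subject", detailed=True)
    aov = aov.rename(columns={"Source": "term", "p-unc": "p", "p_unc": "p"})
    for col in ("F", "p", "np2"):  # absent when pingouin hits a degenerate dv
        if col not in aov.columns:
            aov[col] = np.nan

    try:
        spher = pg.sphericity(data=data, dv=dv, within="interval", subject="subject")
        spher_out = {
            "W": float(spher.W),
            "chi2": float(spher.chi2),
            "dof": int(spher.dof),
            "p": float(spher.pval),
            "sphericity": bool(spher.spher),
        }
    except Exception:  # degenerate covariance
        spher_out = {"W": np.nan, "chi2": np.nan, "dof": 0, "p": np.nan, "sphericity": True}
    contrasts = [
        _repeated_contrast(data, dv, levels[i], levels[i + 1])
        for i in range(len(levels) - 1)
    ]
    return {
        "anova": aov,
        "sphericity": spher_out,
        "contrasts": contrasts,
        "n_subjects": int(len(complete)),
    }
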