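"""Per-subject logistic-GLM comparison of four candidate choice strategies.

For every subject, one simultaneous logistic GLM is fitted to the choice
sequence with a constant and four regressors:

* ``ideal`` — the Bayesian observer's expected-value difference: predictive
  E[r_A] times A's magnitude minus (1 - E[r_A]) times B's magnitude
  (subject-independent given the schedule); optimal choice follows the
  expected value, i.e. reward probability multiplied by reward size,
* ``alternation`` — the prediction that the subject flips their previous
  choice,
* ``wsls`` — the win-stay lose-shift prediction from the subject's own
  previous choice and its outcome,
* ``value`` — the displayed reward magnitude of option A (z-scored).

Strategy predictions are 0/1 and mapped to +/-0.5 around the constant; the
ideal and value regressors are z-scored. Trial 1 has no alternation/WSLS
prediction and is dropped. A model "fits" a subject when
its regressor's two-sided p-value is below .05.

Fitting is plain maximum likelihood (Newton/IRLS) with Wald t and p per
regressor. When ML diverges — guaranteed under the perfect separation
produced by deterministic strategy agents — the fit falls back to Firth's
bias-reducing penalized likelihood, which stays finite and keeps meaningful
Wald statistics; non-degenerate fits are untouched by the fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import chi2_contingency

from .ideal_observer import ObserverTrajectory
from .schedule import Schedule

MODEL_NAMES = ("ideal", "alternation", "wsls", "value")
ALPHA_LEVEL = 0.05


@dataclass
class DesignMatrix:
    """Aligned regressors and responses for one subject's choices."""

    X: np.ndarray  # (n_rows, 5): const + 4 regressors
    y: np.ndarray  # 1 = chose A
    columns: tuple = ("const",) + MODEL_NAMES
    trial_index: np.ndarray | None = None  # 1-based trials retained


@dataclass
class ModelFit:
    coef: dict
    se: dict
    tstat: dict
    pvalue: dict
    significant: dict  # per candidate model, p < .05
    best_model: str  # argmax t among the four candidates
    dropped: tuple = ()  # columns removed for rank deficiency
    converged: bool = True
    method: str = "ml"  # "ml" or "firth" (separation fallback)


def build_design(schedule: Schedule, trajectory: ObserverTrajectory) -> DesignMatrix:
    """Assemble the design matrix from a choice-bearing schedule and observer run."""
    choices = schedule.choices
    if choices is None:
        raise ValueError("schedule has no complete choice column")
    if len(trajectory) != schedule.n_trials:
        raise ValueError(
            f"trajectory length {len(trajectory)} != {schedule.n_trials} trials"
        )
    y_rewarded = schedule.rewarded_a

    # predictive estimate available when the choice was made
    e_r_pred = np.concatenate(([0.5], trajectory.e_r[:-1]))

    prev_choice = choices[:-1]
    prev_won = prev_choice == y_rewarded[:-1]
    pred_alt = 1.0 - prev_choice
    pred_wsls = np.where(prev_won, prev_choice, 1.0 - prev_choice)

    mag_a = schedule.magnitudes_a / 100.0
    mag_b = schedule.magnitudes_b / 100.0
    ideal = e_r_pred * mag_a - (1.0 - e_r_pred) * mag_b

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    n = schedule.n_trials
    X = np.column_stack(
        [
            np.ones(n - 1),
            _z(ideal[1:]),
            pred_alt - 0.5,
            pred_wsls - 0.5,
            _z(mag_a[1:]),
        ]
    )
    return DesignMatrix(
        X=X, y=choices[1:].astype(float), trial_index=np.arange(2, n + 1)
    )


def _ml_logistic(X, y, max_iter=50, tol=1e-10, coef_cap=15.0):
    """Plain Newton/IRLS logistic fit.

    Returns (beta, cov, ok); ``ok`` is False when the iteration fails to
    converge or a coefficient runs away (separation), in which case the
    caller should fall back to the Firth fit.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ok = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = X.T @ (y - mu)
        hess = (X.T * w) @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.abs(beta).max() > coef_cap:
            return beta, None, False
        if np.abs(step).max() < tol:
            ok = True
            break
    if not ok:
        return beta, None, False
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, True


def _firth_logistic(X, y, max_iter=200, tol=1e-8):
    """Firth bias-reduced logistic regression via modified-score Newton steps.

    The Jeffreys-prior penalty keeps estimates finite under complete
    separation. Returns (beta, cov, converged); cov is the inverse Fisher
    information at the optimum.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        # leverages of the weighted design
        h = np.einsum("ij,jk,ik->i", X * w[:, None], info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # damp oversized steps for stability on separated data
        norm = np.abs(step).max()
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if norm < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.pinv((X.T * w) @ X)
    return beta, cov, converged


def fit_choice_glm(design: DesignMatrix, min_trials: int = 20) -> ModelFit:
    """Fit the simultaneous 4-regressor logistic GLM for one subject."""
    X, y = design.X, design.y
    if len(y) < min_trials:
        raise ValueError(f"need >= {min_trials} choice trials, got {len(y)}")

    # degeneracy screen: drop constant-valued or duplicate regressor columns
    cols = list(design.columns)
    keep = [0]
    dropped = []
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if np.ptp(col) < 1e-12 or any(
            np.allclose(col, X[:, i]) for i in keep[1:]
        ):
            dropped.append(cols[j])
            warnings.warn(f"dropping degenerate regressor {cols[j]!r}")
        else:
            keep.append(j)
    Xk = X[:, keep]
    kept_names = [cols[j] for j in keep]

    beta, cov, ml_ok = _ml_logistic(Xk, y)
    if ml_ok:
        method, converged = "ml", True
    else:
        beta, cov, converged = _firth_logistic(Xk, y)
        method = "firth"
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * stats.norm.sf(np.abs(t))

    coef = dict(zip(kept_names, beta))
    se_d = dict(zip(kept_names, se))
    t_d = dict(zip(kept_names, t))
    p_d = dict(zip(kept_names, p))
    significant = {
        m: (m in p_d and p_d[m] < ALPHA_LEVEL) for m in MODEL_NAMES
    }
    candidates = {m: t_d[m] for m in MODEL_NAMES if m in t_d}
    best_model = max(candidates, key=candidates.get) if candidates else "none"
    return ModelFit(
        coef=coef,
        se=se_d,
        tstat=t_d,
        pvalue=p_d,
        significant=significant,
        best_model=best_model,
        dropped=tuple(dropped),
        converged=converged,
        method=method,
    )


def fits_frame(fits, subjects=None, groups=None) -> pd.DataFrame:
    """Tidy per-subject, per-model table of t, p and significance."""
    rows = []
    for i, fit in enumerate(fits):
        for m in MODEL_NAMES:
            rows.append(
                {
                    "subject": subjects[i] if subjects else f"s{i + 1:03d}",
                    "group": groups[i] if groups else "all",
                    "model": m,
                    "t": fit.tstat.get(m, np.nan),
                    "p": fit.pvalue.get(m, np.nan),
                    "significant": fit.significant.get(m, False),
                    "best": fit.best_model == m,
                }
            )
    return pd.DataFrame(rows)


def summarize_group(fits, group_labels) -> pd.DataFrame:
    """Group x model summary: mean t (with SEM), proportion significantly fit,
    and the share of subjects for which the model is the per-subject best.

    Both the per-group argmax of mean t and per-subject best-model counts are
    reported, since either reading supports a "best model" statement.
    """
    if len(fits) == 0:
        raise ValueError("no fits to summarize")
    if len(fits) != len(group_labels):
        raise ValueError("fits and group_labels differ in length")
    df = fits_frame(fits, groups=list(group_labels))
    out = (
        df.groupby(["group", "model"], sort=False)
        .agg(
            mean_t=("t", "mean"),
            sem_t=("t", lambda s: s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan),
            prop_significant=("significant", "mean"),
            prop_best=("best", "mean"),
            n=("t", "size"),
        )
        .reset_index()
    )
    best_by_mean_t = (
        out.loc[out.groupby("group")["mean_t"].idxmax(), ["group", "model"]]
        .set_index("group")["model"]
        .to_dict()
    )
    out.attrs["best_by_mean_t"] = best_by_mean_t
    return out


def compare_proportions(n_fit_a: int, n_a: int, n_fit_b: int, n_b: int) -> dict:
    """Pearson chi-squared (no continuity correction) on a 2x2 fit table."""
    if not (0 <= n_fit_a <= n_a and 0 <= n_fit_b <= n_b):
        raise ValueError("counts exceed group sizes")
    table = np.array([[n_fit_a, n_a - n_fit_a], [n_fit_b, n_b - n_fit_b]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"chi2": 0.0, "p": 1.0, "dof": 1}
    chi2, p, dof, _ = chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
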