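"""Cohort validation statistics.

Group summaries, one-way ANOVA with Scheffé post hoc contrasts, Pearson
correlation with the t-transform p value, and hierarchical OLS regression
with an R²-change F test for nested models.  Everything is computed from
first principles with numpy; scipy supplies only distribution quantiles and
tail probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InvariantViolationError,
    RankDeficiencyError,
    UndefinedCorrelationError,
)

#: F_change larger than this is reported as this overflow-safe value
#: (exact fit of the full model makes the statistic infinite).
F_CHANGE_CAP = 1e12


def group_summary(
    values: Sequence[float], labels: Sequence[str]
) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n−1 denominator; SD 0 for n = 1)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(values) != len(labels):
        raise InvariantViolationError("values and labels must have equal length")
    if len(values) == 0:
        raise InvariantViolationError("empty input")
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size == 0:
            raise InvariantViolationError(f"empty group {g!r}")
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        rows.append({"group": g, "n": int(v.size), "mean": float(v.mean()), "sd": sd})
    return pd.DataFrame(rows).set_index("group")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ss_between: float
    ss_within: float
    ms_within: float


def oneway_anova(values: Sequence[float], labels: Sequence[str]) -> AnovaResult:
    """Classical one-way fixed-effects decomposition; F = MSB/MSW."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    groups = pd.unique(labels)
    k = len(groups)
    n = len(values)
    if k < 2:
        raise InvariantViolationError("need at least 2 groups")
    if n <= k:
        raise InvariantViolationError("need total n > number of groups")
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        v = values[labels == g]
        if v.size == 0:
            raise InvariantViolationError(f"empty group {g!r}")
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += float(((v - v.mean()) ** 2).sum())
    df_b = k - 1
    df_w = n - k
    msw = ssw / df_w
    if msw == 0.0:
        raise DegenerateVarianceError("zero within-group variance")
    f = (ssb / df_b) / msw
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=p,
        ss_between=float(ssb),
        ss_within=float(ssw),
        ms_within=float(msw),
    )


@dataclass(frozen=True)
class ScheffeResult:
    group_a: str
    group_b: str
    mean_diff: float
    statistic: float
    criterion: float
    significant: bool


def scheffe_posthoc(
    values: Sequence[float], labels: Sequence[str], alpha: float = 0.05
) -> list[ScheffeResult]:
    """All pairwise Scheffé contrasts.

    A pair (i, j) is significant iff
    (mean_i − mean_j)² / (MSW·(1/n_i + 1/n_j)) > (k − 1)·F_crit(α; k−1, df_w).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    anova = oneway_anova(values, labels)
    groups = list(pd.unique(labels))
    k = len(groups)
    f_crit = float(sps.f.ppf(1 - alpha, k - 1, anova.df_within))
    criterion = (k - 1) * f_crit
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            vi = values[labels == groups[i]]
            vj = values[labels == groups[j]]
            diff = float(vi.mean() - vj.mean())
            stat = diff**2 / (anova.ms_within * (1 / vi.size + 1 / vj.size))
            out.append(
                ScheffeResult(
                    group_a=str(groups[i]),
                    group_b=str(groups[j]),
                    mean_diff=diff,
                    statistic=float(stat),
                    criterion=criterion,
                    significant=bool(stat > criterion),
                )
            )
    return out


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation; two-tailed p from t = r·sqrt((n−2)/(1−r²)).

    Missing values (NaN) are removed pairwise before computing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvariantViolationError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InvariantViolationError("need at least 3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("constant input")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p)


@dataclass(frozen=True)
class R2ChangeResult:
    r2_base: float
    r2_full: float
    delta_r2: float
    f_change: float
    df1: int
    df2: int
    p: float


def _ols_r2(y: np.ndarray, X: np.ndarray, column_names: list[str]) -> float:
    """R² of an OLS fit with intercept; raises on rank deficiency."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for idx in range(1, design.shape[1]):
            reduced = np.delete(design, idx, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(column_names[idx - 1])
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear columns: {bad}", columns=bad
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise DegenerateVarianceError("response is constant")
    return 1.0 - ss_res / ss_tot


def hierarchical_r2_change(
    response: Sequence[float],
    base_predictors,
    added_predictors,
    base_names: Optional[list[str]] = None,
    added_names: Optional[list[str]] = None,
) -> R2ChangeResult:
    """Nested-model comparison: F_change for adding q predictors.

    F_change = (ΔR²/q) / ((1 − R²_full)/(n − k_full − 1)); an exact fit of
    the full model reports the overflow-safe cap instead of infinity.
    """
    y = np.asarray(response, dtype=float)
    Xb = np.atleast_2d(np.asarray(base_predictors, dtype=float))
    Xa = np.atleast_2d(np.asarray(added_predictors, dtype=float))
    if Xb.shape[0] != y.size:
        Xb = Xb.T
    if Xa.shape[0] != y.size:
        Xa = Xa.T
    n = y.size
    q = Xa.shape[1]
    k_full = Xb.shape[1] + q
    if n <= k_full + 1:
        raise InvariantViolationError("need n > number of full-model predictors + 1")
    base_names = base_names or [f"base{i}" for i in range(Xb.shape[1])]
    added_names = added_names or [f"added{i}" for i in range(q)]

    r2_base = _ols_r2(y, Xb, base_names)
    r2_full = _ols_r2(y, np.column_stack([Xb, Xa]), base_names + added_names)
    delta = max(0.0, r2_full - r2_base)
    df2 = n - k_full - 1
    denom = (1.0 - r2_full) / df2
    if denom <= 0.0:
        f_change = F_CHANGE_CAP
    else:
        f_change = min((delta / q) / denom, F_CHANGE_CAP)
    p = float(sps.f.sf(f_change, q, df2))
    return R2ChangeResult(
        r2_base=float(r2_base),
        r2_full=float(r2_full),
        delta_r2=float(delta),
        f_change=float(f_change),
        df1=q,
        df2=df2,
        p=p,
    )


def correlation_battery(
    frame: pd.DataFrame,
    score_columns: Sequence[str],
    roi_columns: Sequence[str],
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of each score against each ROI."""
    rows = []
    for score in score_columns:
        for roi in roi_columns:
            res = pearson_r(frame[score].to_numpy(), frame[roi].to_numpy())
            rows.append(
                {"score": score, "roi": roi, "r": res.r, "n": res.n, "p": res.p}
            )
    return pd.DataFrame(rows, columns=["score", "roi", "r", "n", "p"])
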