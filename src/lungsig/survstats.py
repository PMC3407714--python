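"""Survival and agreement statistics for signature evaluation.

Kaplan–Meier / log-rank / multivariate Cox come from lifelines; the
time-thresholded ROC labelling rules, Hanley–McNeil CIs, the DeLong
correlated-AUC comparison and Passing–Bablok method-comparison
regression (with its cusum linearity test) are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import special, stats

from .containers import LungsigError


@dataclass
class SurvivalSummary:
    """Hazard ratio with CI/p for an indicator, plus context counts/curves."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    statistic: float
    n: int
    events: int
    km_curves: dict = field(default_factory=dict)
    evaluable: bool = True
    note: str = ""
    logrank_p: float = float("nan")

    def to_jsonable(self):
        return {
            "hr": self.hr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "statistic": self.statistic,
            "n": self.n,
            "events": self.events,
            "evaluable": self.evaluable,
            "note": self.note,
            "logrank_p": self.logrank_p,
        }


def censor_at(clinical: pd.DataFrame, horizon_months: float) -> pd.DataFrame:
    """Administratively censor at a horizon (events beyond it become censored)."""
    if horizon_months <= 0:
        raise LungsigError("censoring horizon must be positive")
    out = clinical.copy()
    late = out["followup_months"] > horizon_months
    out.loc[late, "dss_event"] = 0
    out.loc[late, "followup_months"] = horizon_months
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a step function.

    Returns a DataFrame with columns ``time`` and ``survival`` (the curve
    starts at S(0)=1 and drops only at event times).
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        raise LungsigError("empty survival data")
    if (times < 0).any():
        raise LungsigError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank(times, events, group_labels):
    """k-group log-rank test; returns (chi2, p) with k-1 df."""
    groups = pd.Series(group_labels)
    if groups.nunique() < 2:
        raise LungsigError("log-rank test requires at least 2 groups")
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise LungsigError("log-rank test requires at least one event")
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups, events)
    return float(res.test_statistic), float(res.p_value)


def _drop_degenerate_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Drop constant then linearly dependent columns (warning names them)."""
    keep = []
    for c in df.columns:
        col = df[c].to_numpy(dtype=float)
        if np.nanstd(col) == 0.0:
            warnings.warn(f"dropping constant covariate column {c!r}")
            continue
        keep.append(c)
    df = df[keep]
    X = df.to_numpy(dtype=float)
    if X.shape[1] == 0:
        return df
    q, r = np.linalg.qr(X - X.mean(axis=0))
    diag = np.abs(np.diag(r))
    tol = diag.max() * 1e-8 if diag.size else 0.0
    keep2 = []
    rank = 0
    Xc = X - X.mean(axis=0)
    basis = np.zeros((X.shape[0], 0))
    for j, c in enumerate(df.columns):
        cand = np.column_stack([basis, Xc[:, j]])
        if np.linalg.matrix_rank(cand, tol=1e-8) > rank:
            keep2.append(c)
            basis = cand
            rank += 1
        else:
            warnings.warn(f"dropping linearly dependent covariate column {c!r}")
    return df[keep2]


def cox_multivariate(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    indicator: str,
    covariate_cols=(),
) -> SurvivalSummary:
    """Covariate-adjusted Cox PH fit; HR/CI/Wald p for ``indicator``.

    Degenerate (constant or collinear) covariate columns are dropped with
    a warning. Monotone-likelihood (separation) fits are flagged in
    ``note`` with lifelines' bounded estimate retained.
    """
    cols = [indicator] + [c for c in covariate_cols if c != indicator]
    design = _drop_degenerate_columns(df[cols])
    if indicator not in design.columns:
        raise LungsigError(f"indicator column {indicator!r} is degenerate")
    data = pd.concat([df[[duration_col, event_col]], design], axis=1)
    cph = CoxPHFitter()
    note = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as err:
            raise LungsigError(f"Cox model failed to converge: {err}") from err
        for w in caught:
            if "convergence" in str(w.message).lower() or "complete separation" in str(w.message).lower():
                note = f"possible separation/ill-conditioning: {w.message}"
    # monotone likelihood (e.g. an arm with zero events) drives |coef| and its
    # SE to infinity; refit with a small ridge for a bounded, flagged estimate
    s = cph.summary.loc[indicator]
    if not np.isfinite(s["z"]) or abs(s["coef"]) > 10 or s["se(coef)"] > 10:
        cph = CoxPHFitter(penalizer=0.1, l1_ratio=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        note = (note + "; ridge-stabilized (monotone likelihood / separation)").lstrip("; ")
        warnings.warn(f"separation detected for {indicator!r}; ridge-stabilized estimate reported")
    s = cph.summary.loc[indicator]
    return SurvivalSummary(
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
        statistic=float(s["z"]),
        n=len(data),
        events=int(data[event_col].sum()),
        note=note,
    )


def dss_outcome_labels(
    clinical: pd.DataFrame,
    event_horizon_months: float,
    min_followup_months: float = 12.0,
    late_event_exclusion_months: float | None = None,
):
    """Binary outcome labels for time-thresholded ROC, with exclusions.

    Positive: disease-specific death by ``event_horizon_months``.
    Negative: event-free with follow-up of at least ``min_followup_months``.
    Excluded: alive with short follow-up; and, when
    ``late_event_exclusion_months`` is set, deaths after that time.

    Returns (labels, included_mask) as aligned pandas Series; labels are
    NaN where excluded.
    """
    if event_horizon_months <= 0 or min_followup_months <= 0:
        raise LungsigError("horizons must be positive")
    t = clinical["followup_months"].astype(float)
    e = clinical["dss_event"].astype(int)
    labels = pd.Series(np.nan, index=clinical.index)
    included = pd.Series(False, index=clinical.index)
    pos = (e == 1) & (t <= event_horizon_months)
    late_excl = pd.Series(False, index=clinical.index)
    if late_event_exclusion_months is not None:
        late_excl = (e == 1) & (t > late_event_exclusion_months)
    neg = (e == 0) & (t >= min_followup_months)
    labels[pos] = 1.0
    labels[neg] = 0.0
    # events after the horizon but within the late-exclusion window count as negative
    mid = (e == 1) & (t > event_horizon_months) & ~late_excl
    labels[mid] = 0.0
    included = labels.notna() & ~late_excl
    labels[~included] = np.nan
    return labels, included


def _auc_mann_whitney(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise LungsigError("ROC requires both outcome classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
    return float(auc), len(pos), len(neg)


def roc_auc(scores, labels):
    """AUC (tie-corrected Mann–Whitney) with Hanley–McNeil CI and p vs 0.5.

    Returns (auc, ci_low, ci_high, p_vs_half).
    """
    auc, n1, n0 = _auc_mann_whitney(scores, labels)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = float(np.sqrt(max(var, 0.0)))
    ci_low = max(0.0, auc - 1.959963984540054 * se)
    ci_high = min(1.0, auc + 1.959963984540054 * se)
    # null variance at AUC = 0.5 (Hanley-McNeil form evaluated at 0.5)
    var0 = (0.25 + (n1 + n0 - 2) * (1 / 3 - 0.25)) / (n1 * n0)
    z = (auc - 0.5) / np.sqrt(var0)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(auc), ci_low, ci_high, p


def _delong_placements(scores, labels):
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    all_ = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n  # placement of each positive among negatives
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = v10.mean()
    return auc, v10, v01


def compare_auc(scores_a, scores_b, labels):
    """DeLong test for the difference of two correlated (paired) AUCs.

    Both score vectors must be measured on the same samples. Returns a
    two-sided p-value.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise LungsigError("compare_auc requires paired scores on identical samples")
    if len(np.unique(labels)) < 2:
        raise LungsigError("compare_auc requires both outcome classes present")
    auc_a, v10a, v01a = _delong_placements(scores_a, labels)
    auc_b, v10b, v01b = _delong_placements(scores_b, labels)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def passing_bablok(x, y, alpha: float = 0.05):
    """Passing–Bablok method-comparison regression with cusum linearity test.

    Slope is the shifted median of all pairwise slopes (slopes equal to
    -1 discarded; the shift K counts slopes below -1), with rank-based
    confidence bounds; intercept is the median of ``y - slope*x``. The
    linearity p-value comes from a cusum of residual signs taken in order
    of increasing x, referred to the Kolmogorov distribution.

    Returns a dict with slope, intercept, slope_ci, intercept_ci,
    linearity_p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise LungsigError("Passing-Bablok requires n >= 3 paired points")
    if np.all(x == x[0]):
        raise LungsigError("Passing-Bablok requires variation in x")
    slopes = []
    for i, j in combinations(range(len(x)), 2):
        dx = x[j] - x[i]
        dy = y[j] - y[i]
        if dx == 0:
            if dy == 0:
                continue
            slopes.append(np.inf if dy > 0 else -np.inf)
            continue
        s = dy / dx
        if s == -1.0:
            continue  # discarded per the original procedure
        slopes.append(s)
    slopes = np.sort(np.asarray(slopes, dtype=float))
    N = len(slopes)
    if N == 0:
        raise LungsigError("no valid pairwise slopes")
    K = int(np.sum(slopes < -1.0))

    def shifted_at(rank_1based: int) -> float:
        idx = min(max(rank_1based - 1, 0), N - 1)
        return float(slopes[idx])

    if N % 2 == 1:
        slope = shifted_at((N + 1) // 2 + K)
    else:
        slope = 0.5 * (shifted_at(N // 2 + K) + shifted_at(N // 2 + 1 + K))
    n = len(x)
    w = stats.norm.ppf(1 - alpha / 2) * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((N - w) / 2.0))
    m2 = N - m1 + 1
    slope_lo = shifted_at(max(m1, 1) + K)
    slope_hi = shifted_at(min(m2, N) + K)
    intercept = float(np.median(y - slope * x))
    intercept_lo = float(np.median(y - slope_hi * x))
    intercept_hi = float(np.median(y - slope_lo * x))

    resid = y - (intercept + slope * x)
    above = resid > 0
    below = resid < 0
    l_above, l_below = int(above.sum()), int(below.sum())
    if l_above == 0 or l_below == 0:
        linearity_p = 1.0
    else:
        score = np.zeros(n)
        score[above] = np.sqrt(l_below / l_above)
        score[below] = -np.sqrt(l_above / l_below)
        order = np.argsort(x, kind="stable")
        cusum = np.cumsum(score[order])
        statistic = np.max(np.abs(cusum)) / np.sqrt(l_above + l_below)
        linearity_p = float(special.kolmogorov(statistic))
    return {
        "slope": slope,
        "intercept": intercept,
        "slope_ci": (slope_lo, slope_hi),
        "intercept_ci": (intercept_lo, intercept_hi),
        "linearity_p": linearity_p,
    }


def treatment_benefit(
    clinical_rct: pd.DataFrame,
    predicted_class: pd.Series,
    covariates=("age", "gender", "stage", "histology"),
    censor_horizon: float = 36.0,
) -> dict:
    """ACT-vs-OBS benefit, separately within each predicted response class.

    Within each class: Kaplan–Meier curves per arm, log-rank test, and a
    covariate-adjusted Cox HR for the treatment indicator, censored at
    ``censor_horizon`` months. A class with only one arm present is
    reported as not evaluable rather than raising.
    """
    from .containers import design_matrix  # late import avoids cycle at module load

    calls = pd.Series(predicted_class).reindex(clinical_rct.index)
    if calls.isna().any():
        raise LungsigError("predicted_class missing for some samples")
    out = {}
    for cls in sorted(calls.unique(), key=str):
        sub = censor_at(clinical_rct.loc[calls == cls], censor_horizon)
        arms = sub["treatment"].astype(str).str.upper()
        if arms.nunique() < 2:
            out[cls] = SurvivalSummary(
                np.nan, np.nan, np.nan, np.nan, np.nan,
                n=len(sub), events=int(sub["dss_event"].sum()),
                evaluable=False, note="only one treatment arm present",
            )
            continue
        km = {
            arm: km_estimate(g["followup_months"], g["dss_event"])
            for arm, g in sub.groupby(arms)
        }
        try:
            chi2, logrank_p = logrank(sub["followup_months"], sub["dss_event"], arms)
        except LungsigError:
            chi2, logrank_p = np.nan, np.nan
        Z = design_matrix(sub, list(covariates) + ["treatment"])
        df = pd.concat(
            [sub[["followup_months", "dss_event"]], Z], axis=1
        )
        try:
            summ = cox_multivariate(
                df, "followup_months", "dss_event", "treatment_act",
                covariate_cols=[c for c in Z.columns if c != "treatment_act"],
            )
        except LungsigError as err:
            out[cls] = SurvivalSummary(
                np.nan, np.nan, np.nan, np.nan, np.nan,
                n=len(sub), events=int(sub["dss_event"].sum()),
                evaluable=False, note=str(err), km_curves=km,
            )
            continue
        summ.km_curves = km
        summ.statistic = chi2
        summ.logrank_p = logrank_p
        out[cls] = summ
    return out
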