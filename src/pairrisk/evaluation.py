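"""Survival evaluation: Kaplan-Meier, log-rank, time-dependent ROC.

The time-dependent ROC uses the cumulative/dynamic definition: at horizon
tau, cases are subjects with an observed event at or before tau and
controls are subjects still under observation past tau. Subjects censored
before tau are neither; the resulting selection bias is corrected by
inverse-probability-of-censoring weights (IPCW) from a Kaplan-Meier
estimate of the censoring distribution. With no censoring the weighted
concordance collapses exactly to the Mann-Whitney AUC of the binary
event-by-tau status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cox import CoxFit, SingularMatrixError, fit_cox
from .datamodel import SurvivalData

DAYS_PER_YEAR = 365.25


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """S(t) (right-continuous step function; S = 1 before first event)."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def at_minus(self, t: float) -> float:
        """Left limit S(t-)."""
        i = np.searchsorted(self.times, t, side="left")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    p: float


@dataclass
class TimeROC:
    """Cumulative/dynamic ROC at one horizon."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _time_event(surv):
    if isinstance(surv, SurvivalData):
        return surv.time, surv.event
    t, e = surv
    return np.asarray(t, float), np.asarray(e, int)


def km_curve(surv) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at t remain in the risk set for events at t (the
    standard tie convention); censoring reduces the risk set only after
    its time.
    """
    time, event = _time_event(surv)
    if time.size == 0:
        raise ValueError("empty survival subset")
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    ev_times = np.unique(ts[es == 1])
    if ev_times.size == 0:
        return KMCurve(np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int))
    n_at_risk = ts.size - np.searchsorted(ts, ev_times, side="left")
    d = np.array([int(((ts == t) & (es == 1)).sum()) for t in ev_times])
    surv_prob = np.cumprod(1.0 - d / n_at_risk)
    return KMCurve(ev_times, surv_prob, n_at_risk.astype(int), d)


def censoring_km(surv) -> KMCurve:
    """KM estimate of the censoring distribution (event roles flipped)."""
    time, event = _time_event(surv)
    return km_curve((time, 1 - event))


def logrank_test(surv, groups) -> LogRankResult:
    """Two-group log-rank test, chi-square on 1 df.

    At each distinct event time: O1 = observed events in group 1,
    E1 = d * n1/n (hypergeometric mean), V = d (n1/n)(n2/n)(n-d)/(n-1);
    chi_square = (sum(O1 - E1))^2 / sum(V).
    """
    time, event = _time_event(surv)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"need exactly 2 nonempty groups, got {labels.size}")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    is1 = g == labels[0]
    ev_times = np.unique(time[event == 1])
    o_minus_e = 0.0
    v = 0.0
    for t in ev_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & is1).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & is1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return LogRankResult(0.0, 1.0)
    chi = o_minus_e**2 / v
    return LogRankResult(float(chi), float(stats.chi2.sf(chi, 1)))


def td_auc(scores, surv, horizon: float) -> TimeROC:
    """IPCW cumulative/dynamic ROC and AUC at one horizon (in days).

    Cases (event by tau) are weighted 1/G(T_i-), controls (followed past
    tau) 1/G(tau), with G the censoring-distribution KM. AUC is the
    weighted concordance of scores, ties counted 1/2.
    """
    time, event = _time_event(surv)
    s = np.asarray(scores, float)
    if s.shape != time.shape:
        raise ValueError("scores and survival data must be aligned")
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    if not case.any() or not control.any():
        raise ValueError(f"no cases or no controls at horizon {horizon}")
    G = censoring_km((time, event))
    w = np.zeros(s.size)
    for i in np.nonzero(case)[0]:
        g = G.at_minus(time[i])
        w[i] = 1.0 / g if g > 0 else 0.0
    g_tau = G.at(horizon)
    w[control] = 1.0 / g_tau if g_tau > 0 else 0.0

    sc, wc = s[case], w[case]
    sk, wk = s[control], w[control]
    # weighted concordance via sorting: O((nc+nk) log)
    order = np.argsort(sk, kind="stable")
    sk_s, wk_s = sk[order], wk[order]
    cum_w = np.concatenate([[0.0], np.cumsum(wk_s)])
    total_k = cum_w[-1]
    lo = np.searchsorted(sk_s, sc, side="left")
    hi = np.searchsorted(sk_s, sc, side="right")
    conc = wc * (cum_w[lo] + 0.5 * (cum_w[hi] - cum_w[lo]))
    auc = float(conc.sum() / (wc.sum() * total_k))

    thresholds = np.unique(s)[::-1]  # descending: predict case if score > c
    sens = np.array([(wc * (sc > c)).sum() / wc.sum() for c in thresholds])
    spec = np.array([(wk * (sk <= c)).sum() / total_k for c in thresholds])
    thresholds = np.concatenate([[np.inf], thresholds, [-np.inf]])
    sens = np.concatenate([[0.0], sens, [1.0]])
    spec = np.concatenate([[1.0], spec, [0.0]])
    return TimeROC(horizon, thresholds, sens, spec, auc)


def multi_index_roc(surv: SurvivalData, horizon: float, variables: pd.DataFrame) -> dict[str, TimeROC]:
    """td_auc per variable on the identical listwise-complete sample subset.

    ``variables`` is samples x variables (risk score plus numeric/ordinal
    clinical covariates), indexed like ``surv``.
    """
    v = variables.loc[list(surv.sample_ids)].astype(float)
    if v.isna().all().any():
        bad = v.columns[v.isna().all()][0]
        raise ValueError(f"covariate {bad!r} is entirely missing")
    complete = v.dropna()
    sub = surv.subset(complete.index)
    out = {}
    for name in complete.columns:
        out[name] = td_auc(complete[name].to_numpy(), sub, horizon)
    return out


def independence_test(
    score: pd.Series, covariates: pd.DataFrame, surv: SurvivalData, alpha: float = 0.05
) -> tuple[CoxFit, CoxFit, bool]:
    """Is the risk score prognostic after adjusting for clinical covariates?

    Returns (univariate fit of the score, multivariate fit of score plus
    covariates on the listwise-complete subset, independent-predictor flag:
    multivariate score p < alpha). Collinear covariates raise
    SingularMatrixError.
    """
    ids = list(surv.sample_ids)
    uni = fit_cox(score.loc[ids].to_frame("score"), surv)
    X = pd.concat([score.rename("score"), covariates], axis=1).loc[ids].astype(float)
    complete = X.dropna()
    sub = surv.subset(complete.index)
    if len(complete) < 10 * X.shape[1]:
        warnings.warn(
            f"only {len(complete)} complete samples for {X.shape[1]} covariates",
            stacklevel=2,
        )
    # exact duplicates of the score are collinear by construction
    for c in covariates.columns:
        col = complete[c].to_numpy()
        if col.std() > 0 and np.allclose(col, complete["score"].to_numpy()):
            raise SingularMatrixError(f"covariate {c!r} duplicates the risk score")
    multi = fit_cox(complete, sub)
    independent = bool(multi.p[multi.names.index("score")] < alpha)
    return uni, multi, independent


def group_trend_test(scores, levels) -> tuple[float, float]:
    """Association of the risk score with an ordinal clinical variable.

    Two levels: Mann-Whitney rank-sum; more: Kruskal-Wallis. Returns
    (statistic, p).
    """
    from .downstream import rank_sum_test  # local import avoids a cycle

    s = np.asarray(scores, float)
    lv = np.asarray(levels)
    uniq = np.unique(lv)
    if uniq.size < 2:
        raise ValueError("need at least 2 levels")
    if uniq.size == 2:
        res = rank_sum_test(s[lv == uniq[0]], s[lv == uniq[1]])
        return res.statistic, res.p
    stat, p = stats.kruskal(*[s[lv == u] for u in uniq])
    return float(stat), float(p)
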