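"""Cox proportional-hazards machinery implemented from first principles.

Contains the partial-likelihood core (Efron and Breslow tie handling),
Newton-Raphson maximization with observed-information standard errors, the
per-pair univariate screen, cross-validated L1-penalized (LASSO) Cox by
cyclic coordinate descent, the unpenalized refit that finalizes a risk
model, and risk-score stratification at the training-median cutoff.

The partial likelihood with Efron ties: for an event time with d tied
deaths (set D, risk set R),

    ll += sum_{i in D} eta_i - sum_{l=0}^{d-1} log(S_R - (l/d) S_D)

with S_R = sum_{j in R} exp(eta_j) and S_D the same sum over D; Breslow is
the l/d -> 0 special case. All risk-set sums are suffix cumulative sums
over samples sorted by time, so every gradient/Hessian evaluation is O(n)
vectorized work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SurvivalData
from .pairing import PairMatrix

MAX_NEWTON_ITER = 100
SCORE_TOL = 1e-9
LOGLIK_RTOL = 1e-12
SEPARATION_BETA = 20.0
CD_TOL = 1e-7  # coordinate-descent max |delta beta| per cycle


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge; carries the last iterate."""

    def __init__(self, msg, beta):
        super().__init__(msg)
        self.last_beta = beta


class SingularMatrixError(np.linalg.LinAlgError):
    """Covariate matrix is collinear (information matrix singular)."""


class _CoxData:
    """Sorted times/events with precomputed risk-set and tie bookkeeping.

    Independent of the covariates, so one instance can be reused across
    many univariate fits or coordinate-descent sweeps on the same cohort.
    """

    def __init__(self, time, event, ties: str = "efron"):
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be equal-length vectors")
        if event.sum() < 1:
            raise ValueError("need at least one event")
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.ts = time[self.order]
        self.es = event[self.order]
        self.event_pos = np.nonzero(self.es == 1)[0]
        self.n_events = self.event_pos.size

        # event groups = distinct event times
        ev_times = self.ts[self.event_pos]
        is_new = np.empty(self.n_events, bool)
        is_new[0] = True
        is_new[1:] = ev_times[1:] != ev_times[:-1]
        self.group_bounds = np.nonzero(is_new)[0]  # reduceat bounds into event_pos
        group_times = ev_times[self.group_bounds]
        self.d = np.add.reduceat(np.ones(self.n_events), self.group_bounds).astype(int)
        # first index in sorted order with ts >= group time => risk-set start
        self.risk_start = np.searchsorted(self.ts, group_times, side="left")

        # one slot per (group, l), l = 0..d-1; frac = l/d for Efron
        n_groups = group_times.size
        self.slot_group = np.repeat(np.arange(n_groups), self.d)
        within = np.arange(self.n_events) - np.repeat(self.group_bounds, self.d)
        if ties == "efron":
            self.frac = within / np.repeat(self.d, self.d)
        else:
            self.frac = np.zeros(self.n_events)

    # -- suffix risk-set sums -------------------------------------------------
    def _suffix_at_risk(self, a):
        """sum_{k >= risk_start_g} a_k for each event group (a in sorted order)."""
        return np.cumsum(a[::-1], axis=0)[::-1][self.risk_start]

    def _tied_sum(self, a):
        return np.add.reduceat(a[self.event_pos], self.group_bounds, axis=0)

    def denominators(self, w):
        """Per-slot Efron/Breslow denominators given w = exp(eta) (sorted)."""
        s_r = self._suffix_at_risk(w)[self.slot_group]
        s_d = self._tied_sum(w)[self.slot_group]
        return s_r - self.frac * s_d

    def loglik(self, eta_sorted):
        c = eta_sorted.mean()  # shifts cancel: one slot per event
        w = np.exp(eta_sorted - c)
        denom = self.denominators(w)
        return float(eta_sorted[self.event_pos].sum() - self.n_events * c - np.log(denom).sum())

    def grad_hess(self, eta_sorted, X_sorted):
        """Gradient and Hessian of the log partial likelihood (not negated)."""
        c = eta_sorted.mean()
        w = np.exp(eta_sorted - c)
        denom = self.denominators(w)
        wx = w[:, None] * X_sorted
        num = (
            self._suffix_at_risk(wx)[self.slot_group]
            - self.frac[:, None] * self._tied_sum(wx)[self.slot_group]
        )
        xbar = num / denom[:, None]
        grad = X_sorted[self.event_pos].sum(axis=0) - xbar.sum(axis=0)
        wxx = wx[:, :, None] * X_sorted[:, None, :]
        num2 = (
            self._suffix_at_risk(wxx)[self.slot_group]
            - self.frac[:, None, None] * self._tied_sum(wxx)[self.slot_group]
        )
        hess = -(num2 / denom[:, None, None]).sum(axis=0) + np.einsum("si,sj->ij", xbar, xbar)
        return grad, hess

    def grad_hess_1d(self, eta_sorted, x_sorted, w=None, denom=None):
        """Scalar gradient/curvature for one coordinate (for coordinate descent)."""
        if w is None:
            w = np.exp(eta_sorted - eta_sorted.mean())
            denom = self.denominators(w)
        wx = w * x_sorted
        num = (
            self._suffix_at_risk(wx)[self.slot_group]
            - self.frac * self._tied_sum(wx)[self.slot_group]
        )
        xbar = num / denom
        grad = x_sorted[self.event_pos].sum() - xbar.sum()
        wxx = wx * x_sorted
        num2 = (
            self._suffix_at_risk(wxx)[self.slot_group]
            - self.frac * self._tied_sum(wxx)[self.slot_group]
        )
        hess = -(num2 / denom).sum() + (xbar**2).sum()
        return grad, hess


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit with Wald inference."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    ties: str
    n: int
    n_events: int
    converged: bool = True
    separation: bool = False

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci_lo(self) -> np.ndarray:
        return np.exp(self.beta - 1.959963984540054 * self.se)

    @property
    def ci_hi(self) -> np.ndarray:
        return np.exp(self.beta + 1.959963984540054 * self.se)

    @property
    def p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, 0.0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "p": self.p,
            },
            index=pd.Index(self.names, name="variable"),
        )


def _as_xy(X, surv):
    """Coerce (X, surv) to aligned numpy arrays plus names."""
    if isinstance(surv, SurvivalData):
        time, event = surv.time, surv.event
        index = surv.sample_ids
    else:
        time, event = surv
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        index = None
    if isinstance(X, pd.DataFrame):
        if index is not None:
            X = X.loc[index]
        names = [str(c) for c in X.columns]
        Xa = X.to_numpy(float)
    else:
        Xa = np.atleast_2d(np.asarray(X, float))
        if Xa.shape[0] != time.size:
            Xa = Xa.T
        names = [f"x{j}" for j in range(Xa.shape[1])]
    return Xa, names, time, event


def fit_cox(X, surv, ties: str = "efron") -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    ``X`` is samples x covariates (DataFrame aligned on sample IDs, or
    array); ``surv`` a SurvivalData or (time, event) tuple. Constant
    columns carry no information: their coefficient stays 0 with infinite
    SE. A collinear (non-constant) covariate set raises
    SingularMatrixError; |beta| > 20 sets the separation flag.
    """
    Xa, names, time, event = _as_xy(X, surv)
    cd = _CoxData(time, event, ties)
    n, p = Xa.shape
    Xs = Xa[cd.order]
    loglik_null = cd.loglik(np.zeros(n))
    if p == 0:
        return CoxFit([], np.empty(0), np.empty(0), loglik_null, loglik_null, ties, n, cd.n_events)

    const = Xs.std(axis=0) == 0
    free = np.nonzero(~const)[0]
    beta = np.zeros(p)
    ll = loglik_null
    if free.size:
        Xf = Xs[:, free]
        # standardize for conditioning; back-transform at the end
        mu, sd = Xf.mean(axis=0), Xf.std(axis=0)
        Xz = (Xf - mu) / sd
        bz = np.zeros(free.size)
        for it in range(MAX_NEWTON_ITER):
            eta = Xz @ bz
            ll = cd.loglik(eta)
            grad, hess = cd.grad_hess(eta, Xz)
            info = -hess
            singular = (
                np.linalg.matrix_rank(info, tol=1e-8 * max(1.0, np.abs(info).max()))
                < free.size
            )
            if singular and it == 0:
                # flat directions at beta = 0 mean collinear covariates;
                # later on they signal separation, handled via pinv + flag
                raise SingularMatrixError("singular covariate matrix (collinear covariates)")
            if np.max(np.abs(bz / sd)) > SEPARATION_BETA:
                break  # diverging estimate: complete separation
            step = np.linalg.pinv(info) @ grad if singular else np.linalg.solve(info, grad)
            # step-halving keeps the likelihood non-decreasing
            t = 1.0
            for _ in range(40):
                ll_new = cd.loglik(Xz @ (bz + t * step))
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                t *= 0.5
            bz = bz + t * step
            if np.max(np.abs(grad)) < SCORE_TOL or abs(ll_new - ll) <= LOGLIK_RTOL * (abs(ll) + 1.0):
                ll = ll_new
                break
        else:
            raise ConvergenceError(
                f"Cox fit did not converge in {MAX_NEWTON_ITER} iterations", bz / sd
            )
        beta[free] = bz / sd
        ll = cd.loglik(Xs @ beta)

    # observed information on the original scale
    se = np.full(p, np.inf)
    if free.size:
        grad, hess = cd.grad_hess(Xs @ beta, Xs[:, free])
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-hess)
        se[free] = np.sqrt(np.maximum(np.diag(cov), 0.0))
    separation = bool(np.any(np.abs(beta) > SEPARATION_BETA))
    return CoxFit(names, beta, se, ll, loglik_null, ties, n, cd.n_events, True, separation)


# ---------------------------------------------------------------------------
# univariate screen


def univariate_screen(
    pm: PairMatrix, surv: SurvivalData, p_max: float = 0.01, ties: str = "efron"
) -> tuple[pd.DataFrame, list[str]]:
    """One single-covariate Cox fit per pair indicator; keep Wald p < p_max.

    Returns (retained table with beta/se/hr/ci/p for every tested pair plus
    a ``retained`` flag, skipped-pair list). Pairs constant across the
    modelled samples carry no ordering contrast and are skipped.
    """
    samples = [s for s in surv.sample_ids if s in pm.indicators.columns]
    if len(samples) < len(surv.sample_ids):
        missing = set(surv.sample_ids) - set(samples)
        raise KeyError(f"pair matrix lacks survival samples, e.g. {sorted(missing)[:3]}")
    sub = pm.indicators[samples]
    rows, skipped = [], []
    for pid, row in sub.iterrows():
        x = row.to_numpy(float)
        if x.std() == 0:
            skipped.append(pid)
            continue
        fit = fit_cox(x[:, None], (surv.time, surv.event), ties)
        rows.append(
            {
                "pair_id": pid,
                "beta": fit.beta[0],
                "se": fit.se[0],
                "hr": fit.hr[0],
                "ci_lo": fit.ci_lo[0],
                "ci_hi": fit.ci_hi[0],
                "p": fit.p[0],
            }
        )
    table = pd.DataFrame(rows).set_index("pair_id") if rows else pd.DataFrame(
        columns=["beta", "se", "hr", "ci_lo", "ci_hi", "p"]
    )
    table["retained"] = table["p"] < p_max
    return table, skipped


# ---------------------------------------------------------------------------
# LASSO-Cox by cyclic coordinate descent


@dataclass
class LassoPath:
    """L1-penalized Cox path with k-fold cross-validated deviance."""

    names: list[str]
    lambdas: np.ndarray  # descending
    betas: np.ndarray  # p x n_lambda
    cv_deviance: np.ndarray
    cv_se: np.ndarray
    lambda_selected: float
    selected_index: int
    n_folds: int
    seed: int

    @property
    def selected_beta(self) -> pd.Series:
        return pd.Series(self.betas[:, self.selected_index], index=self.names)

    def selected_pairs(self, tol: float = 0.0) -> list[str]:
        b = self.selected_beta
        return [n for n, v in b.items() if abs(v) > tol]


def _cd_path(cd: _CoxData, Xs, lambdas, tol=CD_TOL, max_cycles=2000):
    """Coordinate-descent solutions along a descending lambda grid.

    Objective: -(1/n) loglik + lambda * ||beta||_1, warm-started.
    """
    n, p = Xs.shape
    betas = np.zeros((p, lambdas.size))
    beta = np.zeros(p)
    eta = np.zeros(n)
    active = np.zeros(p, bool)
    for li, lam in enumerate(lambdas):
        for _outer in range(100):
            # inner loop on current active set
            for _cycle in range(max_cycles):
                max_delta = 0.0
                w = np.exp(eta - eta.mean())
                denom = cd.denominators(w)
                for j in np.nonzero(active)[0]:
                    g, h = cd.grad_hess_1d(eta, Xs[:, j], w, denom)
                    g = -g / n  # gradient of the negative mean loglik
                    h = max(-h / n, 1e-12)  # curvature (positive)
                    z = h * beta[j] - g
                    bj = np.sign(z) * max(abs(z) - lam, 0.0) / h
                    d = bj - beta[j]
                    if d != 0.0:
                        eta = eta + d * Xs[:, j]
                        beta[j] = bj
                        w = np.exp(eta - eta.mean())
                        denom = cd.denominators(w)
                        max_delta = max(max_delta, abs(d))
                if max_delta < tol:
                    break
            # KKT sweep: bring in violating coordinates
            grad, _ = _grad_all(cd, eta, Xs)
            viol = (~active) & (np.abs(grad / n) > lam * (1 + 1e-9))
            if not viol.any():
                break
            active |= viol
        betas[:, li] = beta
    return betas


def _grad_all(cd: _CoxData, eta, Xs):
    grad, hess = None, None
    c = eta.mean()
    w = np.exp(eta - c)
    denom = cd.denominators(w)
    wx = w[:, None] * Xs
    num = (
        cd._suffix_at_risk(wx)[cd.slot_group]
        - cd.frac[:, None] * cd._tied_sum(wx)[cd.slot_group]
    )
    grad = Xs[cd.event_pos].sum(axis=0) - (num / denom[:, None]).sum(axis=0)
    return grad, hess


def lasso_cox(
    pm_or_X,
    surv: SurvivalData,
    n_folds: int = 10,
    seed: int = 0,
    ties: str = "efron",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    cv_rule: str = "min",
) -> LassoPath:
    """Cross-validated L1-penalized Cox over a log-spaced lambda grid.

    The grid runs from lambda_max (smallest penalty with an all-zero
    solution, i.e. the largest |gradient| of the mean log partial
    likelihood at beta = 0) down to ``lambda_min_ratio * lambda_max``.
    Fold assignment is a pure function of (seed, sample order); the
    selected lambda minimizes the Verweij-van-Houwelingen cross-validated
    partial-likelihood deviance ("lambda.min"; ``cv_rule='1se'`` picks the
    sparsest model within one SE of the minimum).
    """
    if isinstance(pm_or_X, PairMatrix):
        X = pm_or_X.indicators.T.loc[list(surv.sample_ids)]
    else:
        X = pm_or_X.loc[list(surv.sample_ids)]
    names = [str(c) for c in X.columns]
    if len(names) < 2:
        raise ValueError("need at least 2 candidate pairs for the LASSO")
    n_events = int(surv.event.sum())
    if n_events < n_folds:
        raise ValueError(
            f"only {n_events} events for {n_folds} folds; use a smaller n_folds"
        )
    Xa = X.to_numpy(float)
    n = Xa.shape[0]
    time, event = surv.time, surv.event
    cd = _CoxData(time, event, ties)
    Xs = Xa[cd.order]

    grad0, _ = _grad_all(cd, np.zeros(n), Xs)
    lambda_max = np.max(np.abs(grad0)) / n
    lambdas = np.geomspace(lambda_max, lambda_min_ratio * lambda_max, n_lambda)
    betas = _cd_path(cd, Xs, lambdas)

    # k-fold CV: deviance_k(lam) = -2 [ ll_all(b_-k) - ll_train(b_-k) ]
    rng = np.random.default_rng(seed)
    fold = rng.permuted(np.arange(n) % n_folds)
    cvl = np.zeros((n_folds, lambdas.size))
    for k in range(n_folds):
        tr = fold != k
        cd_tr = _CoxData(time[tr], event[tr], ties)
        Xtr = Xa[tr][cd_tr.order]
        b_tr = _cd_path(cd_tr, Xtr, lambdas)
        for li in range(lambdas.size):
            b = b_tr[:, li]
            cvl[k, li] = cd.loglik(Xs @ b) - cd_tr.loglik(Xtr @ b)
    dev = -2.0 * cvl
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    if cv_rule == "1se":
        thresh = cv_mean[i_min] + cv_se[i_min]
        ok = np.nonzero(cv_mean <= thresh)[0]
        i_sel = int(ok[0])  # largest lambda within one SE (grid is descending)
    else:
        i_sel = i_min
    return LassoPath(
        names, lambdas, betas, cv_mean, cv_se, float(lambdas[i_sel]), i_sel, n_folds, seed
    )


# ---------------------------------------------------------------------------
# final model and stratification


@dataclass
class RiskModel:
    """Selected pairs, refit Cox coefficients and the median-score cutoff."""

    pair_ids: list[str]
    coefficients: pd.Series
    cutoff: float
    fit: CoxFit = field(repr=False, default=None)

    def scores(self, pm: PairMatrix) -> pd.Series:
        missing = [p for p in self.pair_ids if p not in pm.indicators.index]
        if missing:
            raise KeyError(f"pair matrix lacks model pair(s): {missing[:5]}")
        ind = pm.indicators.loc[self.pair_ids]
        s = ind.T.to_numpy(float) @ self.coefficients.to_numpy()
        return pd.Series(s, index=pm.sample_ids, name="score")


@dataclass
class RiskStratification:
    """Per-sample RiskScore and low/high label (high iff score > cutoff)."""

    table: pd.DataFrame  # columns: score, group

    @property
    def score(self) -> pd.Series:
        return self.table["score"]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]


def finalize_model(
    selected_pairs, pm: PairMatrix, surv: SurvivalData, ties: str = "efron",
    aic_backward: bool = False,
) -> RiskModel:
    """Unpenalized multivariate Cox refit on the selected pair indicators.

    The cutoff is the median training RiskScore. ``aic_backward`` enables
    backward elimination by AIC after the refit (off by default).
    """
    selected = list(selected_pairs)
    if not selected:
        raise ValueError("empty model: no pairs selected")
    X = pm.indicators.loc[selected].T.loc[list(surv.sample_ids)].astype(float)
    fit = fit_cox(X, surv, ties)
    if aic_backward:
        while len(selected) > 1:
            aic_full = 2 * len(selected) - 2 * fit.loglik
            best = None
            for drop in selected:
                keep = [s for s in selected if s != drop]
                f2 = fit_cox(X[keep], surv, ties)
                aic2 = 2 * len(keep) - 2 * f2.loglik
                if aic2 < aic_full and (best is None or aic2 < best[0]):
                    best = (aic2, keep, f2)
            if best is None:
                break
            _, selected, fit = best
            X = X[selected]
    coef = pd.Series(fit.beta, index=selected, name="coefficient")
    scores = X.to_numpy() @ fit.beta
    cutoff = float(np.median(scores))
    return RiskModel(selected, coef, cutoff, fit)


def risk_score(model: RiskModel, pm: PairMatrix) -> RiskStratification:
    """Score = sum_k coef_k * indicator_k; high iff score > cutoff (ties low)."""
    s = model.scores(pm)
    group = np.where(s.to_numpy() > model.cutoff, "high", "low")
    return RiskStratification(pd.DataFrame({"score": s, "group": group}, index=s.index))
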