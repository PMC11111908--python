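"""Deterministic survival estimators and metrics.

Everything downstream (deep models, ITE calculators, recommendation
evaluation) speaks through the containers defined here. Conventions fixed
package-wide: time is in months, ``event == 1`` means cancer-specific death,
ties in the Cox partial likelihood and the Breslow baseline use the Breslow
approximation, and survival curves are right-continuous step functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "BaselineHazard",
    "CoxFit",
    "LifeTable",
    "neg_log_partial_likelihood",
    "fit_linear_cox",
    "breslow_baseline",
    "predict_curve",
    "kaplan_meier",
    "log_rank",
    "rmst",
    "rmst_diff",
    "median_survival",
    "concordance_index",
    "integrated_brier_score",
    "life_table",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------
@dataclass
class SurvivalCurve:
    """Right-continuous step function S(t) on an ascending grid with S(0)=1.

    ``variance`` optionally carries a pointwise (Greenwood) variance of S.
    For Kaplan–Meier output the distinct event times with their at-risk and
    death counts are attached so that downstream RMST variance can be formed.
    """

    times: np.ndarray
    surv: np.ndarray
    variance: np.ndarray | None = None
    ev_times: np.ndarray | None = field(default=None, repr=False)
    ev_n: np.ndarray | None = field(default=None, repr=False)
    ev_d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        self.validate()

    def validate(self):
        if self.times.ndim != 1 or self.times.shape != self.surv.shape:
            raise ValueError("times and surv must be 1-d arrays of equal length")
        if self.times[0] != 0:
            raise ValueError("grid must start at t=0")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("time grid must be ascending")
        if abs(self.surv[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.surv < -1e-12) | (self.surv > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")

    def evaluate(self, t) -> np.ndarray:
        """S(t) for scalar or array t (right-continuous lookup)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.surv[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "survival": self.surv})
        if self.variance is not None:
            df["variance"] = self.variance
        return df


@dataclass
class BaselineHazard:
    """Cumulative baseline hazard H0 as a step function at distinct event times."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cumhaz = np.asarray(self.cumhaz, dtype=float)
        if np.any(np.diff(self.cumhaz) < -1e-12):
            raise ValueError("cumulative hazard must be non-decreasing")
        if np.any(self.cumhaz < -1e-12):
            raise ValueError("cumulative hazard must be non-negative")

    def evaluate(self, t) -> np.ndarray:
        """H0(t); zero before the first event time."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        out = np.where(idx > 0, self.cumhaz[np.maximum(idx - 1, 0)], 0.0)
        return out


@dataclass
class CoxFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    cov: np.ndarray
    names: list | None = None

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def confint(self, level=0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])


# --------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# --------------------------------------------------------------------------
def _check_surv_args(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if events.sum() == 0:
        raise ValueError("no events in data; partial likelihood undefined")
    return times, events


def neg_log_partial_likelihood(lp, times, events, weights=None) -> float:
    """Negative log Cox partial likelihood, Breslow ties, averaged over events.

    Invariant to adding a constant to all linear predictors.
    """
    lp = np.asarray(lp, dtype=float).ravel()
    times, events = _check_surv_args(times, events)
    w = np.ones_like(lp) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(-times, kind="stable")  # descending time
    lp_o, t_o, e_o, w_o = lp[order], times[order], events[order], w[order]
    shift = lp_o.max()
    risk = np.cumsum(w_o * np.exp(lp_o - shift))
    # tied subjects must share the full risk set: take per-time-group maxima
    uniq, inv = np.unique(-t_o, return_inverse=True)
    grp_last = np.zeros(len(uniq))
    np.maximum.at(grp_last, inv, risk)
    risk_full = grp_last[inv]
    ll = np.sum(w_o * e_o * ((lp_o - shift) - np.log(risk_full)))
    total_ev_w = np.sum(w_o * e_o)
    return float(-ll / total_ev_w)


def _cox_quantities(X, times, events, beta, weights):
    """Weighted Breslow log PL, gradient, Hessian at beta."""
    lp = X @ beta
    order = np.argsort(times, kind="stable")
    Xo, to, eo, wo, lpo = X[order], times[order], events[order], weights[order], lp[order]
    n, p = Xo.shape
    r = wo * np.exp(lpo - lpo.max())
    # suffix sums over risk sets (time >= t)
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum((r[:, None] * Xo)[::-1], axis=0)[::-1]
    S2 = np.cumsum((r[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]))[::-1], axis=0)[::-1]
    # map each subject to the first index of its (tied) time group
    first_idx = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_idx[i] = first_idx[i - 1] if to[i] == to[i - 1] else i
    S0g, S1g, S2g = S0[first_idx], S1[first_idx], S2[first_idx]
    ev = (eo == 1)
    we = wo[ev]
    ll = np.sum(we * ((lpo[ev] - lpo.max()) - np.log(S0g[ev])))
    xbar = S1g[ev] / S0g[ev][:, None]
    grad = (we[:, None] * (Xo[ev] - xbar)).sum(axis=0)
    V = S2g[ev] / S0g[ev][:, None, None] - xbar[:, :, None] * xbar[:, None, :]
    hess = -(we[:, None, None] * V).sum(axis=0)
    return ll, grad, hess, (Xo, to, eo, wo, lpo, S0, S1, first_idx)


def fit_linear_cox(X, times, events, weights=None, names=None,
                   max_iter=100, tol=1e-7) -> CoxFit:
    """Newton–Raphson maximizer of the (weighted) Breslow partial likelihood.

    Robust (sandwich) standard errors are reported whenever weights are
    supplied; model-based otherwise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and len(np.asarray(times)) != 1:
        X = X.T
    times, events = _check_surv_args(times, events)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant column in design matrix")
    robust = weights is not None
    w = np.ones(len(times)) if weights is None else np.asarray(weights, dtype=float)
    beta = np.zeros(X.shape[1])
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, hess, _ = _cox_quantities(X, times, events, beta, w)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular information matrix in Cox fit (beta={beta})") from exc
        beta_new = beta - step
        if np.abs(beta_new).max() > 50:
            beta = beta_new  # likely separation / monotone likelihood
            break
        beta = beta_new
        if np.abs(grad).max() < tol:
            converged = True
            break
    ll, grad, hess, parts = _cox_quantities(X, times, events, beta, w)
    converged = converged or np.abs(grad).max() < tol
    info_inv = np.linalg.inv(-hess)
    if robust:
        U = _score_residuals(parts, beta)
        meat = U.T @ U
        cov = info_inv @ meat @ info_inv
    else:
        cov = info_inv
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return CoxFit(coef=beta, se=se, loglik=float(ll), converged=bool(converged),
                  cov=cov, names=list(names) if names is not None else None)


def _score_residuals(parts, beta):
    """Weighted per-subject score residuals for the sandwich estimator."""
    Xo, to, eo, wo, lpo, S0, S1, first_idx = parts
    n, p = Xo.shape
    S0g = S0[first_idx]
    S1g = S1[first_idx]
    ev_idx = np.where(eo == 1)[0]
    xbar = S1g[ev_idx] / S0g[ev_idx][:, None]
    dN_term = np.zeros((n, p))
    dN_term[ev_idx] = wo[ev_idx, None] * (Xo[ev_idx] - xbar)
    # compensator: for each subject i, sum over event times t_k <= t_i of
    #   w_i e^{lp_i} * (x_i - xbar_k) * w_k / S0_k
    r_i = wo * np.exp(lpo - lpo.max())
    S0e = S0g[ev_idx]
    we = wo[ev_idx]
    cum_a = np.cumsum(we / S0e)                      # scalar part
    cum_b = np.cumsum(we[:, None] * xbar / S0e[:, None], axis=0)  # vector part
    # event index count for each subject's time (events with time <= t_i)
    ev_times = to[ev_idx]
    k = np.searchsorted(ev_times, to, side="right")
    a = np.where(k > 0, cum_a[np.maximum(k - 1, 0)], 0.0)
    b = np.zeros((n, p))
    b[k > 0] = cum_b[k[k > 0] - 1]
    comp = r_i[:, None] * (Xo * a[:, None] - b)
    return dN_term - comp


def breslow_baseline(lp, times, events, weights=None) -> BaselineHazard:
    """Breslow estimator of the cumulative baseline hazard.

    dH0(t_k) = d_k / sum_{j in risk(t_k)} w_j exp(lp_j) at each distinct
    event time t_k (with d_k the weighted death count).
    """
    lp = np.asarray(lp, dtype=float).ravel()
    if lp.size == 0:
        raise ValueError("empty input")
    times, events = _check_surv_args(times, events)
    w = np.ones_like(lp) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(times, kind="stable")
    to, eo, wo, lpo = times[order], events[order], w[order], lp[order]
    r = wo * np.exp(lpo)
    S0 = np.cumsum(r[::-1])[::-1]
    first_idx = np.zeros(len(to), dtype=int)
    for i in range(1, len(to)):
        first_idx[i] = first_idx[i - 1] if to[i] == to[i - 1] else i
    ev_times, steps = [], []
    i = 0
    n = len(to)
    while i < n:
        j = i
        d = 0.0
        while j < n and to[j] == to[i]:
            if eo[j] == 1:
                d += wo[j]
            j += 1
        if d > 0:
            ev_times.append(to[i])
            steps.append(d / S0[first_idx[i]])
        i = j
    return BaselineHazard(np.array(ev_times), np.cumsum(steps))


def predict_curve(lp_value: float, baseline: BaselineHazard, grid) -> SurvivalCurve:
    """Individual survival curve S(t) = exp(-H0(t) * e^lp) on a grid."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] != 0:
        grid = np.concatenate([[0.0], grid])
    H = baseline.evaluate(grid)
    S = np.exp(-H * np.exp(lp_value))
    return SurvivalCurve(grid, S)


# --------------------------------------------------------------------------
# nonparametric estimators
# --------------------------------------------------------------------------
def _event_table(times, events, weights):
    order = np.argsort(times, kind="stable")
    to, eo, wo = times[order], events[order], weights[order]
    uniq = np.unique(to)
    n_at_risk, d, c = [], [], []
    total = wo.sum()
    removed = 0.0
    for t in uniq:
        mask = to == t
        n_at_risk.append(total - removed)
        d.append(wo[mask & (eo == 1)].sum() if mask.any() else 0.0)
        c.append(wo[mask & (eo == 0)].sum() if mask.any() else 0.0)
        removed += wo[mask].sum()
    return uniq, np.array(n_at_risk), np.array(d), np.array(c)


def kaplan_meier(times, events, weights=None) -> SurvivalCurve:
    """Product-limit estimator with Greenwood pointwise variance.

    Accepts optional case weights (e.g. IPTW); the Greenwood formula is then
    the plug-in with weighted counts.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty data")
    w = np.ones_like(times) if weights is None else np.asarray(weights, dtype=float)
    uniq, n_at_risk, d, _ = _event_table(times, events, w)
    has_event = d > 0
    ev_t, ev_n, ev_d = uniq[has_event], n_at_risk[has_event], d[has_event]
    frac = 1.0 - ev_d / ev_n
    S_steps = np.cumprod(frac)
    denom = ev_n * (ev_n - ev_d)
    gw_terms = np.divide(ev_d, denom, out=np.zeros_like(denom, dtype=float),
                         where=denom > 0)
    gw = np.cumsum(gw_terms)
    var_steps = S_steps**2 * gw
    tmax = times.max()
    grid = np.concatenate([[0.0], ev_t])
    surv = np.concatenate([[1.0], S_steps])
    var = np.concatenate([[0.0], var_steps])
    if len(ev_t) == 0 or ev_t[-1] < tmax:
        grid = np.concatenate([grid, [tmax]])
        surv = np.concatenate([surv, [surv[-1]]])
        var = np.concatenate([var, [var[-1]]])
    return SurvivalCurve(grid, np.clip(surv, 0, 1), variance=var,
                         ev_times=ev_t, ev_n=ev_n, ev_d=ev_d)


def log_rank(timesA, eventsA, timesB, eventsB, weightsA=None, weightsB=None):
    """Two-group log-rank test; returns (chi2, p). Symmetric in the groups."""
    tA = np.asarray(timesA, dtype=float)
    tB = np.asarray(timesB, dtype=float)
    eA = np.asarray(eventsA, dtype=int)
    eB = np.asarray(eventsB, dtype=int)
    if len(tA) == 0 or len(tB) == 0:
        raise ValueError("both groups must be non-empty")
    if eA.sum() + eB.sum() == 0:
        raise ValueError("no events overall; log-rank statistic undefined")
    wA = np.ones_like(tA) if weightsA is None else np.asarray(weightsA, dtype=float)
    wB = np.ones_like(tB) if weightsB is None else np.asarray(weightsB, dtype=float)
    all_ev_times = np.unique(np.concatenate([tA[eA == 1], tB[eB == 1]]))
    O_minus_E = 0.0
    V = 0.0
    for t in all_ev_times:
        nA = wA[tA >= t].sum()
        nB = wB[tB >= t].sum()
        dA = wA[(tA == t) & (eA == 1)].sum()
        dB = wB[(tB == t) & (eB == 1)].sum()
        n, dtot = nA + nB, dA + dB
        if n <= 1 or dtot == 0:
            continue
        E_A = dtot * nA / n
        O_minus_E += dA - E_A
        V += dtot * (nA / n) * (nB / n) * (n - dtot) / max(n - 1, 1e-12)
    if V <= 0:
        return 0.0, 1.0
    chi2 = O_minus_E**2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def rmst(curve: SurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: exact step-function integral of S on [0, tau]."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if tau > curve.times[-1] + 1e-9 and curve.surv[-1] > 0:
        # beyond the grid the step function is only determined once S hits 0
        raise ValueError(f"tau={tau} beyond curve grid (max {curve.times[-1]}); no extrapolation")
    t = curve.times
    s = curve.surv
    keep = t < tau
    knots = np.concatenate([t[keep], [tau]])
    vals = s[keep]
    return float(np.sum(vals * np.diff(knots)))


def _rmst_variance(curve: SurvivalCurve, tau: float) -> float:
    """Integrated Greenwood variance of the KM RMST estimate."""
    if curve.ev_times is None:
        raise ValueError("curve lacks event-table info (not a KM curve)")
    ev_t, ev_n, ev_d = curve.ev_times, curve.ev_n, curve.ev_d
    var = 0.0
    for tj, nj, dj in zip(ev_t, ev_n, ev_d):
        if tj >= tau or nj <= dj:
            continue
        # area under S from tj to tau
        t = np.clip(curve.times, tj, tau)
        area = np.sum(curve.surv[:-1] * np.diff(t)) if len(t) > 1 else 0.0
        var += area**2 * dj / (nj * (nj - dj))
    return var


def rmst_diff(kmA: SurvivalCurve, kmB: SurvivalCurve, tau: float, level=0.95):
    """RMST_A - RMST_B with a normal CI from summed integrated Greenwood variances."""
    est = rmst(kmA, tau) - rmst(kmB, tau)
    var = _rmst_variance(kmA, tau) + _rmst_variance(kmB, tau)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return float(est), (float(est - half), float(est + half))


def median_survival(curve: SurvivalCurve):
    """First grid time with S(t) <= 0.5; (time, True) or (inf, False) if not reached."""
    idx = np.where(curve.surv <= 0.5)[0]
    if len(idx) == 0:
        return float("inf"), False
    return float(curve.times[idx[0]]), True


def concordance_index(lp, times, events, n_boot=0, seed=0, level=0.95):
    """Harrell's C: concordant / comparable pairs, ties in lp credited 0.5.

    Higher lp means higher risk (shorter survival). Returns c or
    (c, (lo, hi)) when a bootstrap CI is requested.
    """
    lp = np.asarray(lp, dtype=float).ravel()
    times, events = _check_surv_args(times, events)
    if len(lp) < 2:
        raise ValueError("need at least two subjects")

    def _c(lp, t, e):
        conc = comp = 0.0
        # pair (i, j) comparable if t_i < t_j and e_i == 1, or t_i == t_j
        # with exactly one event (the censored subject outlives the death)
        dt = t[:, None] - t[None, :]
        ei = e[:, None]
        ej = e[None, :]
        comparable = ((dt < 0) & (ei == 1)) | ((dt == 0) & (ei == 1) & (ej == 0))
        dl = lp[:, None] - lp[None, :]
        conc = np.sum(comparable * ((dl > 0) + 0.5 * (dl == 0)))
        comp = comparable.sum()
        if comp == 0:
            raise ValueError("no comparable pairs; C-index undefined")
        return conc / comp

    c = float(_c(lp, times, events))
    if n_boot <= 0:
        return c
    rng = np.random.default_rng(seed)
    n = len(lp)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps.append(_c(lp[idx], times[idx], events[idx]))
        except ValueError:
            continue
    lo, hi = np.percentile(reps, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return c, (float(lo), float(hi))


def integrated_brier_score(surv_matrix, grid, times, events, tau):
    """Graf IPCW integrated Brier score over [0, tau].

    ``surv_matrix`` is (n_subjects, len(grid)) of predicted S_i(t) on
    ``grid``. The censoring distribution G is the KM of censoring times;
    if G reaches 0 before tau the integration grid is truncated with a
    warning.
    """
    surv_matrix = np.asarray(surv_matrix, dtype=float)
    grid = np.asarray(grid, dtype=float)
    times, events = _check_surv_args(times, events)
    n = len(times)
    cens_km = kaplan_meier(times, 1 - events) if (1 - events).sum() > 0 else None

    def G(t):
        if cens_km is None:
            return np.ones_like(np.asarray(t, dtype=float))
        return cens_km.evaluate(t)

    eval_times = np.unique(times[events == 1])
    eval_times = eval_times[eval_times <= tau]
    if tau not in eval_times:
        eval_times = np.append(eval_times, tau)
    Gvals = G(eval_times)
    if np.any(Gvals <= 0):
        warnings.warn("censoring KM reaches 0 before tau; truncating IBS grid")
        eval_times = eval_times[Gvals > 0]
        if len(eval_times) < 2:
            raise ValueError("too few usable time points for IBS")

    # interpolate predictions at eval times (step lookup on provided grid)
    idx = np.clip(np.searchsorted(grid, eval_times, side="right") - 1, 0, len(grid) - 1)
    S_at = surv_matrix[:, idx]  # (n, T)
    G_tm = G(np.maximum(times - 1e-9, 0.0))  # G(T_i-)
    bs = np.zeros(len(eval_times))
    for k, t in enumerate(eval_times):
        died = (times <= t) & (events == 1)
        alive = times > t
        contrib = np.zeros(n)
        contrib[died] = S_at[died, k] ** 2 / np.maximum(G_tm[died], 1e-12)
        contrib[alive] = (1 - S_at[alive, k]) ** 2 / max(G(t), 1e-12)
        bs[k] = contrib.sum() / n
    return float(np.trapezoid(bs, eval_times) / (eval_times[-1] - eval_times[0]))


@dataclass
class LifeTable:
    table: pd.DataFrame

    def survival_at(self, t: float, level=0.95):
        """Cumulative survival at time t with a normal CI."""
        rows = self.table[self.table["end"] <= t + 1e-9]
        if len(rows) == 0:
            return 1.0, (1.0, 1.0)
        S = float(rows["cum_survival"].iloc[-1])
        se = float(rows["se"].iloc[-1])
        z = stats.norm.ppf(0.5 + level / 2)
        return S, (max(S - z * se, 0.0), min(S + z * se, 1.0))


def life_table(times, events, interval_width: float = 1.0, horizon=None) -> LifeTable:
    """Actuarial life table with the half-interval censoring correction.

    Effective exposure n' = n - c/2 per interval; q = d / n'. Variance of the
    cumulative survival by the Greenwood-type accumulation.
    """
    if interval_width <= 0:
        raise ValueError("interval_width must be positive")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    horizon = horizon if horizon is not None else times.max()
    n_int = int(np.ceil(horizon / interval_width + 1e-9))
    rows = []
    S = 1.0
    gw = 0.0
    n_enter = len(times)
    for k in range(n_int):
        lo, hi = k * interval_width, (k + 1) * interval_width
        in_int = (times >= lo) & (times < hi)
        d = int(np.sum(in_int & (events == 1)))
        c = int(np.sum(in_int & (events == 0)))
        n_eff = n_enter - c / 2.0
        q = d / n_eff if n_eff > 0 else 0.0
        S *= 1.0 - q
        if n_eff > d and d > 0:
            gw += d / (n_eff * (n_eff - d))
        rows.append({"start": lo, "end": hi, "n_enter": n_enter, "deaths": d,
                     "censored": c, "n_effective": n_eff, "q": q,
                     "cum_survival": S, "se": S * np.sqrt(gw)})
        n_enter -= d + c
        if n_enter <= 0:
            break
    return LifeTable(pd.DataFrame(rows))
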