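"""Cohort-level evaluation of treatment recommendations.

Patients whose actual surgery matches the model's recommendation form the
Rec group; the rest form the Anti-rec group. The recommendation is judged by
whether Rec enjoys better brain-cancer-specific survival: difference in
restricted mean survival time (dRMST) and the Cox hazard ratio are the two
core metrics, supported by per-group median survival, the life-table 5-year
survival probability, and the log-rank test. Because group membership is
not randomized, inverse-probability-of-treatment weighting (IPTW) on the
baseline covariates and a counterfactual mediation analysis (treatment as
the mediator between recommendation and death) probe whether the apparent
benefit survives confounding adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .recommenders import FeatureEncoder, _as_df
from .survival import fit_linear_cox, kaplan_meier, life_table, log_rank, median_survival, rmst, rmst_diff

__all__ = ["GroupAssignment", "EvalReport", "IPTWWeights", "MediationResult",
           "assign_groups", "evaluate_recommendation", "fit_iptw",
           "standardized_mean_differences", "iptw_adjusted_hr",
           "iptw_adjusted_or", "mediation_nde_cde", "behavior_logistic",
           "DEFAULT_IPTW_COVARIATES", "mortality_at"]

# the baseline adjustment set: demographics and tumor characteristics,
# excluding treatment (measured after the exposure of interest)
DEFAULT_IPTW_COVARIATES = ["age", "race", "married", "income", "region",
                           "location", "laterality", "extension",
                           "tumor_size", "metastasis"]


@dataclass
class GroupAssignment:
    actual: np.ndarray
    recommended: np.ndarray
    group: np.ndarray            # "Rec" / "Anti-rec"
    consistency_rate: float


@dataclass
class EvalReport:
    n_rec: int
    n_anti: int
    consistency_rate: float
    drmst: float
    drmst_ci: tuple
    hr: float
    hr_ci: tuple
    logrank_p: float
    rmst_rec: float
    rmst_rec_ci: tuple
    rmst_anti: float
    rmst_anti_ci: tuple
    mst_rec: float
    mst_anti: float
    sat_rec: float
    sat_rec_ci: tuple
    sat_anti: float
    sat_anti_ci: tuple
    tau: float
    arm_metrics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class IPTWWeights:
    propensity: np.ndarray
    weights: np.ndarray
    truncation_bounds: tuple


@dataclass
class MediationResult:
    total_effect: float
    total_ci: tuple
    nde: float
    nde_ci: tuple
    cde: float
    cde_ci: tuple


def mortality_at(times, events, horizon: float = 60.0) -> np.ndarray:
    """Binary death-by-horizon endpoint; censored-before-horizon counts as alive."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    return ((events == 1) & (times <= horizon)).astype(int)


def assign_groups(actual, recommended) -> GroupAssignment:
    """Label each patient Rec (actual == recommended) or Anti-rec."""
    actual = np.asarray(actual)
    recommended = np.asarray(recommended)
    if actual.shape != recommended.shape:
        raise ValueError("actual and recommended arms must have equal length")
    rec = actual == recommended
    group = np.where(rec, "Rec", "Anti-rec")
    return GroupAssignment(actual, recommended, group, float(rec.mean()))


def evaluate_recommendation(data, groups: GroupAssignment, tau: float = 60.0,
                            arm_metrics: dict | None = None) -> EvalReport:
    """Rec vs Anti-rec survival comparison: dRMST, HR, MST, SaT, log-rank."""
    df = _as_df(data)
    times = df["time"].to_numpy(float)
    events = df["event"].to_numpy(int)
    g = groups.group
    m_rec, m_anti = g == "Rec", g == "Anti-rec"
    if m_rec.sum() == 0 or m_anti.sum() == 0:
        raise ValueError("degenerate grouping: one of Rec/Anti-rec is empty")
    if events[m_rec].sum() == 0 or events[m_anti].sum() == 0:
        raise ValueError("a recommendation group has no events")
    km_rec = kaplan_meier(times[m_rec], events[m_rec])
    km_anti = kaplan_meier(times[m_anti], events[m_anti])
    tau_eff = min(tau, km_rec.times[-1], km_anti.times[-1])
    dr, dr_ci = rmst_diff(km_rec, km_anti, tau_eff)
    cox = fit_linear_cox(m_rec.astype(float).reshape(-1, 1), times, events,
                         names=["rec"])
    hr = float(np.exp(cox.coef[0]))
    hr_ci = tuple(np.exp(cox.confint()[0]))
    chi2, p = log_rank(times[m_rec], events[m_rec], times[m_anti], events[m_anti])

    def group_summary(mask, km):
        r = rmst(km, tau_eff)
        z = stats.norm.ppf(0.975)
        from .survival import _rmst_variance
        half = z * np.sqrt(_rmst_variance(km, tau_eff))
        mst, _ = median_survival(km)
        lt = life_table(times[mask], events[mask], 1.0, horizon=tau)
        sat, sat_ci = lt.survival_at(min(tau, 60.0))
        return r, (r - half, r + half), mst, sat, sat_ci

    r_r, rci_r, mst_r, sat_r, satci_r = group_summary(m_rec, km_rec)
    r_a, rci_a, mst_a, sat_a, satci_a = group_summary(m_anti, km_anti)
    return EvalReport(
        n_rec=int(m_rec.sum()), n_anti=int(m_anti.sum()),
        consistency_rate=groups.consistency_rate,
        drmst=dr, drmst_ci=dr_ci, hr=hr, hr_ci=hr_ci, logrank_p=p,
        rmst_rec=r_r, rmst_rec_ci=rci_r, rmst_anti=r_a, rmst_anti_ci=rci_a,
        mst_rec=mst_r, mst_anti=mst_a,
        sat_rec=sat_r, sat_rec_ci=satci_r, sat_anti=sat_a, sat_anti_ci=satci_a,
        tau=tau_eff, arm_metrics=arm_metrics or {})


# --------------------------------------------------------------------------
# IPTW
# --------------------------------------------------------------------------
def _design_for(df: pd.DataFrame, covariate_cols) -> tuple:
    """Design matrix over exactly the requested covariates.

    Categorical schema columns are one-hot encoded against their reference
    level; continuous columns are z-scored; binaries pass through.
    """
    from .synthetic import SCHEMA
    from .recommenders import REFERENCES
    if "treatment" in covariate_cols:
        raise ValueError("treatment must not appear in the IPTW adjustment set "
                         "(it is measured after the exposure)")
    cols, names = [], []
    for col in covariate_cols:
        if col not in df.columns:
            raise KeyError(f"covariate column {col!r} missing from data")
        if col in SCHEMA:
            ref = REFERENCES.get(col, SCHEMA[col][0])
            for lev in SCHEMA[col]:
                if lev != ref:
                    cols.append((df[col] == lev).to_numpy(float))
                    names.append(f"{col}_{lev}")
        else:
            x = df[col].to_numpy(float)
            if len(np.unique(x)) > 2:
                sd = x.std() or 1.0
                x = (x - x.mean()) / sd
            cols.append(x)
            names.append(col)
    X = np.column_stack(cols)
    keep = X.std(axis=0) > 0
    return X[:, keep], [n for n, k in zip(names, keep) if k]


def fit_iptw(data, groups, covariate_cols=None, truncation=(1.0, 99.0)) -> IPTWWeights:
    """Stabilized inverse-probability weights for Rec-group membership.

    Logistic propensity of the group label on the baseline covariates
    (treatment excluded by contract); weights are marginal prevalence over
    propensity of the observed group, truncated at the given percentiles.
    """
    df = _as_df(data)
    g = groups.group if isinstance(groups, GroupAssignment) else np.asarray(groups)
    y = (g == "Rec").astype(int) if g.dtype.kind in "OUS" else g.astype(int)
    covariate_cols = DEFAULT_IPTW_COVARIATES if covariate_cols is None else covariate_cols
    X, _ = _design_for(df, covariate_cols)
    Xc = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise np.linalg.LinAlgError("unstable propensity fit")
        ps = np.asarray(res.predict(Xc))
    except Exception:
        warnings.warn("propensity model unstable (possible separation); "
                      "refitting with an L2-penalized logistic model")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=1000).fit(X, y)
        ps = lr.predict_proba(X)[:, 1]
    ps = np.clip(ps, 1e-6, 1 - 1e-6)
    prev = y.mean()
    w = np.where(y == 1, prev / ps, (1 - prev) / (1 - ps))
    lo, hi = np.percentile(w, truncation)
    return IPTWWeights(ps, np.clip(w, lo, hi), (float(lo), float(hi)))


def standardized_mean_differences(data, groups, covariate_cols=None,
                                  weights=None) -> pd.Series:
    """Absolute standardized mean difference per encoded covariate column."""
    df = _as_df(data)
    g = groups.group if isinstance(groups, GroupAssignment) else np.asarray(groups)
    y = (g == "Rec").astype(int) if g.dtype.kind in "OUS" else g.astype(int)
    covariate_cols = DEFAULT_IPTW_COVARIATES if covariate_cols is None else covariate_cols
    X, names = _design_for(df, covariate_cols)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for j, name in enumerate(names):
        x = X[:, j]
        m1 = np.average(x[y == 1], weights=w[y == 1])
        m0 = np.average(x[y == 0], weights=w[y == 0])
        v1 = np.average((x[y == 1] - m1) ** 2, weights=w[y == 1])
        v0 = np.average((x[y == 0] - m0) ** 2, weights=w[y == 0])
        denom = np.sqrt((v1 + v0) / 2)
        out[name] = abs(m1 - m0) / denom if denom > 0 else 0.0
    return pd.Series(out)


def iptw_adjusted_hr(data, groups, weights: IPTWWeights | np.ndarray):
    """Weighted Cox HR (Rec vs Anti-rec) with robust sandwich CI."""
    df = _as_df(data)
    g = groups.group if isinstance(groups, GroupAssignment) else np.asarray(groups)
    y = (g == "Rec").astype(float)
    w = weights.weights if isinstance(weights, IPTWWeights) else np.asarray(weights)
    cox = fit_linear_cox(y.reshape(-1, 1), df["time"].to_numpy(float),
                         df["event"].to_numpy(int), weights=w, names=["rec"])
    return float(np.exp(cox.coef[0])), tuple(np.exp(cox.confint()[0]))


def iptw_adjusted_or(mortality, groups, weights: IPTWWeights | np.ndarray):
    """Weighted logistic OR (Rec vs Anti-rec) for horizon mortality, robust CI."""
    y = np.asarray(mortality, dtype=int)
    g = groups.group if isinstance(groups, GroupAssignment) else np.asarray(groups)
    a = (g == "Rec").astype(float)
    w = weights.weights if isinstance(weights, IPTWWeights) else np.asarray(weights)
    Xc = sm.add_constant(a)
    res = sm.GLM(y, Xc, family=sm.families.Binomial(), freq_weights=w).fit(cov_type="HC1")
    coef = res.params[1]
    ci = res.conf_int()[1]
    return float(np.exp(coef)), (float(np.exp(ci[0])), float(np.exp(ci[1])))


# --------------------------------------------------------------------------
# mediation
# --------------------------------------------------------------------------
def _fit_logit(y, X):
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 30:
            raise np.linalg.LinAlgError
        return lambda Z: np.asarray(res.predict(sm.add_constant(Z, has_constant="add")))
    except Exception:
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=10.0, max_iter=1000).fit(X, y)
        return lambda Z: lr.predict_proba(Z)[:, 1]


def mediation_nde_cde(outcome, exposure, mediator, covariates,
                      n_boot: int = 500, seed: int = 0) -> MediationResult:
    """Regression-based counterfactual mediation on the risk-difference scale.

    Outcome model: logistic Y ~ A + M + X; mediator model: logistic
    M ~ A + X. NDE contrasts exposure levels with the mediator drawn from
    its distribution under the exposure reference (A=0); CDE fixes the
    mediator at its reference level (M=0). Percentile bootstrap CIs.
    """
    y = np.asarray(outcome, dtype=int)
    a = np.asarray(exposure, dtype=int)
    m = np.asarray(mediator, dtype=int)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    for name, v in (("outcome", y), ("exposure", a), ("mediator", m)):
        if not set(np.unique(v)) <= {0, 1}:
            raise ValueError(f"{name} must be binary 0/1")

    def estimates(y, a, m, X):
        out_model = _fit_logit(y, np.column_stack([a, m, X]))
        med_model = _fit_logit(m, np.column_stack([a, X]))
        n = len(y)
        ones, zeros = np.ones(n), np.zeros(n)
        p_m1_a0 = med_model(np.column_stack([zeros, X]))
        p_m1_a1 = med_model(np.column_stack([ones, X]))

        def py(avec, mvec):
            return out_model(np.column_stack([avec, mvec, X]))

        # NDE: mediator at its A=0 distribution
        y1 = py(ones, zeros) * (1 - p_m1_a0) + py(ones, ones) * p_m1_a0
        y0 = py(zeros, zeros) * (1 - p_m1_a0) + py(zeros, ones) * p_m1_a0
        nde = float(np.mean(y1 - y0))
        # CDE: mediator fixed at reference (M=0)
        cde = float(np.mean(py(ones, zeros) - py(zeros, zeros)))
        # total effect: mediator follows its own exposure-specific distribution
        t1 = py(ones, zeros) * (1 - p_m1_a1) + py(ones, ones) * p_m1_a1
        t0 = y0
        te = float(np.mean(t1 - t0))
        return te, nde, cde

    te, nde, cde = estimates(y, a, m, X)
    rng = np.random.default_rng(seed)
    reps = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(a[idx])) < 2 or len(np.unique(m[idx])) < 2:
            continue
        try:
            reps.append(estimates(y[idx], a[idx], m[idx], X[idx]))
        except Exception:
            continue
    reps = np.asarray(reps)
    cis = [tuple(np.percentile(reps[:, k], [2.5, 97.5])) for k in range(3)]
    return MediationResult(te, cis[0], nde, cis[1], cde, cis[2])


# --------------------------------------------------------------------------
# recommendation-behavior regression
# --------------------------------------------------------------------------
def behavior_logistic(data, recommendations, covariate_cols=None) -> pd.DataFrame:
    """Multivariable logistic OR per covariate for being recommended SpTR."""
    df = _as_df(data)
    rec = np.asarray(recommendations)
    y = (rec == "SpTR").astype(int) if rec.dtype.kind in "OUS" else rec.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("recommendation is constant; logistic model degenerate")
    cols = covariate_cols if covariate_cols is not None else \
        ["age", "sex", "race", "married", "urban", "income", "region", "location",
         "laterality", "extension", "tumor_size", "metastasis"]
    X, names = _design_for(df, cols)
    Xc = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.abs(res.params).max() > 30:
            raise np.linalg.LinAlgError
        coefs = res.params[1:]
        ses = res.bse[1:]
    except Exception:
        warnings.warn("separation in behavior regression; using L2-penalized fit "
                      "(CIs from penalized curvature are approximate)")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1.0, max_iter=1000).fit(X, y)
        coefs = lr.coef_.ravel()
        p = lr.predict_proba(X)[:, 1]
        W = p * (1 - p)
        info = (X * W[:, None]).T @ X + np.eye(X.shape[1])
        ses = np.sqrt(np.diag(np.linalg.inv(info)))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame({
        "feature": names,
        "odds_ratio": np.exp(coefs),
        "or_low": np.exp(coefs - z * ses),
        "or_high": np.exp(coefs + z * ses),
    })
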