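"""Time-dependent Shapley explanations on the survival-function scale.

For a predictor x -> S(t | x) evaluated on a time grid, each feature
receives an attribution curve phi_j(t) such that, at every grid time,
baseline(t) + sum_j phi_j(t) equals the model's predicted survival for the
explained instance (local accuracy). The value function is the marginal
(interventional) expectation: features outside a coalition are replaced by
background-sample draws. Coalitions are enumerated exactly for up to 10
features; otherwise a kernel-weighted least-squares solution over a shared
sampled coalition set is used, one solve per grid time.

Feature importance for an observation is the time-integral of |phi_j(t)|;
rankings are aggregated across observations into per-rank-position counts,
the bar-chart summary used to compare variables across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
import pandas as pd

__all__ = ["TimeAttribution", "ImportanceRanking", "survshap_t",
           "aggregate_importance", "curve_predictor"]

_EXACT_LIMIT = 10


@dataclass
class TimeAttribution:
    features: list
    times: np.ndarray
    values: np.ndarray          # (n_features, n_times)
    baseline: np.ndarray        # (n_times,) background-average prediction
    prediction: np.ndarray      # (n_times,) model output for the instance
    residual: np.ndarray        # prediction - baseline - sum(values)

    def to_long(self, observation=0) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.features):
            for k, t in enumerate(self.times):
                rows.append({"observation": observation, "feature": f,
                             "time": t, "value": self.values[i, k]})
        return pd.DataFrame(rows)


@dataclass
class ImportanceRanking:
    features: list
    mean_importance: np.ndarray      # (n_features,)
    rank_counts: np.ndarray          # (n_features, n_ranks) counts per position
    n_observations: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rank_counts,
                          columns=[f"rank_{r + 1}" for r in range(self.rank_counts.shape[1])])
        df.insert(0, "feature", self.features)
        df.insert(1, "mean_importance", self.mean_importance)
        return df


def curve_predictor(model, arm: str, grid):
    """Adapt a fitted recommender to the x -> S(t) predictor contract.

    The treatment arm is not an explained feature: it selects the risk head
    and baseline hazard, and explanations are computed per arm.
    """
    from .recommenders import predict_lp

    grid = np.asarray(grid, dtype=float)

    def f(df: pd.DataFrame) -> np.ndarray:
        lps = predict_lp(model, df, arm)
        H = model.baselines[arm].evaluate(grid)
        return np.exp(-np.outer(np.exp(lps), H))

    return f


def survshap_t(predict_fn, background: pd.DataFrame, instance, grid,
               features=None, n_coalitions=None, seed: int = 0) -> TimeAttribution:
    """Shapley attribution curves for one instance.

    ``predict_fn`` maps a covariate DataFrame to an (n, len(grid)) survival
    matrix. Exact coalition enumeration when the feature count allows it;
    otherwise a kernel-weighted least-squares solution with ``n_coalitions``
    sampled coalitions shared across grid times.
    """
    if len(background) == 0:
        raise ValueError("background sample must be non-empty")
    grid = np.asarray(grid, dtype=float)
    inst = instance.to_frame().T if isinstance(instance, pd.Series) else instance
    if isinstance(inst, dict):
        inst = pd.DataFrame([inst])
    inst = inst.reset_index(drop=True)
    features = list(features) if features is not None else list(background.columns)
    p = len(features)
    exact = n_coalitions is None and p <= _EXACT_LIMIT
    if not exact and n_coalitions is not None and n_coalitions < p + 2:
        raise ValueError("n_coalitions must be at least n_features + 2")
    if not exact and n_coalitions is None:
        raise ValueError(f"{p} features exceed the exact-enumeration limit "
                         f"({_EXACT_LIMIT}); pass n_coalitions")

    if exact:
        masks = np.array([[(c >> j) & 1 for j in range(p)] for c in range(2 ** p)],
                         dtype=bool)
    else:
        rng = np.random.default_rng(seed)
        masks = rng.integers(0, 2, size=(n_coalitions, p)).astype(bool)
        masks[0, :] = False
        masks[1, :] = True

    # value function: mean prediction over background with coalition features
    # set to the instance's values
    B = len(background)
    frames = []
    for mk in masks:
        mixed = background.copy().reset_index(drop=True)
        for j, f in enumerate(features):
            if mk[j]:
                mixed[f] = inst[f].iloc[0]
        frames.append(mixed)
    big = pd.concat(frames, ignore_index=True)
    preds = predict_fn(big)                      # (n_masks * B, T)
    v = preds.reshape(len(masks), B, len(grid)).mean(axis=1)   # (n_masks, T)

    baseline = v[int(np.where(~masks.any(axis=1))[0][0])] if exact else v[0]
    full_row = np.where(masks.all(axis=1))[0]
    prediction = v[int(full_row[0])] if len(full_row) else predict_fn(inst)[0]

    if exact:
        phi = _exact_shapley(masks, v, p)
    else:
        phi = _kernel_shapley(masks, v, p, baseline, prediction)
    residual = prediction - baseline - phi.sum(axis=0)
    return TimeAttribution(features, grid, phi, baseline, prediction, residual)


def _exact_shapley(masks, v, p):
    idx = {tuple(mk.tolist()): i for i, mk in enumerate(masks)}
    phi = np.zeros((p, v.shape[1]))
    fact = [factorial(k) for k in range(p + 1)]
    for j in range(p):
        for mk_t, i in idx.items():
            if mk_t[j]:
                continue
            s = sum(mk_t)
            w = fact[s] * fact[p - s - 1] / fact[p]
            with_j = list(mk_t)
            with_j[j] = 1
            phi[j] += w * (v[idx[tuple(with_j)]] - v[i])
    return phi


def _kernel_shapley(masks, v, p, baseline, prediction):
    """Constrained weighted least squares per grid time (shared coalitions)."""
    sizes = masks.sum(axis=1)
    w = np.zeros(len(masks))
    for i, s in enumerate(sizes):
        if 0 < s < p:
            w[i] = (p - 1) / (comb(p, s) * s * (p - s))
    interior = w > 0
    Z = masks[interior].astype(float)
    W = w[interior]
    y = v[interior] - baseline[None, :]
    # efficiency constraint sum(phi) = prediction - baseline via elimination
    Zr = Z[:, :-1] - Z[:, -1:][:, [0] * (p - 1)] if p > 1 else Z
    total = prediction - baseline
    yr = y - Z[:, -1:] * total[None, :]
    A = Zr * W[:, None]
    G = Zr.T @ A + 1e-10 * np.eye(max(p - 1, 1))
    phi = np.zeros((p, v.shape[1]))
    sol = np.linalg.solve(G, A.T @ yr)
    if p > 1:
        phi[:-1] = sol
        phi[-1] = total - sol.sum(axis=0)
    else:
        phi[0] = total
    return phi


def aggregate_importance(attributions: list) -> ImportanceRanking:
    """Aggregate per-observation rankings of time-integrated |attribution|.

    Per observation, importance_j = step integral of |phi_j(t)| over the
    grid; features are ranked descending (ties broken by stable feature
    order) and the count of observations placing each feature at each rank
    position is tabulated.
    """
    if not attributions:
        raise ValueError("no attributions to aggregate")
    feats = attributions[0].features
    times = attributions[0].times
    for att in attributions:
        if att.features != feats or not np.array_equal(att.times, times):
            raise ValueError("attributions must share feature set and time grid")
    p = len(feats)
    dt = np.diff(times)
    imp = np.zeros((len(attributions), p))
    for i, att in enumerate(attributions):
        imp[i] = (np.abs(att.values[:, :-1]) * dt[None, :]).sum(axis=1)
    counts = np.zeros((p, p), dtype=int)
    for row in imp:
        order = np.argsort(-row, kind="stable")
        for rank, j in enumerate(order):
            counts[j, rank] += 1
    return ImportanceRanking(list(feats), imp.mean(axis=0), counts, len(attributions))
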