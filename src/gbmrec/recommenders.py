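"""End-to-end trainable counterfactual survival models.

All model kinds share one contract: fit on a cohort, predict per-arm log
hazard ratios, and predict per-arm survival curves from treatment-specific
Breslow baseline hazards.

Kinds
-----
``BDE``
    Balanced Decision Ensembles: LassoNet shared representation, one NODE
    risk head per treatment arm, trained on the sum of the two arms' Cox
    partial-likelihood losses plus an MMD balancing penalty on the shared
    representation. The LassoNet hierarchical proximal step runs after each
    optimizer step.
``BITES``
    Same twin-loss + balancing objective with a shared MLP and MLP heads.
``DeepSurvT``
    T-learner of two independent deep Cox (MLP) networks, one per arm.
``CoxT``
    T-learner of two linear Cox models.
``CoxPooled``
    A single linear Cox model on covariates only, with an all-cohort
    baseline hazard — the treatment-agnostic survival predictor.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Adam, Tensor
from .components import (MLP, NODE, LassoNet, LassoNetSpec, NODESpec,
                         RepresentationBatch, ipm_penalty)
from .survival import BaselineHazard, SurvivalCurve, breslow_baseline, fit_linear_cox, predict_curve
from .synthetic import BINARY_COLS, SCHEMA, Cohort

__all__ = ["TrainConfig", "SplitPlan", "FeatureEncoder", "FittedRecommender",
           "encode_features", "split_cohort", "fit", "predict_lp",
           "predict_counterfactual_curves", "tune_hyperparameters",
           "save_model", "load_model", "MODEL_KINDS"]

MODEL_KINDS = ("BDE", "BITES", "DeepSurvT", "CoxT", "CoxPooled")

# reference levels dropped by the one-hot encoding
REFERENCES = {"region": "Midwest", "location": "frontal",
              "laterality": "left", "extension": "confined"}


@dataclass
class TrainConfig:
    """Training protocol: 80/20 split, 5-fold CV, patience-1000 early stopping."""

    test_fraction: float = 0.2
    cv_folds: int = 5
    patience: int = 1000          # optimizer steps without validation improvement
    max_iter: int = 10000
    batch_size: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    alpha: float = 1.0            # IPM weight
    seed: int = 0
    val_fraction: float = 0.2     # held out from the training data for early stopping
    eval_every: int = 25
    # architecture
    mlp_hidden: tuple = (16, 8)
    lassonet_hidden: tuple = (16,)
    lambda_skip: float = 0.01
    hierarchy_M: float = 10.0
    node_trees: int = 8
    node_depth: int = 3
    node_layers: int = 1
    node_temperature: float = 1.0
    hyper_grid: list = field(default_factory=list)

    def validate(self):
        if not 0 < self.test_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("fractions must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        return self

    def replace(self, **kw) -> "TrainConfig":
        d = asdict(self)
        d.update(kw)
        for key in ("mlp_hidden", "lassonet_hidden"):
            d[key] = tuple(d[key])
        return TrainConfig(**d).validate()


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list  # list of (fold_train_idx, fold_val_idx), indices into the cohort


class FeatureEncoder:
    """One-hot + z-score design-matrix builder with frozen training state.

    Reference levels: sex=female, region=Midwest, location=frontal,
    laterality=left, extension=confined; age and tumor_size are z-scored by
    training-set mean/sd. Unseen category levels at transform time raise.
    """

    def __init__(self):
        self.fitted = False

    def fit(self, df: pd.DataFrame) -> "FeatureEncoder":
        self.age_mean = float(df["age"].mean())
        self.age_sd = float(df["age"].std(ddof=0)) or 1.0
        self.size_mean = float(df["tumor_size"].mean())
        self.size_sd = float(df["tumor_size"].std(ddof=0)) or 1.0
        self.columns = ["age", "tumor_size", *BINARY_COLS]
        for col, ref in REFERENCES.items():
            for lev in SCHEMA[col]:
                if lev != ref:
                    self.columns.append(f"{col}_{lev}")
        self.fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("encoder not fitted")
        n = len(df)
        out = np.zeros((n, len(self.columns)))
        out[:, 0] = (df["age"].to_numpy(float) - self.age_mean) / self.age_sd
        out[:, 1] = (df["tumor_size"].to_numpy(float) - self.size_mean) / self.size_sd
        j = 2
        for col in BINARY_COLS:
            out[:, j] = df[col].to_numpy(float)
            j += 1
        for col, ref in REFERENCES.items():
            seen = set(df[col])
            unknown = seen - set(SCHEMA[col])
            if unknown:
                raise ValueError(f"unseen {col} level(s) at transform time: {sorted(unknown)}")
            for lev in SCHEMA[col]:
                if lev != ref:
                    out[:, j] = (df[col] == lev).to_numpy(float)
                    j += 1
        return out

    def decode(self, X: np.ndarray) -> pd.DataFrame:
        """Recover raw covariates (categorical labels exact, continuous de-scored)."""
        X = np.atleast_2d(X)
        cols = {c: X[:, i] for i, c in enumerate(self.columns)}
        df = pd.DataFrame({
            "age": cols["age"] * self.age_sd + self.age_mean,
            "tumor_size": cols["tumor_size"] * self.size_sd + self.size_mean,
        })
        for c in BINARY_COLS:
            df[c] = cols[c].astype(int)
        for col, ref in REFERENCES.items():
            lab = np.full(len(X), ref, dtype=object)
            for lev in SCHEMA[col]:
                if lev != ref:
                    lab[cols[f"{col}_{lev}"] == 1] = lev
            df[col] = lab
        return df

    def state(self) -> dict:
        return {"age_mean": self.age_mean, "age_sd": self.age_sd,
                "size_mean": self.size_mean, "size_sd": self.size_sd,
                "columns": self.columns}

    @classmethod
    def from_state(cls, s: dict) -> "FeatureEncoder":
        enc = cls()
        enc.age_mean, enc.age_sd = s["age_mean"], s["age_sd"]
        enc.size_mean, enc.size_sd = s["size_mean"], s["size_sd"]
        enc.columns = list(s["columns"])
        enc.fitted = True
        return enc


def encode_features(cohort, encoder: FeatureEncoder | None = None):
    """Design matrix for a cohort; fits a new encoder unless one is given."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    if encoder is None:
        encoder = FeatureEncoder().fit(df)
    return encoder.transform(df), encoder


def split_cohort(cohort, config: TrainConfig) -> SplitPlan:
    """Seeded 80/20 split stratified by (treatment, event), plus 5 CV folds."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    n = len(df)
    if n < 10:
        raise ValueError("cohort too small to split")
    strata = df["treatment"].astype(str) + "_" + df["event"].astype(str)
    counts = strata.value_counts()
    if counts.min() < config.cv_folds:
        warnings.warn("a (treatment, event) stratum is smaller than the fold count; "
                      "falling back to event-only stratification")
        strata = df["event"].astype(str)
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=config.test_fraction, random_state=config.seed,
        stratify=strata.to_numpy())
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.seed)
    folds = [(train_idx[tr], train_idx[va])
             for tr, va in skf.split(train_idx, strata.to_numpy()[train_idx])]
    return SplitPlan(np.sort(train_idx), np.sort(test_idx), folds)


@dataclass
class FittedRecommender:
    kind: str
    encoder: FeatureEncoder
    baselines: dict                 # arm name -> BaselineHazard
    config: TrainConfig
    cox_fits: dict | None = None    # arm -> CoxFit (linear kinds)
    feature_masks: dict | None = None  # arm -> columns kept (non-constant)
    nets: dict | None = None        # neural modules
    pooled_baseline: BaselineHazard | None = None
    train_log: pd.DataFrame | None = None

    def n_parameters(self) -> int:
        if self.cox_fits is not None:
            return int(sum(len(f.coef) for f in self.cox_fits.values()))
        return int(sum(p.data.size for p in _net_params(self.nets)))


def _net_params(nets: dict) -> list:
    params = []
    for key in sorted(nets):
        params.extend(nets[key].parameters())
    return params


# --------------------------------------------------------------------------
# Cox loss on a batch risk set (autodiff)
# --------------------------------------------------------------------------
def cox_nll_tensor(lp: Tensor, times, events) -> Tensor:
    """Breslow negative log partial likelihood, averaged over events (autodiff)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n_ev = int(events.sum())
    if n_ev == 0:
        raise ValueError("no events in batch")
    shift = float(lp.data.max())
    e = (lp - shift).exp()                      # (n, 1)
    ev_idx = np.where(events == 1)[0]
    R = (times[None, :] >= times[ev_idx, None]).astype(float)  # (n_ev, n)
    risk = Tensor(R) @ e                         # (n_ev, 1)
    return (risk.log().sum() - (lp[ev_idx] - shift).sum()) * (1.0 / n_ev)


def _forward_lp(kind, nets, X: Tensor, arm: str):
    """Linear predictor Tensor for a neural model kind."""
    if kind in ("BDE", "BITES"):
        rep, _ = nets["shared"].forward(X)
        out = nets[f"head_{arm}"].forward(rep)
        return out[1] if isinstance(out, tuple) else out
    if kind == "DeepSurvT":
        return nets[f"arm_{arm}"].forward(X)[1]
    raise ValueError(f"not a neural kind: {kind}")


def _shared_rep(nets, X: Tensor):
    rep, _ = nets["shared"].forward(X)
    return rep


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------
def fit(kind: str, cohort_train, config: TrainConfig) -> FittedRecommender:
    """Fit a recommender of the given kind on the training cohort.

    Neural kinds early-stop on a held-out validation split (validation loss
    includes the IPM term for the balanced kinds) with the configured
    patience in optimizer steps; treatment-specific Breslow baselines are
    computed from each arm's training subjects after fitting.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")
    config = config.validate()
    df = (cohort_train.df if isinstance(cohort_train, Cohort) else cohort_train).reset_index(drop=True)
    treat = (df["treatment"] == "SpTR").astype(int).to_numpy()
    times = df["time"].to_numpy(float)
    events = df["event"].to_numpy(int)
    for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
        if kind != "CoxPooled" and events[treat == arm_val].sum() < 1:
            raise ValueError(f"arm {arm} has no events; model unfittable")
    X, encoder = encode_features(df)

    if kind == "CoxPooled":
        keep = X.std(axis=0) > 0   # rare indicator levels can be absent
        f = fit_linear_cox(X[:, keep], times, events,
                           names=[c for c, k in zip(encoder.columns, keep) if k])
        lp = X[:, keep] @ f.coef
        pooled = breslow_baseline(lp, times, events)
        baselines = {}
        for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
            m = treat == arm_val
            baselines[arm] = breslow_baseline(lp[m], times[m], events[m]) \
                if events[m].sum() > 0 else pooled
        return FittedRecommender(kind, encoder, baselines, config,
                                 cox_fits={"pooled": f},
                                 feature_masks={"pooled": keep},
                                 pooled_baseline=pooled)

    if kind == "CoxT":
        fits, baselines, masks = {}, {}, {}
        for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
            m = treat == arm_val
            keep = X[m].std(axis=0) > 0
            f = fit_linear_cox(X[m][:, keep], times[m], events[m],
                               names=[c for c, k in zip(encoder.columns, keep) if k])
            fits[arm] = f
            masks[arm] = keep
            baselines[arm] = breslow_baseline(X[m][:, keep] @ f.coef, times[m], events[m])
        return FittedRecommender(kind, encoder, baselines, config, cox_fits=fits,
                                 feature_masks=masks)

    return _fit_neural(kind, df, X, treat, times, events, encoder, config)


def _build_nets(kind, d_in, config, rng):
    if kind == "DeepSurvT":
        return {"arm_GTR": MLP(d_in, config.mlp_hidden, 1, rng=rng),
                "arm_SpTR": MLP(d_in, config.mlp_hidden, 1, rng=rng)}
    if kind == "BITES":
        shared = MLP(d_in, config.mlp_hidden, 1, rng=rng)
        rep_dim = config.mlp_hidden[-1] + 1
        # heads consume (last hidden, output) concatenated
        return {"shared": _SharedMLPWrapper(shared),
                "head_GTR": MLP(rep_dim, (max(rep_dim // 2, 2),), 1, rng=rng),
                "head_SpTR": MLP(rep_dim, (max(rep_dim // 2, 2),), 1, rng=rng)}
    if kind == "BDE":
        spec = LassoNetSpec(d_in, config.lassonet_hidden, config.lambda_skip,
                            config.hierarchy_M)
        shared = LassoNet(spec, rng)
        nspec = NODESpec(shared.rep_dim, config.node_trees, config.node_depth,
                         1, config.node_layers, config.node_temperature)
        return {"shared": shared,
                "head_GTR": NODE(nspec, rng), "head_SpTR": NODE(nspec, rng)}
    raise ValueError(kind)


class _SharedMLPWrapper:
    """Adapts an MLP to the shared-net contract (rep = [last hidden, output])."""

    def __init__(self, mlp: MLP):
        self.mlp = mlp

    def parameters(self):
        return self.mlp.parameters()

    def forward(self, x: Tensor):
        from .autodiff import concat
        hidden, out = self.mlp.forward(x)
        return concat([hidden, out], axis=1), out


def _fit_neural(kind, df, X, treat, times, events, encoder, config):
    rng = np.random.default_rng(config.seed)
    nets = _build_nets(kind, X.shape[1], config, rng)
    params = _net_params(nets)
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)

    # held-out validation split for early stopping (stratified by arm/event)
    strata = treat * 2 + events
    idx = np.arange(len(df))
    try:
        tr_idx, va_idx = train_test_split(idx, test_size=config.val_fraction,
                                          random_state=config.seed, stratify=strata)
    except ValueError:
        tr_idx, va_idx = train_test_split(idx, test_size=config.val_fraction,
                                          random_state=config.seed, stratify=events)

    def full_loss(sub_idx):
        Xt = Tensor(X[sub_idx])
        loss = None
        if kind == "DeepSurvT":
            for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
                m = treat[sub_idx] == arm_val
                if events[sub_idx][m].sum() == 0:
                    continue
                lp = _forward_lp(kind, nets, Tensor(X[sub_idx][m]), arm)
                part = cox_nll_tensor(lp, times[sub_idx][m], events[sub_idx][m])
                loss = part if loss is None else loss + part
        else:
            rep = _shared_rep(nets, Xt)
            for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
                m = np.where(treat[sub_idx] == arm_val)[0]
                if events[sub_idx][m].sum() == 0:
                    continue
                lp = nets[f"head_{arm}"].forward(rep[m])
                if isinstance(lp, tuple):
                    lp = lp[1]
                part = cox_nll_tensor(lp, times[sub_idx][m], events[sub_idx][m])
                loss = part if loss is None else loss + part
            if config.alpha > 0:
                loss = loss + config.alpha * ipm_penalty(
                    RepresentationBatch(rep, treat[sub_idx]))
        return loss

    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    best_step = 0
    log_rows = []
    n_tr = len(tr_idx)
    bs = min(config.batch_size, n_tr)
    for step in range(1, config.max_iter + 1):
        batch = rng.choice(tr_idx, size=bs, replace=False)
        # batch must contain events in at least one arm
        if events[batch].sum() == 0:
            continue
        opt.zero_grad()
        loss = full_loss(batch)
        loss.backward()
        opt.step()
        if kind == "BDE":
            nets["shared"].apply_prox(config.learning_rate)
        if step % config.eval_every == 0 or step == config.max_iter:
            val = float(full_loss(va_idx).data)
            log_rows.append({"iteration": step, "train_loss": float(loss.data),
                             "val_loss": val})
            if val < best_val - 1e-9:
                best_val = val
                best_state = [p.data.copy() for p in params]
                best_step = step
            elif step - best_step >= config.patience:
                break
        if not np.isfinite(float(loss.data)):
            raise FloatingPointError(f"NaN/inf loss at step {step}; aborting fit")
    for p, s in zip(params, best_state):
        p.data = s

    baselines = {}
    for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
        m = treat == arm_val
        lp = _forward_lp(kind, nets, Tensor(X[m]), arm)
        lp_arr = lp.data.ravel() if isinstance(lp, Tensor) else np.asarray(lp).ravel()
        baselines[arm] = breslow_baseline(lp_arr, times[m], events[m])
    return FittedRecommender(kind, encoder, baselines, config, nets=nets,
                             train_log=pd.DataFrame(log_rows))


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------
def _as_df(x) -> pd.DataFrame:
    if isinstance(x, Cohort):
        return x.df
    if isinstance(x, pd.DataFrame):
        return x
    if isinstance(x, pd.Series):
        return x.to_frame().T
    if isinstance(x, dict):
        return pd.DataFrame([x])
    raise TypeError(f"cannot interpret {type(x)} as patient data")


def predict_lp(model: FittedRecommender, x, arm: str) -> np.ndarray:
    """Per-subject log hazard ratio under the hypothesis of the given arm."""
    if arm not in ("GTR", "SpTR"):
        raise ValueError(f"unknown arm {arm!r}")
    df = _as_df(x)
    X = model.encoder.transform(df)
    if model.kind == "CoxPooled":
        return X[:, model.feature_masks["pooled"]] @ model.cox_fits["pooled"].coef
    if model.kind == "CoxT":
        return X[:, model.feature_masks[arm]] @ model.cox_fits[arm].coef
    lp = _forward_lp(model.kind, model.nets, Tensor(X), arm)
    return (lp.data if isinstance(lp, Tensor) else np.asarray(lp)).ravel()


def predict_counterfactual_curves(model: FittedRecommender, x, grid):
    """(curves under GTR, curves under SpTR) for each subject in x."""
    df = _as_df(x)
    out = {}
    for arm in ("GTR", "SpTR"):
        lps = predict_lp(model, df, arm)
        out[arm] = [predict_curve(v, model.baselines[arm], grid) for v in lps]
    if len(df) == 1:
        return out["GTR"][0], out["SpTR"][0]
    return out["GTR"], out["SpTR"]


# --------------------------------------------------------------------------
# hyperparameter tuning
# --------------------------------------------------------------------------
def tune_hyperparameters(kind: str, cohort_train, config: TrainConfig):
    """5-fold CV over ``config.hyper_grid``; returns (best overrides, CV table).

    Each grid point is a dict of TrainConfig overrides. Mean validation loss
    (full-data Cox partial likelihood, plus the weighted IPM term for the
    balanced kinds) selects the winner; ties break toward the smaller model,
    then grid order.
    """
    if not config.hyper_grid:
        raise ValueError("hyperparameter grid is empty")
    df = (cohort_train.df if isinstance(cohort_train, Cohort) else cohort_train).reset_index(drop=True)
    strata = ((df["treatment"] == "SpTR").astype(int) * 2 + df["event"]).to_numpy()
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    folds = list(skf.split(np.arange(len(df)), strata))
    rows = []
    results = []
    for gi, over in enumerate(config.hyper_grid):
        cfg = config.replace(**over)
        losses, n_params = [], None
        diverged = False
        for fi, (tr, va) in enumerate(folds):
            try:
                m = fit(kind, Cohort(df.iloc[tr].reset_index(drop=True)), cfg)
            except FloatingPointError:
                diverged = True
                break
            n_params = m.n_parameters()
            loss = _validation_loss(m, df.iloc[va].reset_index(drop=True), cfg)
            losses.append(loss)
            rows.append({"grid_index": gi, "fold": fi, "val_loss": loss,
                         **{k: str(v) for k, v in over.items()}})
        if not diverged:
            results.append((float(np.mean(losses)), n_params, gi, over))
    if not results:
        raise RuntimeError("all hyperparameter grid points diverged")
    results.sort(key=lambda r: (r[0], r[1], r[2]))
    return results[0][3], pd.DataFrame(rows)


def _validation_loss(model: FittedRecommender, df: pd.DataFrame, cfg: TrainConfig) -> float:
    from .survival import neg_log_partial_likelihood
    treat = (df["treatment"] == "SpTR").astype(int).to_numpy()
    total = 0.0
    if model.kind == "CoxPooled":
        lp = predict_lp(model, df, "GTR")
        return neg_log_partial_likelihood(lp, df["time"], df["event"])
    for arm_val, arm in ((0, "GTR"), (1, "SpTR")):
        m = treat == arm_val
        if df["event"].to_numpy()[m].sum() == 0:
            continue
        lp = predict_lp(model, df[m], arm)
        total += neg_log_partial_likelihood(lp, df["time"].to_numpy()[m],
                                            df["event"].to_numpy()[m])
    if model.kind in ("BDE", "BITES") and cfg.alpha > 0:
        X = model.encoder.transform(df)
        rep = _shared_rep(model.nets, Tensor(X))
        total += cfg.alpha * float(ipm_penalty(RepresentationBatch(rep, treat)).data)
    return float(total)


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------
_ARCHIVE_VERSION = 1


def save_model(model: FittedRecommender, path):
    """Serialize a fitted recommender to a versioned JSON archive."""
    blob = {"version": _ARCHIVE_VERSION, "kind": model.kind,
            "encoder": model.encoder.state(),
            "config": {**asdict(model.config),
                       "mlp_hidden": list(model.config.mlp_hidden),
                       "lassonet_hidden": list(model.config.lassonet_hidden)},
            "baselines": {arm: {"times": b.times.tolist(), "cumhaz": b.cumhaz.tolist()}
                          for arm, b in model.baselines.items()}}
    if model.pooled_baseline is not None:
        blob["pooled_baseline"] = {"times": model.pooled_baseline.times.tolist(),
                                   "cumhaz": model.pooled_baseline.cumhaz.tolist()}
    if model.cox_fits is not None:
        blob["cox_fits"] = {k: {"coef": f.coef.tolist(), "se": f.se.tolist(),
                                "loglik": f.loglik, "converged": f.converged,
                                "cov": f.cov.tolist(), "names": f.names}
                            for k, f in model.cox_fits.items()}
        blob["feature_masks"] = {k: np.asarray(v).astype(int).tolist()
                                 for k, v in (model.feature_masks or {}).items()}
    if model.nets is not None:
        blob["net_params"] = [p.data.tolist() for p in _net_params(model.nets)]
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_model(path) -> FittedRecommender:
    from .survival import CoxFit
    with open(path) as fh:
        blob = json.load(fh)
    if blob["version"] != _ARCHIVE_VERSION:
        raise ValueError(f"unsupported archive version {blob['version']}")
    cfgd = blob["config"]
    cfgd["mlp_hidden"] = tuple(cfgd["mlp_hidden"])
    cfgd["lassonet_hidden"] = tuple(cfgd["lassonet_hidden"])
    config = TrainConfig(**cfgd)
    encoder = FeatureEncoder.from_state(blob["encoder"])
    baselines = {arm: BaselineHazard(np.array(b["times"]), np.array(b["cumhaz"]))
                 for arm, b in blob["baselines"].items()}
    model = FittedRecommender(blob["kind"], encoder, baselines, config)
    if "pooled_baseline" in blob:
        pb = blob["pooled_baseline"]
        model.pooled_baseline = BaselineHazard(np.array(pb["times"]), np.array(pb["cumhaz"]))
    if "cox_fits" in blob:
        model.cox_fits = {k: CoxFit(np.array(f["coef"]), np.array(f["se"]),
                                    f["loglik"], f["converged"], np.array(f["cov"]),
                                    f["names"])
                          for k, f in blob["cox_fits"].items()}
        model.feature_masks = {k: np.asarray(v, dtype=bool)
                               for k, v in blob.get("feature_masks", {}).items()}
    if "net_params" in blob:
        rng = np.random.default_rng(config.seed)
        nets = _build_nets(blob["kind"], len(encoder.columns), config, rng)
        model.nets = nets
        for p, saved in zip(_net_params(nets), blob["net_params"]):
            p.data = np.asarray(saved, dtype=float).reshape(p.data.shape)
    return model
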