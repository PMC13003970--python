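"""Tiller-number estimation models and their evaluation.

Three tiers of estimators operate on the normalized 12-feature table:

* the packaged single- and multi-factor linear equations (the field-study
  regressions relating plant area, perimeter, rectangle extent, hull area
  and greenness to tiller count),
* machine-learning regressors — random forest, support-vector regression
  and gradient-boosted trees, and
* their particle-swarm-optimized variants, where canonical PSO minimizes
  the cross-validated RMSE over each algorithm's hyperparameter box.

Accuracy is reported as R², RMSE, nRMSE (normalized by the observed mean,
as a percentage) and MAE.  R² comes in two forms: the standard
1 − SSres/SStot (default; the only form under which held-out metrics are
meaningful for nonlinear models) and the regression-sum-of-squares form
SSreg/SStot (identical for in-sample OLS fits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

__all__ = [
    "LinearTillerModel",
    "load_linear_models",
    "predict_linear",
    "PsoConfig",
    "pso_optimize",
    "fit_ml",
    "fit_pso_ml",
    "EvalReport",
    "evaluate_regression",
    "split_train_test",
    "ALGORITHMS",
]


# --------------------------------------------------------------------------
# packaged linear models
# --------------------------------------------------------------------------
@dataclass
class LinearTillerModel:
    """y = intercept + Σ coefᵢ·xᵢ over named features."""

    id: str
    feature_names: list[str]
    coefficients: list[float]
    intercept: float
    form: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("one coefficient per feature required")


def load_linear_models() -> dict[str, LinearTillerModel]:
    """The 11 packaged regression equations (F1–F6 single-factor,
    MF1–MF5 multi-factor)."""
    doc = json.loads(
        resources.files("paddytiller").joinpath("data/table3_models.json").read_text()
    )
    return {k: LinearTillerModel(id=k, **v) for k, v in doc.items()}


def predict_linear(model: LinearTillerModel, features: Mapping[str, float] | pd.DataFrame):
    """Evaluate a linear tiller model; raises KeyError naming any missing
    feature."""
    if isinstance(features, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in features.columns]
        if missing:
            raise KeyError(f"missing feature(s) {missing} for model {model.id}")
        x = features[model.feature_names].to_numpy(dtype=float)
        return x @ np.asarray(model.coefficients) + model.intercept
    missing = [n for n in model.feature_names if n not in features]
    if missing:
        raise KeyError(f"missing feature(s) {missing} for model {model.id}")
    return float(
        sum(c * float(features[n]) for c, n in zip(model.coefficients, model.feature_names))
        + model.intercept
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass
class EvalReport:
    r2: float
    r2_printed: float
    rmse: float
    nrmse: float  # percent
    mae: float
    n: int
    degenerate: bool = False


def evaluate_regression(
    y_true: Sequence[float], y_pred: Sequence[float], nf: float | None = None
) -> EvalReport:
    """R² (both forms), RMSE, nRMSE (% of NF; NF defaults to mean observed
    value) and MAE."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1 or len(yt) < 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays")
    n = len(yt)
    resid = yt - yp
    rmse = float(np.sqrt((resid**2).mean()))
    mae = float(np.abs(resid).mean())
    nf = float(np.mean(yt)) if nf is None else float(nf)
    nrmse = rmse / nf * 100.0
    sstot = float(((yt - yt.mean()) ** 2).sum())
    degenerate = sstot == 0.0
    if degenerate:
        r2 = r2p = float("nan")
    else:
        r2 = 1.0 - float((resid**2).sum()) / sstot
        r2p = float(((yp - yt.mean()) ** 2).sum()) / sstot
    return EvalReport(r2=r2, r2_printed=r2p, rmse=rmse, nrmse=nrmse, mae=mae, n=n, degenerate=degenerate)


def split_train_test(
    table: pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random 80/20 split (train size floored); disjoint and
    exhaustive."""
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    order = np.random.default_rng(seed).permutation(n)
    k = int(np.floor(train_frac * n))
    return table.iloc[order[:k]].copy(), table.iloc[order[k:]].copy()


# --------------------------------------------------------------------------
# machine-learning regressors
# --------------------------------------------------------------------------
# hyperparameter search boxes: (name, low, high, log-scale, integer)
ALGORITHMS: dict[str, list[tuple[str, float, float, bool, bool]]] = {
    "gradient-boosted-trees": [
        ("n_estimators", 50, 500, False, True),
        ("max_depth", 2, 10, False, True),
        ("learning_rate", 0.01, 0.3, False, False),
        ("subsample", 0.5, 1.0, False, False),
        ("colsample_bytree", 0.5, 1.0, False, False),
        ("reg_lambda", 0.0, 10.0, False, False),
    ],
    "random-forest": [
        ("n_estimators", 50, 500, False, True),
        ("max_depth", 2, 20, False, True),
        ("min_samples_leaf", 1, 10, False, True),
    ],
    "support-vector": [
        ("C", 0.1, 100.0, True, False),
        ("gamma", 1e-4, 1.0, True, False),
        ("epsilon", 0.01, 1.0, False, False),
    ],
}

_LIB_DEFAULTS = {
    "gradient-boosted-trees": {
        "n_estimators": 100,
        "max_depth": 6,
        "learning_rate": 0.3,
        "subsample": 1.0,
        "colsample_bytree": 1.0,
        "reg_lambda": 1.0,
    },
    "random-forest": {"n_estimators": 100, "max_depth": 20, "min_samples_leaf": 1},
    "support-vector": {"C": 1.0, "gamma": 1.0 / 12, "epsilon": 0.1},
}


def _make_estimator(algorithm: str, hyperparams: Mapping[str, float], seed: int):
    hp = dict(hyperparams)
    if algorithm == "gradient-boosted-trees":
        return XGBRegressor(
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            **{k: (int(v) if k in ("n_estimators", "max_depth") else v) for k, v in hp.items()},
        )
    if algorithm == "random-forest":
        return RandomForestRegressor(
            random_state=seed,
            n_jobs=1,
            **{k: int(v) for k, v in hp.items()},
        )
    if algorithm == "support-vector":
        return SVR(kernel="rbf", **hp)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def fit_ml(
    train_table: pd.DataFrame,
    algorithm: str,
    hyperparams: Mapping[str, float] | None = None,
    seed: int = 0,
    target: str = "tiller_count",
    feature_cols: Sequence[str] | None = None,
):
    """Fit one regressor on a feature table with a numeric target column.

    A single-row training set yields a constant predictor (tree ensembles
    degenerate to the mean).  Deterministic under a fixed seed.
    """
    if target not in train_table.columns:
        raise ValueError(f"target column {target!r} absent")
    y = pd.to_numeric(train_table[target], errors="raise").to_numpy(dtype=float)
    cols = list(feature_cols) if feature_cols is not None else [
        c for c in train_table.columns if c != target
    ]
    x = train_table[cols].to_numpy(dtype=float)
    est = _make_estimator(algorithm, hyperparams or _LIB_DEFAULTS[algorithm], seed)
    est.fit(x, y)
    est.feature_cols_ = cols
    return est


# --------------------------------------------------------------------------
# particle swarm optimization
# --------------------------------------------------------------------------
@dataclass
class PsoConfig:
    """Canonical PSO with constriction-style coefficients."""

    swarm_size: int = 30
    iterations: int = 50
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    bounds: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be ≥ 2")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("each bound must satisfy low < high")


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    config: PsoConfig,
    init_positions: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Minimize ``objective`` over the bounded box by canonical PSO.

    v ← ωv + c1·r1·(pbest − x) + c2·r2·(gbest − x); x ← clip(x + v).
    Random draw order (fixed for reproducibility): initial positions one
    uniform vector per particle, then per iteration and particle r1 then
    r2.  NaN objectives are penalized with +inf.  Returns (best position,
    best value, per-iteration gbest trace).
    """
    bounds = np.asarray(config.bounds, dtype=float)
    dim = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(config.seed)

    def safe(v: float) -> float:
        return float("inf") if np.isnan(v) else float(v)

    x = np.stack([lo + rng.random(dim) * (hi - lo) for _ in range(config.swarm_size)])
    if init_positions is not None:
        init = np.clip(np.atleast_2d(init_positions), lo, hi)
        x[: len(init)] = init
    v = np.zeros_like(x)
    pbest = x.copy()
    pval = np.array([safe(objective(xi)) for xi in x])
    g = int(pval.argmin())
    gbest, gval = pbest[g].copy(), float(pval[g])
    trace = []
    for _ in range(config.iterations):
        for i in range(config.swarm_size):
            r1 = rng.random(dim)
            r2 = rng.random(dim)
            v[i] = (
                config.inertia * v[i]
                + config.cognitive * r1 * (pbest[i] - x[i])
                + config.social * r2 * (gbest - x[i])
            )
            x[i] = np.clip(x[i] + v[i], lo, hi)
            val = safe(objective(x[i]))
            if val < pval[i]:
                pval[i] = val
                pbest[i] = x[i].copy()
                if val < gval:
                    gval = val
                    gbest = x[i].copy()
        trace.append(gval)
    return gbest, gval, trace


def _decode(vec: np.ndarray, space) -> dict[str, float]:
    out = {}
    for val, (name, lo, hi, logscale, integer) in zip(vec, space):
        if logscale:
            val = 10.0 ** val
        out[name] = int(round(val)) if integer else float(val)
    return out


def _encode_bounds(space) -> list[tuple[float, float]]:
    return [
        (np.log10(lo), np.log10(hi)) if logscale else (float(lo), float(hi))
        for (_, lo, hi, logscale, _) in space
    ]


def _cv_rmse(table, algorithm, hp, seed, folds, target, feature_cols) -> float:
    y = table[target].to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for tr_idx, te_idx in kf.split(table):
        est = fit_ml(
            table.iloc[tr_idx], algorithm, hp, seed=seed, target=target, feature_cols=feature_cols
        )
        pred = est.predict(table.iloc[te_idx][est.feature_cols_].to_numpy(dtype=float))
        errs.append(np.sqrt(((table.iloc[te_idx][target].to_numpy(dtype=float) - pred) ** 2).mean()))
    del y
    return float(np.mean(errs))


def fit_pso_ml(
    train_table: pd.DataFrame,
    algorithm: str,
    pso_config: PsoConfig | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    target: str = "tiller_count",
    feature_cols: Sequence[str] | None = None,
):
    """PSO-tune hyperparameters by cross-validated RMSE, then refit.

    One particle is warm-started at the library-default hyperparameters,
    so the tuned cross-validated RMSE can never exceed the default one on
    the same folds.  Returns (fitted model, best hyperparams, report dict
    with tuned/default CV RMSE).
    """
    if cv_folds > len(train_table):
        raise ValueError("more folds than samples")
    space = ALGORITHMS[algorithm]
    config = pso_config or PsoConfig(seed=seed)
    config = PsoConfig(
        swarm_size=config.swarm_size,
        iterations=config.iterations,
        inertia=config.inertia,
        cognitive=config.cognitive,
        social=config.social,
        bounds=_encode_bounds(space),
        seed=config.seed,
    )

    def objective(vec: np.ndarray) -> float:
        hp = _decode(vec, space)
        return _cv_rmse(train_table, algorithm, hp, seed, cv_folds, target, feature_cols)

    defaults = _LIB_DEFAULTS[algorithm]
    default_vec = np.array(
        [
            np.log10(defaults[name]) if logscale else defaults[name]
            for (name, _, _, logscale, _) in space
        ]
    )
    default_rmse = _cv_rmse(train_table, algorithm, defaults, seed, cv_folds, target, feature_cols)
    best_vec, best_val, trace = pso_optimize(objective, config, init_positions=default_vec)
    best_hp = _decode(best_vec, space)
    model = fit_ml(train_table, algorithm, best_hp, seed=seed, target=target, feature_cols=feature_cols)
    return model, best_hp, {
        "tuned_cv_rmse": best_val,
        "default_cv_rmse": default_rmse,
        "trace": trace,
    }
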