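"""The potency model: epsilon-regression SVM with an RBF kernel.

The regressor maps the 196-dimensional feature vector (192 positional
indicators + 4 auxiliary scores) to the harmonized potency label.
Hyperparameters default to cost C = 2.25 and kernel width gamma = 0.1,
with tube width epsilon = 0.1; the model is not very sensitive to C and
gamma around these values (see :func:`tune`).

Feature scaling: the positional indicators already share a common 0/1
scale, so by default only the four auxiliary features are standardized
(mean/sd learned on the training set and stored in the model; never
refitted at prediction time).  Z-scoring the indicator block too is
available via ``scale="all"`` but inflates pairwise distances enough to
make the RBF kernel at gamma = 0.1 nearly diagonal, which destroys
generalization — see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import features as F
from .sequence import GuideCandidate, Transcript, candidate_from_context
from .training import PotencyRecord

MODEL_FORMAT_VERSION = 1

#: columns standardized under the default "aux" scaling policy
SCALE_POLICIES = ("aux", "all", "none")


class ModelError(RuntimeError):
    pass


class SchemaMismatchError(ModelError):
    """Feature schema of the input does not match the trained model."""


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameters of the epsilon-SVR (radial kernel throughout)."""

    cost: float = 2.25
    gamma: float = 0.1
    epsilon: float = 0.1
    kernel: str = "radial"
    seed: int = 0

    def __post_init__(self):
        if self.cost <= 0 or self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("cost, gamma and epsilon must be positive")
        if self.kernel != "radial":
            raise ValueError("only the radial (RBF) kernel is supported")


@dataclass
class TrainedPotencyModel:
    config: SvmConfig
    schema_id: str
    encoding: str
    scale_policy: str
    scale_mean: np.ndarray  # per-feature center (0 for unscaled columns)
    scale_sd: np.ndarray    # per-feature scale (1 for unscaled columns)
    fitted_state: SVR
    n_train: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_sd


def _records_to_matrix(
    records: Sequence[PotencyRecord],
    providers: Optional[Mapping[str, F.Provider]] = None,
    encoding: str = "onehot",
) -> Tuple[np.ndarray, np.ndarray]:
    rows = []
    for r in records:
        cand, frag = candidate_from_context(r.context48)
        aux = F.compute_aux_features(cand, frag, providers)
        rows.append(F.build_feature_vector(cand, aux, encoding).values)
    X = np.array(rows)
    y = np.array([r.label for r in records])
    return X, y


def _fit_scaler(
    X: np.ndarray, policy: str, encoding: str
) -> Tuple[np.ndarray, np.ndarray]:
    if policy not in SCALE_POLICIES:
        raise ValueError(f"unknown scale policy {policy!r}")
    mean = np.zeros(X.shape[1])
    sd = np.ones(X.shape[1])
    if policy == "none":
        return mean, sd
    n_pos = len(F.positional_feature_names(encoding))
    cols = slice(0, X.shape[1]) if policy == "all" else slice(n_pos, X.shape[1])
    mean[cols] = X[:, cols].mean(axis=0)
    s = X[:, cols].std(axis=0)
    sd[cols] = np.where(s > 0, s, 1.0)  # constant columns pass through
    return mean, sd


def _fit_svr(X: np.ndarray, y: np.ndarray, cfg: SvmConfig) -> SVR:
    svr = SVR(kernel="rbf", C=cfg.cost, gamma=cfg.gamma, epsilon=cfg.epsilon)
    svr.fit(X, y)
    return svr


def train(
    records: Sequence[PotencyRecord],
    cfg: Optional[SvmConfig] = None,
    providers: Optional[Mapping[str, F.Provider]] = None,
    encoding: str = "onehot",
    scale: str = "aux",
    min_records: int = 10,
) -> TrainedPotencyModel:
    """Fit the potency SVR on harmonized training records.

    Deterministic given records and config.  Scaling statistics are
    computed on the training features only and frozen into the model.
    """
    cfg = cfg or SvmConfig()
    if len(records) < min_records:
        raise ModelError(
            f"need at least {min_records} training records, got {len(records)}"
        )
    X, y = _records_to_matrix(records, providers, encoding)
    mean, sd = _fit_scaler(X, scale, encoding)
    svr = _fit_svr((X - mean) / sd, y, cfg)
    return TrainedPotencyModel(
        config=cfg,
        schema_id=F.schema_digest(F.feature_names(encoding)),
        encoding=encoding,
        scale_policy=scale,
        scale_mean=mean,
        scale_sd=sd,
        fitted_state=svr,
        n_train=len(records),
    )


def _check_schema(model: TrainedPotencyModel, schema_id: str) -> None:
    if schema_id != model.schema_id:
        raise SchemaMismatchError(
            f"feature schema {schema_id} does not match the model's "
            f"schema {model.schema_id}; retrain or switch encodings/providers"
        )


def predict_matrix(model: TrainedPotencyModel, X: np.ndarray, schema_id: str) -> np.ndarray:
    _check_schema(model, schema_id)
    return model.fitted_state.predict(model.transform(X))


def predict(
    model: TrainedPotencyModel,
    candidates: Sequence[GuideCandidate],
    transcript: Transcript,
    providers: Optional[Mapping[str, F.Provider]] = None,
) -> List[Tuple[GuideCandidate, float]]:
    """Score candidates against their transcript; order-preserving and pure."""
    if not candidates:
        return []
    X = F.feature_matrix(candidates, transcript, providers, model.encoding)
    scores = predict_matrix(model, X, F.schema_digest(F.feature_names(model.encoding)))
    return list(zip(candidates, scores.tolist()))


def predict_records(
    model: TrainedPotencyModel,
    records: Sequence[PotencyRecord],
    providers: Optional[Mapping[str, F.Provider]] = None,
) -> np.ndarray:
    """Score bare training-style records (context48 only)."""
    X, _ = _records_to_matrix(records, providers, model.encoding)
    return predict_matrix(model, X, F.schema_digest(F.feature_names(model.encoding)))


def tune(
    records: Sequence[PotencyRecord],
    cost_grid: Sequence[float],
    gamma_grid: Sequence[float],
    k_folds: int = 5,
    seed: int = 0,
    providers: Optional[Mapping[str, F.Provider]] = None,
    encoding: str = "onehot",
    scale: str = "aux",
) -> Tuple[SvmConfig, pd.DataFrame]:
    """k-fold cross-validated grid search over (cost, gamma).

    Returns the best config (minimal mean squared error; exact ties broken
    toward (2.25, 0.1), then toward smaller cost, then smaller gamma) and
    the full score table for sensitivity reporting.
    """
    if not cost_grid or not gamma_grid:
        raise ValueError("empty tuning grid")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X, y = _records_to_matrix(records, providers, encoding)
    if min(len(tr) for tr, _ in KFold(k_folds).split(X)) < 2:
        raise ModelError("folds would contain fewer than 2 records")
    splits = list(KFold(n_splits=k_folds, shuffle=True, random_state=seed).split(X))
    rows = []
    for cost in cost_grid:
        for gamma in gamma_grid:
            cfg = SvmConfig(cost=cost, gamma=gamma, seed=seed)
            fold_mse = []
            for tr, te in splits:
                mean, sd = _fit_scaler(X[tr], scale, encoding)
                svr = _fit_svr((X[tr] - mean) / sd, y[tr], cfg)
                pred = svr.predict((X[te] - mean) / sd)
                fold_mse.append(float(np.mean((pred - y[te]) ** 2)))
            rows.append({"cost": cost, "gamma": gamma, "mse": float(np.mean(fold_mse))})
    table = pd.DataFrame(rows)
    best_mse = table["mse"].min()
    tied = table[table["mse"] == best_mse]
    preferred = tied[(tied["cost"] == 2.25) & (tied["gamma"] == 0.1)]
    if len(preferred):
        pick = preferred.iloc[0]
    else:
        pick = tied.sort_values(["cost", "gamma"]).iloc[0]
    return SvmConfig(cost=float(pick["cost"]), gamma=float(pick["gamma"]), seed=seed), table


def save_model(model: TrainedPotencyModel, path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": {
            "cost": model.config.cost,
            "gamma": model.config.gamma,
            "epsilon": model.config.epsilon,
            "kernel": model.config.kernel,
            "seed": model.config.seed,
        },
        "schema_id": model.schema_id,
        "encoding": model.encoding,
        "scale_policy": model.scale_policy,
        "scale_mean": model.scale_mean,
        "scale_sd": model.scale_sd,
        "fitted_state": model.fitted_state,
        "n_train": model.n_train,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedPotencyModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"cannot load model from {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(
            f"unsupported or corrupt model file {path} "
            f"(format {payload.get('format_version') if isinstance(payload, dict) else '?'})"
        )
    return TrainedPotencyModel(
        config=SvmConfig(**payload["config"]),
        schema_id=payload["schema_id"],
        encoding=payload["encoding"],
        scale_policy=payload["scale_policy"],
        scale_mean=payload["scale_mean"],
        scale_sd=payload["scale_sd"],
        fitted_state=payload["fitted_state"],
        n_train=payload["n_train"],
    )
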