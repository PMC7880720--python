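"""Cohort/prediction CSV I/O and portable JSON model files.

Model files are plain JSON capturing the full fitted state (output weights,
random hidden parameters, standardization statistics, hyperparameters and
solver trace); float64 values survive the round trip exactly because JSON
decimal reprs of doubles are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .rvfl import HiddenParams, RVFLRegressor, StandardizationStats
from .solver import Hyperparameters, SLapRVFLRegressor, SolverTrace

__all__ = [
    "read_cohort",
    "write_predictions",
    "save_model",
    "load_model",
]


def read_cohort(path, target: str | None = None, feature_columns=None):
    """Read a cohort from delimited text (header row expected).

    Returns ``(X, y, feature_names)``; ``y`` is None when ``target`` is
    None or absent.  ``feature_columns`` restricts/orders the features,
    otherwise every non-target numeric column is used in file order.
    """
    df = pd.read_csv(path)
    y = None
    if target is not None and target in df.columns:
        y = df[target].to_numpy(dtype=float)
    if feature_columns is None:
        feature_columns = [c for c in df.columns if c != target]
    missing = [c for c in feature_columns if c not in df.columns]
    if missing:
        raise ValueError(f"columns missing from {path}: {missing}")
    X = df[list(feature_columns)].to_numpy(dtype=float)
    return X, y, list(feature_columns)


def write_predictions(path, y_pred, y_true=None, ids=None) -> None:
    """Write predictions as CSV with columns id, [y_true,] y_pred."""
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    data = {"id": np.arange(len(y_pred)) if ids is None else ids}
    if y_true is not None:
        data["y_true"] = np.asarray(y_true, dtype=float).ravel()
    data["y_pred"] = y_pred
    pd.DataFrame(data).to_csv(path, index=False)


def _array(a) -> list:
    return np.asarray(a, dtype=float).tolist()


def save_model(model, path) -> None:
    """Serialize a fitted regressor to a single portable JSON file."""
    if getattr(model, "beta_", None) is None:
        raise ValueError("model is not fitted")
    state = {
        "format": "slaprvfl-model",
        "version": 1,
        "type": type(model).__name__,
        "include_bias": model.include_bias,
        "standardize": model.standardize,
        "center_target": model.center_target,
        "y_mean": _array(model.y_mean_),
        "beta": _array(model.beta_),
        "hidden": {
            "a": _array(model.hidden_.a),
            "b": _array(model.hidden_.b),
            "activation": model.hidden_.activation,
            "seed": model.hidden_.seed,
        },
        "scaler": {
            "means": _array(model.scaler_.means),
            "sds": _array(model.scaler_.sds),
        },
    }
    if isinstance(model, SLapRVFLRegressor):
        state["hyper"] = asdict(model.hyper)
        state["epsilon"] = model.epsilon
        state["gamma_resolved"] = model.gamma_
        state["n_iter"] = model.n_iter_
        state["trace"] = {
            "objectives": model.trace_.objectives,
            "beta_deltas": model.trace_.beta_deltas,
        }
        state["squeeze_output"] = getattr(model, "_squeeze_output", True)
    else:
        state["P"] = model.P
        state["lambda_ridge"] = model.lambda_ridge
        state["seed"] = model.seed
    Path(path).write_text(json.dumps(state))


def load_model(path):
    """Restore a regressor saved by :func:`save_model`."""
    state = json.loads(Path(path).read_text())
    if state.get("format") != "slaprvfl-model":
        raise ValueError(f"{path} is not a slaprvfl model file")
    hidden = HiddenParams(
        a=np.asarray(state["hidden"]["a"], dtype=float),
        b=np.asarray(state["hidden"]["b"], dtype=float),
        activation=state["hidden"]["activation"],
        seed=state["hidden"]["seed"],
    )
    scaler = StandardizationStats(
        means=np.asarray(state["scaler"]["means"], dtype=float),
        sds=np.asarray(state["scaler"]["sds"], dtype=float),
    )
    if state["type"] == "SLapRVFLRegressor":
        model = SLapRVFLRegressor(
            hyper=Hyperparameters(**state["hyper"]),
            include_bias=state["include_bias"],
            standardize=state["standardize"],
            center_target=state["center_target"],
            epsilon=state["epsilon"],
        )
        model.gamma_ = state["gamma_resolved"]
        model.n_iter_ = state["n_iter"]
        model.trace_ = SolverTrace(
            objectives=list(state["trace"]["objectives"]),
            beta_deltas=list(state["trace"]["beta_deltas"]),
        )
        model._squeeze_output = state.get("squeeze_output", True)
    elif state["type"] == "RVFLRegressor":
        model = RVFLRegressor(
            P=state["P"],
            lambda_ridge=state["lambda_ridge"],
            seed=state["seed"],
            include_bias=state["include_bias"],
            standardize=state["standardize"],
            center_target=state["center_target"],
        )
    else:
        raise ValueError(f"unknown model type {state['type']!r}")
    model.beta_ = np.asarray(state["beta"], dtype=float)
    model.hidden_ = hidden
    model.scaler_ = scaler
    model.y_mean_ = np.asarray(state["y_mean"], dtype=float)
    return model
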