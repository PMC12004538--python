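"""Predictive model of the maximum stacking interaction energy.

The strongest possible (global-minimum) stacking interaction of a
heterocycle with a nucleobase is predicted from four descriptors: the
heavy-atom counts of both partners, the ESP_max of the heterocycle and the
ESP_range of the nucleobase.  The shipped functional form is a
two-coefficient bilinear model

    E_max = c1 · (N_HA_het · N_HA_nuc) + c2 · (ESP_max_het · ESP_range_nuc)

whose coefficients are fit by linear least squares to minimise the RMSE on
a training table of observed global-minimum binding energies.  The form is
exposed through a feature-map registry so alternative algebra (e.g. an
additive intercept or size-normalised terms) can be swapped in without
touching the fitting or screening code.

Binding energies are negative; "maximum stacking" means the most negative
value.  r² is the squared Pearson correlation between predicted and
observed energies, matching the reporting convention of this literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .espdesc import NUCLEOBASE_DESCRIPTORS

__all__ = [
    "FEATURE_COLUMNS",
    "ModelCoefficients",
    "MaxStackModel",
    "register_feature_map",
    "fit_model",
    "predict_max",
    "evaluate_model",
    "screen_library",
    "rmse",
    "pearson_r2",
]

FEATURE_COLUMNS = ["n_ha_het", "n_ha_nuc", "esp_max_het", "esp_range_nuc"]

# feature maps: descriptor DataFrame -> (n, k) design matrix, one column per
# fitted coefficient
_FEATURE_MAPS: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {}


def register_feature_map(name: str, func: Callable[[pd.DataFrame], np.ndarray]) -> None:
    _FEATURE_MAPS[name] = func


def _bilinear(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        df["n_ha_het"].to_numpy(float) * df["n_ha_nuc"].to_numpy(float),
        df["esp_max_het"].to_numpy(float) * df["esp_range_nuc"].to_numpy(float),
    ])


register_feature_map("bilinear", _bilinear)


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred, obs = np.asarray(pred, float), np.asarray(obs, float)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation; 0 (with a warning) when either argument
    has zero variance."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: r^2 undefined, reporting 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


@dataclass
class ModelCoefficients:
    """Fitted coefficients plus fit metadata."""

    c1: float
    c2: float
    feature_map: str = "bilinear"
    rmse: float = float("nan")
    r2: float = float("nan")
    training_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_map": self.feature_map, "c1": self.c1, "c2": self.c2,
            "rmse": self.rmse, "r2": self.r2, "training_ids": self.training_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelCoefficients":
        return cls(c1=d["c1"], c2=d["c2"], feature_map=d.get("feature_map", "bilinear"),
                   rmse=d.get("rmse", float("nan")), r2=d.get("r2", float("nan")),
                   training_ids=list(d.get("training_ids", [])))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
        if missing:
            raise KeyError(f"missing descriptor columns: {missing}")
        return X
    arr = np.asarray(X, float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected columns {FEATURE_COLUMNS}")
    return pd.DataFrame(arr, columns=FEATURE_COLUMNS)


class MaxStackModel(BaseEstimator, RegressorMixin):
    """Least-squares maximum-stacking regressor over a declared feature map.

    Parameters
    ----------
    feature_map : str, default "bilinear"
        Name of a registered map from descriptor columns to design-matrix
        columns, one per coefficient.

    Attributes
    ----------
    coef_ : ndarray
        Fitted coefficients (c1, c2 for the bilinear map).
    rmse_, r2_ : float
        Training RMSE (kcal/mol) and squared Pearson correlation.
    """

    def __init__(self, feature_map: str = "bilinear"):
        self.feature_map = feature_map

    def _design(self, X) -> np.ndarray:
        try:
            fmap = _FEATURE_MAPS[self.feature_map]
        except KeyError:
            raise ValueError(f"unknown feature map {self.feature_map!r}") from None
        return fmap(_as_frame(X))

    def fit(self, X, y, training_ids=None) -> "MaxStackModel":
        design = self._design(X)
        y = np.asarray(y, float)
        if design.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if design.shape[0] < design.shape[1]:
            raise ValueError("need at least as many rows as coefficients")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise np.linalg.LinAlgError(
                "rank-deficient design: feature columns are collinear"
            )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.coef_ = coef
        self.n_features_in_ = design.shape[1]
        pred = design @ coef
        self.rmse_ = rmse(pred, y)
        self.r2_ = pearson_r2(pred, y)
        self.training_ids_ = list(training_ids) if training_ids is not None else []
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted")
        return self._design(X) @ self.coef_

    def coefficients(self) -> ModelCoefficients:
        return ModelCoefficients(
            c1=float(self.coef_[0]), c2=float(self.coef_[1]),
            feature_map=self.feature_map, rmse=self.rmse_, r2=self.r2_,
            training_ids=self.training_ids_,
        )

    @classmethod
    def from_coefficients(cls, coeffs: ModelCoefficients) -> "MaxStackModel":
        model = cls(feature_map=coeffs.feature_map)
        model.coef_ = np.array([coeffs.c1, coeffs.c2])
        model.n_features_in_ = 2
        model.rmse_ = coeffs.rmse
        model.r2_ = coeffs.r2
        model.training_ids_ = list(coeffs.training_ids)
        return model


# -- thin functional wrappers ------------------------------------------------


def fit_model(table: pd.DataFrame, target: str = "e_max",
              feature_map: str = "bilinear") -> ModelCoefficients:
    """Fit (c1, c2) on a table with descriptor columns and observed energies."""
    model = MaxStackModel(feature_map=feature_map)
    ids = table["pair_id"].tolist() if "pair_id" in table.columns else None
    model.fit(table, table[target].to_numpy(float), training_ids=ids)
    return model.coefficients()


def predict_max(features, coeffs: ModelCoefficients) -> np.ndarray | float:
    """Predicted maximum stacking energy (kcal/mol) for descriptor rows.

    ``features`` may be a DataFrame/array of rows or a single mapping with
    the four descriptor keys, in which case a scalar is returned.
    """
    single = isinstance(features, dict)
    if single:
        features = pd.DataFrame([features])
    pred = MaxStackModel.from_coefficients(coeffs).predict(features)
    return float(pred[0]) if single else pred


def evaluate_model(table: pd.DataFrame, coeffs: ModelCoefficients,
                   target: str = "e_max") -> tuple[float, float]:
    """(RMSE, r²) of the model on an evaluation table."""
    if len(table) == 0:
        raise ValueError("empty evaluation table")
    pred = predict_max(table, coeffs)
    obs = table[target].to_numpy(float)
    return rmse(pred, obs), pearson_r2(pred, obs)


def screen_library(library: pd.DataFrame, coeffs: ModelCoefficients,
                   nucleobases: str | list[str] = "AGCTU",
                   nucleobase_constants: dict | None = None) -> pd.DataFrame:
    """Predict maximum stacking of every library heterocycle with each base.

    ``library`` needs columns (mol_id, n_ha, esp_max).  Returns one row per
    (heterocycle, nucleobase) with the predicted maximum binding energy;
    per-nucleobase summaries are available via
    ``result.groupby('nucleobase')['e_max_pred'].describe()``.
    """
    needed = {"mol_id", "n_ha", "esp_max"}
    if not needed <= set(library.columns):
        raise KeyError(f"library table missing columns: {sorted(needed - set(library.columns))}")
    consts = nucleobase_constants or NUCLEOBASE_DESCRIPTORS
    rows = []
    for nuc in list(nucleobases):
        feats = pd.DataFrame({
            "n_ha_het": library["n_ha"].to_numpy(float),
            "n_ha_nuc": consts[nuc]["n_ha"],
            "esp_max_het": library["esp_max"].to_numpy(float),
            "esp_range_nuc": consts[nuc]["esp_range"],
        })
        pred = predict_max(feats, coeffs)
        rows.append(pd.DataFrame({
            "mol_id": library["mol_id"], "nucleobase": nuc, "e_max_pred": pred,
        }))
    return pd.concat(rows, ignore_index=True)
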