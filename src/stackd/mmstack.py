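"""Fixed-charge MM stacking energies with heavy-atom-pair vdW scaling.

The intermolecular interaction energy of a rigid stacked dimer is the sum
of a Coulomb term and a 12-6 Lennard-Jones term over all intermolecular
atom pairs.  Standard force fields systematically underbind stacked
aromatics by ~2 kcal/mol; two atom-type-independent constants C_R and C_A
scaling the repulsive (r⁻¹²) and attractive (r⁻⁶) vdW sums over
heavy-atom pairs recover sub-kcal/mol accuracy.  Pairs involving hydrogen
always use C_R = C_A = 1, so the split

    E(C_R, C_A) = E_coul + E_vdw,H + C_R·S_rep − C_A·S_att

is linear in the constants and their RMSE-optimal values follow from the
2×2 normal equations — a closed-form global optimum.

Conventions: AMBER-style A = ε·r_min¹², B = 2ε·r_min⁶ with
Lorentz–Berthelot combination (r_min,ij = r_min,i/2 + r_min,j/2,
ε_ij = √(ε_i ε_j)); energies in kcal/mol, distances in Å, charges in e.
σ/ε tables must be converted explicitly (r_min = 2^(1/6) σ) on import.
Because the scaling partly compensates charge-model error, a
:class:`ScalingFit` is tagged with its charge source and warns when applied
to a dataset tagged otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .chemstruct import Molecule
from .maxstack import pearson_r2, rmse
from .stackgeom import StackedDimer

__all__ = [
    "COULOMB_KCAL",
    "LJParams",
    "PairSums",
    "ScalingFit",
    "ScaledMMModel",
    "DEFAULT_ELEMENT_LJ",
    "assign_lj",
    "load_lj_table",
    "pair_sums",
    "interaction_energy",
    "fit_scaling",
    "evaluate_dataset",
]

COULOMB_KCAL = 332.0637

# Element-keyed fallback LJ parameters (r_min/2 in Å, ε in kcal/mol),
# GAFF-flavoured generic values for quick synthetic work; real studies load
# a force-field-specific table instead.
DEFAULT_ELEMENT_LJ: dict[str, tuple[float, float]] = {
    "H": (1.4870, 0.0157),
    "C": (1.9080, 0.0860),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
    "F": (1.75, 0.0610),
    "Cl": (1.948, 0.2650),
    "Br": (2.02, 0.4200),
    "P": (2.10, 0.2000),
}


class ParameterError(KeyError):
    """An atom has no entry in the LJ parameter table."""


@dataclass
class LJParams:
    """Per-atom 12-6 parameters for one molecule."""

    rmin_half: np.ndarray   # Å
    epsilon: np.ndarray     # kcal/mol
    source: str = "element-default"

    def __post_init__(self) -> None:
        self.rmin_half = np.asarray(self.rmin_half, float)
        self.epsilon = np.asarray(self.epsilon, float)
        if (self.epsilon < 0).any():
            raise ValueError("epsilon must be >= 0")
        if (self.rmin_half <= 0).any():
            raise ValueError("rmin_half must be > 0")


def load_lj_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read an LJ parameter table from CSV (key,rmin_half,epsilon) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
    df = pd.read_csv(path)
    key = "atom_type" if "atom_type" in df.columns else "element"
    return {
        str(r[key]): (float(r["rmin_half"]), float(r["epsilon"]))
        for _, r in df.iterrows()
    }


def assign_lj(mol: Molecule, table: dict[str, tuple[float, float]] | str | Path | None = None,
              atom_types: list[str] | None = None, source: str = "") -> LJParams:
    """Attach per-atom LJ parameters by atom type (if given) or element."""
    if table is None:
        table = DEFAULT_ELEMENT_LJ
        source = source or "element-default"
    elif isinstance(table, (str, Path)):
        source = source or str(table)
        table = load_lj_table(table)
    keys = atom_types if atom_types is not None else mol.symbols
    if atom_types is not None and len(atom_types) != len(mol):
        raise ValueError("atom_types length mismatch")
    rmh, eps = np.empty(len(mol)), np.empty(len(mol))
    for i, k in enumerate(keys):
        if k not in table:
            raise ParameterError(
                f"atom {i} ({mol.symbols[i]}, key {k!r}) has no LJ entry"
            )
        rmh[i], eps[i] = table[k]
    return LJParams(rmin_half=rmh, epsilon=eps, source=source)


@dataclass(frozen=True)
class PairSums:
    """Decomposed intermolecular pair sums of one dimer (kcal/mol).

    ``s_rep``/``s_att`` are the unscaled heavy–heavy r⁻¹²/r⁻⁶ LJ sums;
    ``e_vdw_h`` is the full LJ energy of every pair involving a hydrogen,
    which is never scaled.
    """

    e_coul: float
    s_rep: float
    s_att: float
    e_vdw_h: float

    def __post_init__(self) -> None:
        if self.s_rep < 0 or self.s_att < 0:
            raise ValueError("LJ pair sums must be nonnegative")


def pair_sums(dimer: StackedDimer, params_nuc: LJParams, params_het: LJParams) -> PairSums:
    """Intermolecular Coulomb and split LJ sums for a dimer.

    Strictly intermolecular and rigid-body: no cutoffs, no 1-4 terms, no
    intramolecular energy.
    """
    nuc, het = dimer.nucleobase, dimer.heterocycle
    d = np.linalg.norm(nuc.coords[:, None, :] - het.coords[None, :, :], axis=-1)
    if (d < 1e-6).any():
        raise ZeroDivisionError("overlapping atoms in dimer")
    e_coul = float(COULOMB_KCAL * np.sum(np.outer(nuc.charges, het.charges) / d))
    rmin = params_nuc.rmin_half[:, None] + params_het.rmin_half[None, :]
    eps = np.sqrt(np.outer(params_nuc.epsilon, params_het.epsilon))
    a = eps * rmin**12
    b = 2.0 * eps * rmin**6
    rep = a / d**12
    att = b / d**6
    heavy = np.outer(nuc.heavy_mask, het.heavy_mask)
    s_rep = float(rep[heavy].sum())
    s_att = float(att[heavy].sum())
    e_vdw_h = float((rep[~heavy] - att[~heavy]).sum())
    return PairSums(e_coul=e_coul, s_rep=s_rep, s_att=s_att, e_vdw_h=e_vdw_h)


def interaction_energy(sums: PairSums, c_r: float = 1.0, c_a: float = 1.0) -> float:
    """Scaled MM interaction energy; (1, 1) is the standard unscaled potential."""
    return sums.e_coul + sums.e_vdw_h + c_r * sums.s_rep - c_a * sums.s_att


@dataclass
class ScalingFit:
    """Fitted C_R/C_A with before/after performance on the fitting set."""

    c_r: float
    c_a: float
    rmse_before: float
    rmse_after: float
    r2_before: float
    r2_after: float
    charge_source: str = ""
    n_rows: int = 0

    def __post_init__(self) -> None:
        if self.rmse_after > self.rmse_before + 1e-9:
            raise ValueError("least-squares fit cannot worsen the RMSE")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("c_r", "c_a", "rmse_before", "rmse_after", "r2_before",
                 "r2_after", "charge_source", "n_rows")}


_SUM_COLS = ["e_coul", "s_rep", "s_att", "e_vdw_h"]


def _sums_frame(dataset: pd.DataFrame | list) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        missing = [c for c in _SUM_COLS + ["e_ref"] if c not in dataset.columns]
        if missing:
            raise KeyError(f"dataset missing columns: {missing}")
        return dataset
    rows = [
        {"e_coul": s.e_coul, "s_rep": s.s_rep, "s_att": s.s_att,
         "e_vdw_h": s.e_vdw_h, "e_ref": e}
        for s, e in dataset
    ]
    return pd.DataFrame(rows)


class ScaledMMModel(BaseEstimator, RegressorMixin):
    """Estimator form of the scaled MM potential.

    ``fit`` solves the 2×2 normal equations for (C_R, C_A) against reference
    interaction energies; ``predict`` evaluates the scaled energy on rows of
    precomputed pair sums.  X is a DataFrame with columns
    (e_coul, s_rep, s_att, e_vdw_h).
    """

    def __init__(self, charge_source: str = ""):
        self.charge_source = charge_source

    def fit(self, X, y) -> "ScaledMMModel":
        df = _sums_frame(X) if not isinstance(X, pd.DataFrame) else X
        y = np.asarray(y, float)
        if len(df) < 2:
            raise ValueError("need >= 2 rows to fit two constants")
        design = df[["s_rep", "s_att"]].to_numpy(float) * np.array([1.0, -1.0])
        if np.linalg.matrix_rank(design) < 2:
            raise np.linalg.LinAlgError("collinear s_rep/s_att columns")
        target = y - df["e_coul"].to_numpy(float) - df["e_vdw_h"].to_numpy(float)
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        self.c_r_, self.c_a_ = float(coef[0]), float(coef[1])
        self.n_features_in_ = 2
        return self

    def predict(self, X) -> np.ndarray:
        df = _sums_frame(X) if not isinstance(X, pd.DataFrame) else X
        return (df["e_coul"].to_numpy(float) + df["e_vdw_h"].to_numpy(float)
                + self.c_r_ * df["s_rep"].to_numpy(float)
                - self.c_a_ * df["s_att"].to_numpy(float))


def fit_scaling(dataset, charge_source: str = "") -> ScalingFit:
    """Fit C_R/C_A to minimise RMSE against reference interaction energies.

    ``dataset`` is either a DataFrame with columns (e_coul, s_rep, s_att,
    e_vdw_h, e_ref) or an iterable of (PairSums, reference energy) pairs.
    """
    df = _sums_frame(dataset)
    y = df["e_ref"].to_numpy(float)
    model = ScaledMMModel(charge_source=charge_source).fit(df, y)
    unscaled = (df["e_coul"] + df["e_vdw_h"] + df["s_rep"] - df["s_att"]).to_numpy(float)
    pred = model.predict(df)
    return ScalingFit(
        c_r=model.c_r_, c_a=model.c_a_,
        rmse_before=rmse(unscaled, y), rmse_after=rmse(pred, y),
        r2_before=pearson_r2(unscaled, y), r2_after=pearson_r2(pred, y),
        charge_source=charge_source, n_rows=len(df),
    )


def evaluate_dataset(dataset, c_r: float = 1.0, c_a: float = 1.0,
                     charge_source: str = "",
                     fit: ScalingFit | None = None) -> tuple[float, float]:
    """(RMSE, r²) of the (scaled) MM energies against the reference column.

    When a :class:`ScalingFit` is supplied its constants are used, and a
    warning is emitted if the dataset's charge source differs from the one
    the constants were fit with (they are not transferable across charge
    models).
    """
    df = _sums_frame(dataset)
    if fit is not None:
        if charge_source and fit.charge_source and charge_source != fit.charge_source:
            warnings.warn(
                f"scaling fit for charges {fit.charge_source!r} applied to "
                f"{charge_source!r}: constants are charge-model-specific",
                stacklevel=2,
            )
        c_r, c_a = fit.c_r, fit.c_a
    pred = (df["e_coul"] + df["e_vdw_h"] + c_r * df["s_rep"] - c_a * df["s_att"]).to_numpy(float)
    y = df["e_ref"].to_numpy(float)
    return rmse(pred, y), pearson_r2(pred, y)
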