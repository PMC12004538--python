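"""Analysis statistics for stacking datasets.

Covers the energy-decomposition correlation analysis (which SAPT components
track the total interaction energy, and which are indispensable), linear
regression of the total on a single component, per-pair dataset summaries,
cross-nucleobase correlation of binding energies, tautomer-shift
arithmetic, and the stacking-efficiency metric used to judge how close a
crystallographic pose comes to the optimal stacked geometry.

All correlations are squared Pearson on raw, unweighted rows.  Degenerate
(zero-variance) correlations report 0 with a warning so dataset sweeps run
to completion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maxstack import pearson_r2

__all__ = [
    "COMPONENTS",
    "TautomerPair",
    "component_correlations",
    "regress_on_component",
    "summarize_minima",
    "base_cross_correlations",
    "tautomer_shift",
    "stacking_efficiency",
]

COMPONENTS = ["elec", "exch", "ind", "disp"]


def component_correlations(table: pd.DataFrame, total: str = "total") -> pd.DataFrame:
    """Per-component r² with the total, and r² of the total *without* it.

    For each SAPT component X the first row gives r²(X, E_int) — how well the
    component alone tracks the total — while the second gives
    r²(E_int − X, E_int): a component is determinative when removing it
    collapses the correlation (electrostatics, dispersion) and dispensable
    when the remainder correlates even better (induction, exchange near
    minima).
    """
    if len(table) < 3:
        raise ValueError("need >= 3 rows for correlation analysis")
    missing = [c for c in COMPONENTS + [total] if c not in table.columns]
    if missing:
        raise KeyError(f"component table missing columns: {missing}")
    if table[COMPONENTS + [total]].isna().any().any():
        raise ValueError("rows with missing components are not admitted")
    tot = table[total].to_numpy(float)
    out = {}
    for comp in COMPONENTS:
        x = table[comp].to_numpy(float)
        out[comp] = {
            "r2": pearson_r2(x, tot),
            "r2_without": pearson_r2(tot - x, tot),
        }
    return pd.DataFrame(out).T[["r2", "r2_without"]]


def regress_on_component(table: pd.DataFrame, component: str = "elec",
                         total: str = "total") -> tuple[float, float, float]:
    """OLS of the total interaction energy on one component.

    Returns (slope, intercept, rmse of residuals); a strong single-component
    regression (RMSE ≈ 1 kcal/mol on optimised dimers for E_elec) shows that
    one component can stand in for the full decomposition near minima.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 rows")
    x = table[component].to_numpy(float)
    y = table[total].to_numpy(float)
    if x.std() == 0:
        raise np.linalg.LinAlgError(f"zero-variance predictor {component!r}")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2)))


def summarize_minima(df: pd.DataFrame, energy: str = "e_bind",
                     by: tuple[str, ...] = ("het", "nuc")) -> pd.DataFrame:
    """Per-pair count, strongest (most negative) and mean binding energy.

    Empty groups are dropped with a warning; input row order is irrelevant.
    """
    cols = list(by) + [energy]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    valid = df.dropna(subset=[energy])
    if len(valid) < len(df):
        warnings.warn(f"dropped {len(df) - len(valid)} rows without {energy}",
                      stacklevel=2)
    g = valid.groupby(list(by))[energy]
    out = pd.DataFrame({
        "count": g.size(),
        "e_max": g.min(),   # most negative = strongest binding
        "e_mean": g.mean(),
    }).reset_index()
    return out


def base_cross_correlations(maxtable: pd.DataFrame,
                            het: str = "het") -> pd.DataFrame:
    """r² matrix of per-heterocycle energies across nucleobase columns.

    ``maxtable`` has one row per heterocycle and one column per nucleobase
    (e.g. the global-minimum binding energies).  Every nucleobase column
    must cover the same heterocycle set; the result is symmetric with unit
    diagonal.
    """
    df = maxtable.set_index(het) if het in maxtable.columns else maxtable
    if df.isna().any().any():
        raise ValueError("nucleobase columns cover different heterocycle sets")
    bases = list(df.columns)
    mat = pd.DataFrame(np.eye(len(bases)), index=bases, columns=bases)
    for i, a in enumerate(bases):
        for b in bases[i + 1:]:
            r2 = pearson_r2(df[a].to_numpy(float), df[b].to_numpy(float))
            mat.loc[a, b] = mat.loc[b, a] = r2
    return mat


@dataclass(frozen=True)
class TautomerPair:
    """An annular tautomer pair with its gas-phase tautomerization energy.

    ``delta_e_het`` is ΔE(het) = E(t2) − E(t1) for the isolated heterocycle
    (positive: t1 favored).  ``be_t1``/``be_t2`` map nucleobase → global-
    minimum binding energy of each tautomer's stacked dimer.
    """

    t1: str
    t2: str
    delta_e_het: float
    be_t1: dict
    be_t2: dict


def tautomer_shift(pair: TautomerPair, nucleobase: str) -> float:
    """Stacked tautomerization energy ΔE(het···nuc) in kcal/mol.

    ΔE(het···nuc) = ΔE(het) + [BE(t2···nuc) − BE(t1···nuc)]: the isolated
    preference shifted by how much more strongly each tautomer stacks.  A
    sign change relative to ΔE(het) means stacking swaps the preferred
    tautomer.
    """
    try:
        be1 = pair.be_t1[nucleobase]
        be2 = pair.be_t2[nucleobase]
    except KeyError as exc:
        raise KeyError(
            f"missing global-minimum binding energy for nucleobase {exc}"
        ) from None
    if be1 is None or be2 is None:
        raise ValueError("missing binding energy for one tautomer")
    return pair.delta_e_het + (be2 - be1)


def swaps_preferred_tautomer(pair: TautomerPair, nucleobase: str) -> bool:
    """True when stacking flips the sign of the tautomer preference."""
    shifted = tautomer_shift(pair, nucleobase)
    return bool(np.sign(shifted) * np.sign(pair.delta_e_het) < 0)


def stacking_efficiency(e_pose: float, e_max: float) -> int:
    """Pose energy as an integer percentage of the maximum stacking energy.

    Both energies must be negative (attractive); 100% means the pose
    achieves the full global-minimum stacking interaction.  Rounds half
    away from zero to match the integer-percent granularity used when
    comparing crystallographic poses with model dimers.
    """
    if e_max >= 0:
        raise ValueError("e_max must be negative (attractive)")
    if e_pose >= 0:
        raise ValueError("e_pose must be negative (attractive)")
    pct = 100.0 * e_pose / e_max
    return int(np.floor(pct + 0.5))
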