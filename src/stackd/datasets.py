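"""Loaders for the small reference tables bundled with the package."""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .stackstats import TautomerPair

__all__ = [
    "nucleobase_descriptor_table",
    "tautomer_table",
    "tautomer_pairs",
    "ribocil_contacts",
    "lj_element_table",
]

_BASES = ["A", "C", "G", "T", "U"]


def _path(name: str):
    return resources.files("stackd.data").joinpath(name)


def nucleobase_descriptor_table() -> pd.DataFrame:
    """N_HA and ESP_range constants for the five natural nucleobases."""
    with resources.as_file(_path("nucleobase_descriptors.csv")) as p:
        return pd.read_csv(p)


def tautomer_table() -> pd.DataFrame:
    """Tautomerization energies (kcal/mol) of six annular tautomer pairs.

    ``delta_e_het`` is the isolated-heterocycle value; the per-nucleobase
    columns are the stacked-dimer values ΔE(het···nuc) at the respective
    global-minimum geometries.
    """
    with resources.as_file(_path("tautomer_table.csv")) as p:
        return pd.read_csv(p, dtype={"t1": str, "t2": str})


def tautomer_pairs() -> dict[tuple[str, str], TautomerPair]:
    """Bundled tautomer pairs as :class:`TautomerPair` objects.

    The table stores the *shifted* values ΔE(het···nuc); the implied
    binding-energy differences BE(t2) − BE(t1) = ΔE(het···nuc) − ΔE(het)
    are reconstructed here (with BE(t1) pinned at 0, which the shift
    identity never depends on).
    """
    out = {}
    for _, row in tautomer_table().iterrows():
        be1 = {b: 0.0 for b in _BASES}
        be2 = {b: float(row[b]) - float(row["delta_e_het"]) for b in _BASES}
        out[(row["t1"], row["t2"])] = TautomerPair(
            t1=row["t1"], t2=row["t2"], delta_e_het=float(row["delta_e_het"]),
            be_t1=be1, be_t2=be2,
        )
    return out


def ribocil_contacts() -> dict:
    """Stacking energies of the ribocil worked example (kcal/mol)."""
    return json.loads(_path("ribocil_stacking.json").read_text())


def lj_element_table() -> dict[str, tuple[float, float]]:
    raw = json.loads(_path("lj_element_default.json").read_text())
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}
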