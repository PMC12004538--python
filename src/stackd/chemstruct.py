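"""Molecular structures and tabular records for stacking calculations.

The central container is :class:`Molecule`: an ordered list of atoms
(element, Cartesian coordinates in Å, partial charge in elementary charge
units, van der Waals radius in Å) plus perceived aromatic/ring systems.
Structures are read from XYZ, SDF (V2000) and the coordinate subset of PDB
files, or built from SMILES via RDKit embedding.  Energies live in
:class:`EnergyRecord` rows collected into :class:`DatasetTable` objects
whose schemas mirror the CSV conventions used throughout the package
(comma-separated, header row, energies in kcal/mol, lengths in Å).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Molecule",
    "EnergyRecord",
    "DatasetTable",
    "FormatError",
    "ElementError",
    "AlignmentError",
    "BONDI_RADII",
    "COVALENT_RADII",
    "read_structure",
    "write_structure",
    "from_smiles",
    "assign_charges",
    "register_charge_provider",
    "heavy_atom_count",
    "infer_bonds",
    "detect_rings",
]


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class ElementError(ValueError):
    """An element symbol is not recognised."""


class AlignmentError(ValueError):
    """Tabular data does not align with the molecule's atom list."""


class ConfigurationError(ValueError):
    """An unknown provider or option name."""


# Bondi vdW radii (Å); overridable per call.  Values beyond CHNOS cover the
# halogens and P/Se occasionally present in druglike heterocycles.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "F": 1.47, "Cl": 1.75, "Br": 1.85, "I": 1.98, "P": 1.80, "Se": 1.90,
    "B": 1.92,
}

# Covalent radii (Å, Cordero 2008) for geometric bond inference on formats
# that carry no connectivity (XYZ).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
}

_PERIODIC = {
    "h": "H", "b": "B", "c": "C", "n": "N", "o": "O", "f": "F", "p": "P",
    "s": "S", "cl": "Cl", "br": "Br", "i": "I", "se": "Se",
}


def _normalize_element(symbol: str) -> str:
    key = symbol.strip().lower()
    if key not in _PERIODIC:
        raise ElementError(f"unknown element symbol: {symbol!r}")
    return _PERIODIC[key]


@dataclass
class Molecule:
    """A small molecule with coordinates, charges and ring perception.

    Attributes
    ----------
    name : str
        Free-text label.
    symbols : list of str
        Element symbols, normalised capitalisation.
    coords : (n, 3) ndarray
        Cartesian coordinates in Å.
    charges : (n,) ndarray
        Partial charges in elementary charge units (zero-filled if unknown).
    vdw_radii : (n,) ndarray
        Per-atom van der Waals radii in Å.
    ring_systems : list of list of int
        Atom-index lists of perceived rings (each ≥ 5 members counting all
        ring atoms, aromatic five- and six-membered rings included).
    net_charge : float
        Declared total molecular charge.
    tautomer_id : str or None
        Optional annular-tautomer label.
    glycosidic_n : int or None
        Index of the glycosidic nitrogen for nucleobases (orientation anchor).
    """

    name: str
    symbols: list[str]
    coords: np.ndarray
    charges: np.ndarray = None  # type: ignore[assignment]
    vdw_radii: np.ndarray = None  # type: ignore[assignment]
    ring_systems: list[list[int]] = field(default_factory=list)
    net_charge: float = 0.0
    tautomer_id: str | None = None
    glycosidic_n: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.symbols)
        if self.coords.shape[0] != n:
            raise ValueError("coords and symbols length mismatch")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float).reshape(n)
        if self.vdw_radii is None:
            self.vdw_radii = np.array(
                [BONDI_RADII.get(s, 1.70) for s in self.symbols]
            )
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float).reshape(n)
        if (self.vdw_radii <= 0).any():
            raise ValueError("vdW radii must be positive")
        for ring in self.ring_systems:
            if len(ring) < 5:
                raise ValueError("rings must have >= 5 members")
            if any(i < 0 or i >= n for i in ring):
                raise ValueError("ring atom index out of range")

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([s != "H" for s in self.symbols])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.nonzero(self.heavy_mask)[0]

    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_mask]

    def copy(self) -> "Molecule":
        return replace(
            self,
            symbols=list(self.symbols),
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            vdw_radii=self.vdw_radii.copy(),
            ring_systems=[list(r) for r in self.ring_systems],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def validate_charges(self, tol: float = 1e-6) -> None:
        total = float(self.charges.sum())
        if abs(total - self.net_charge) > tol:
            raise ValueError(
                f"charges sum to {total:.6f}, declared net {self.net_charge:.6f}"
            )


def heavy_atom_count(mol: Molecule) -> int:
    """Number of non-hydrogen atoms (the N_HA size descriptor)."""
    return int(mol.heavy_mask.sum())


# ---------------------------------------------------------------------------
# bond / ring perception for connectivity-free formats


def infer_bonds(
    symbols: Sequence[str], coords: np.ndarray, scale: float = 1.2
) -> list[tuple[int, int]]:
    """Covalent-radius bonding: i-j bonded iff r_ij <= scale * (rc_i + rc_j)."""
    coords = np.asarray(coords, float)
    rc = np.array([COVALENT_RADII.get(s, 0.76) for s in symbols])
    n = len(symbols)
    bonds = []
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = scale * (rc[i] + rc[i + 1:])
        for k in np.nonzero((d <= cut) & (d > 1e-3))[0]:
            bonds.append((i, i + 1 + int(k)))
    return bonds


def detect_rings(
    symbols: Sequence[str], coords: np.ndarray, bonds: Iterable[tuple[int, int]] | None = None
) -> list[list[int]]:
    """Smallest set of smallest rings from the bond graph (cycle basis)."""
    import networkx as nx

    if bonds is None:
        bonds = infer_bonds(symbols, coords)
    g = nx.Graph(list(bonds))
    rings = [sorted(c) for c in nx.minimum_cycle_basis(g) if len(c) >= 5]
    return sorted(rings)


# ---------------------------------------------------------------------------
# readers / writers


def _read_xyz(path: Path) -> Molecule:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line 1: expected atom count") from exc
    if len(lines) < n + 2:
        raise FormatError(f"{path}: truncated, expected {n} atom lines")
    name = lines[1].strip() or path.stem
    symbols, coords = [], []
    for ln, raw in enumerate(lines[2 : 2 + n], start=3):
        parts = raw.split()
        if len(parts) < 4:
            raise FormatError(f"{path}: line {ln}: expected 'El x y z'")
        symbols.append(_normalize_element(parts[0]))
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln}: bad coordinate") from exc
    rings = detect_rings(symbols, np.asarray(coords))
    return Molecule(name=name, symbols=symbols, coords=np.asarray(coords),
                    ring_systems=rings)


def _mol_from_rdkit(rdmol, name: str) -> Molecule:
    from rdkit import Chem

    conf = rdmol.GetConformer()
    symbols = [a.GetSymbol() for a in rdmol.GetAtoms()]
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(rdmol.GetNumAtoms())])
    ri = rdmol.GetRingInfo()
    rings = sorted(sorted(r) for r in ri.AtomRings() if len(r) >= 5)
    charges = np.zeros(len(symbols))
    net = Chem.GetFormalCharge(rdmol)
    return Molecule(name=name, symbols=symbols, coords=coords, charges=charges,
                    ring_systems=[list(r) for r in rings], net_charge=float(net))


def read_structure(path: str | Path, format: str | None = None) -> Molecule:
    """Read a structure file (xyz, sdf or pdb) into a :class:`Molecule`.

    Charges are zero-filled; use :func:`assign_charges` to attach them.
    Ring perception uses the file's aromatic/bond records for SDF and PDB
    (via RDKit) and geometric covalent-radius bonding for XYZ.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        rdmol = next(iter(supplier), None)
        if rdmol is None:
            raise FormatError(f"{path}: no parseable molecule (line 1)")
        return _mol_from_rdkit(rdmol, rdmol.GetProp("_Name") or path.stem)
    if fmt == "pdb":
        rdmol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=True)
        if rdmol is None:
            raise FormatError(f"{path}: unparseable PDB coordinate records")
        return _mol_from_rdkit(rdmol, path.stem)
    raise FormatError(f"unsupported format: {fmt}")


def write_structure(mol: Molecule, path: str | Path, format: str | None = None) -> None:
    """Write XYZ or SDF.  XYZ keeps full float precision for round-trips."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        lines = [str(len(mol)), mol.name]
        for s, (x, y, z) in zip(mol.symbols, mol.coords):
            lines.append(f"{s} {x:.10f} {y:.10f} {z:.10f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "sdf":
        from rdkit import Chem

        rw = Chem.RWMol()
        conf = Chem.Conformer(len(mol))
        for i, s in enumerate(mol.symbols):
            rw.AddAtom(Chem.Atom(s))
            conf.SetAtomPosition(i, tuple(mol.coords[i]))
        for i, j in infer_bonds(mol.symbols, mol.coords):
            rw.AddBond(i, j, Chem.BondType.SINGLE)
        m = rw.GetMol()
        m.AddConformer(conf)
        m.SetProp("_Name", mol.name)
        with Chem.SDWriter(str(path)) as w:
            w.SetKekulize(False)
            w.SetForceV3000(True)  # free-format coords keep 1e-6 round-trips
            w.write(m)
        return
    raise FormatError(f"unsupported format: {fmt}")


# ---------------------------------------------------------------------------
# SMILES


def from_smiles(smiles: str, name: str | None = None, seed: int = 2025,
                planarize: bool = True) -> Molecule:
    """Build a 3D :class:`Molecule` from SMILES via RDKit ETKDG embedding.

    Aromatic-ring atoms are flattened onto their least-squares plane after
    embedding so planar heterocycles are planar to well under 0.05 Å, as the
    stacked-dimer constructors assume.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise FormatError(f"invalid SMILES: {smiles!r}")
    rdmol = Chem.AddHs(rdmol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(rdmol, params) != 0:
        raise RuntimeError(f"3D embedding failed for {smiles!r}")
    AllChem.MMFFOptimizeMolecule(rdmol, maxIters=500)
    mol = _mol_from_rdkit(rdmol, name or smiles)
    if planarize:
        aromatic = [a.GetIdx() for a in rdmol.GetAtoms() if a.GetIsAromatic()]
        # flatten aromatic atoms and their attached hydrogens onto the plane
        attached_h = [
            a.GetIdx() for a in rdmol.GetAtoms()
            if a.GetSymbol() == "H"
            and any(nb.GetIdx() in aromatic for nb in a.GetNeighbors())
        ]
        group = aromatic + attached_h
        if len(aromatic) >= 3:
            pts = mol.coords[aromatic]
            centroid = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - centroid)
            normal = vt[2]
            for i in group:
                v = mol.coords[i] - centroid
                mol.coords[i] = mol.coords[i] - np.dot(v, normal) * normal
    return mol


# ---------------------------------------------------------------------------
# charges

_CHARGE_PROVIDERS: dict[str, Callable[[Molecule], np.ndarray]] = {}


def register_charge_provider(name: str, func: Callable[[Molecule], np.ndarray]) -> None:
    """Register an external charge generator (e.g. an AM1-BCC wrapper).

    Charge *generation* is deliberately external: the package imports charges
    as data (tables or providers) and performs no QM itself.
    """
    _CHARGE_PROVIDERS[name] = func


def assign_charges(mol: Molecule, source: str | Path | Callable,
                   neutralize: bool = False, net_charge: float | None = None) -> Molecule:
    """Attach partial charges from a CSV table or a registered provider.

    CSV schema: columns ``atom_index, charge`` (0-based, one row per atom).
    With ``neutralize=True`` a uniform per-atom correction shifts the sum to
    the declared net charge (a no-op when it already matches).  Without an
    explicit ``net_charge`` and without neutralization the table defines the
    net: the molecule's declared charge is updated to the table sum.
    """
    out = mol.copy()
    if net_charge is not None:
        out.net_charge = float(net_charge)
    if callable(source):
        q = np.asarray(source(mol), float)
    elif isinstance(source, (str, Path)) and Path(str(source)).exists():
        df = pd.read_csv(source)
        if not {"atom_index", "charge"} <= set(df.columns):
            raise FormatError("charge table needs columns atom_index, charge")
        if len(df) != len(mol):
            raise AlignmentError(
                f"charge table has {len(df)} rows for {len(mol)} atoms"
            )
        q = np.empty(len(mol))
        q[df["atom_index"].to_numpy(int)] = df["charge"].to_numpy(float)
    elif isinstance(source, str) and source in _CHARGE_PROVIDERS:
        q = np.asarray(_CHARGE_PROVIDERS[source](mol), float)
    else:
        raise ConfigurationError(f"unknown charge source: {source!r}")
    if q.shape != (len(mol),):
        raise AlignmentError("provider returned wrong charge count")
    total = float(q.sum())
    if net_charge is None and not neutralize:
        out.net_charge = total
    if neutralize and abs(total - out.net_charge) > 1e-12:
        q = q + (out.net_charge - total) / len(mol)
    out.charges = q
    if abs(q.sum() - out.net_charge) > 1e-4:
        raise ValueError(
            f"charges sum to {q.sum():.6f} but net charge is {out.net_charge}"
            " (pass neutralize=True to spread the correction)"
        )
    return out


# ---------------------------------------------------------------------------
# tabular container


@dataclass
class EnergyRecord:
    """One dimer's energies in kcal/mol (binding and/or interaction).

    ``binding_energy`` compares the optimised dimer with separately optimised
    monomers; ``interaction_energy`` uses the monomers frozen in the dimer
    geometry.  SAPT-complete rows carry the four components whose sum must
    reproduce the interaction energy.
    """

    pair_id: tuple[str, str]
    binding_energy: float | None = None
    interaction_energy: float | None = None
    elec: float | None = None
    exch: float | None = None
    ind: float | None = None
    disp: float | None = None
    method: str = ""
    dataset_tag: str = "other"
    sapt_complete: bool = False

    def __post_init__(self) -> None:
        if self.dataset_tag not in {"OSD", "NRSD", "FRSD", "other"}:
            raise ValueError(f"bad dataset_tag {self.dataset_tag!r}")
        comps = (self.elec, self.exch, self.ind, self.disp)
        if self.sapt_complete:
            if any(c is None for c in comps) or self.interaction_energy is None:
                raise ValueError("sapt_complete row missing components")
            if abs(sum(comps) - self.interaction_energy) > 1e-3:
                raise ValueError(
                    "SAPT components do not sum to the interaction energy"
                )


ENERGY_SCHEMA = ["pair_id", "pose_id", "e_bind", "e_int", "elec", "exch", "ind", "disp"]
DESCRIPTOR_SCHEMA = ["mol_id", "n_ha", "esp_max", "esp_min", "esp_mean", "esp_range"]


class DatasetTable:
    """A keyed table of dimer rows with a declared schema.

    Thin wrapper over a pandas DataFrame that enforces the declared columns
    and uniqueness of the (pair_id, pose_id) key on load, so downstream
    analyses can assume a clean table.
    """

    def __init__(self, df: pd.DataFrame, schema: Sequence[str] = ENERGY_SCHEMA,
                 provenance: str = "") -> None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        if {"pair_id", "pose_id"} <= set(df.columns):
            if df.duplicated(["pair_id", "pose_id"]).any():
                raise ValueError("duplicate (pair_id, pose_id) keys")
        self.df = df.reset_index(drop=True)
        self.schema = list(schema)
        self.provenance = provenance

    @classmethod
    def read_csv(cls, path: str | Path, schema: Sequence[str] = ENERGY_SCHEMA,
                 column_map: dict[str, str] | str | Path | None = None,
                 provenance: str | None = None) -> "DatasetTable":
        """Load a CSV, optionally renaming columns through a schema map.

        ``column_map`` may be a dict or a JSON file of {source: canonical}
        names, so externally produced tables drop in without code changes.
        """
        df = pd.read_csv(path)
        if isinstance(column_map, (str, Path)):
            column_map = json.loads(Path(column_map).read_text())
        if column_map:
            df = df.rename(columns=column_map)
        return cls(df, schema=schema, provenance=provenance or str(path))

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)
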