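"""Deterministic synthetic data generators.

Every generator is a pure function of a :class:`SynthSpec` (seed, size,
noise level, generative parameters), so tests and calibration runs are
reproducible bit-for-bit.  The generators emulate the structure of real
stacking datasets — planar aromatic molecules with partial charges,
descriptor/energy tables following the bilinear maximum-stacking form,
dimer datasets whose reference energies come from a known Coulomb + LJ
ground truth with planted scaling constants, and SAPT-style component
tables with a controllable correlation structure — without emulating
QM-level energy surfaces.  Noise is Gaussian and homoscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .chemstruct import Molecule
from .espdesc import NUCLEOBASE_DESCRIPTORS
from .mmstack import assign_lj, interaction_energy, pair_sums
from .stackgeom import place_stacked, sample_frsd

__all__ = [
    "SynthSpec",
    "toy_ring",
    "synth_eq1_table",
    "synth_mm_dataset",
    "synth_component_table",
    "si_fixture",
    "SI_FIXTURE_COUNTS",
]


@dataclass(frozen=True)
class SynthSpec:
    """Immutable recipe for one synthetic dataset."""

    seed: int = 0
    n: int = 100
    noise_sigma: float = 0.0
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def toy_ring(n_atoms: int = 6, radius: float = 1.39,
             charge_pattern: str | np.ndarray = "zero",
             q: float = 0.1, name: str = "toy-ring",
             apex: bool = False) -> Molecule:
    """Planar regular polygon of carbons, optionally with an apex substituent.

    ``charge_pattern`` is "zero", "alternating" (±q around the ring, net 0
    for even rings) or an explicit per-atom array.  The default radius gives
    benzene-like 1.39 Å edges for n=6 (edge = 2 R sin(π/n)).
    """
    if n_atoms < 3:
        raise ValueError("a ring needs >= 3 atoms")
    ang = 2 * np.pi * np.arange(n_atoms) / n_atoms
    # polygon circumradius chosen so the edge length equals `radius`
    circum = radius / (2 * np.sin(np.pi / n_atoms))
    coords = np.column_stack([circum * np.cos(ang), circum * np.sin(ang),
                              np.zeros(n_atoms)])
    symbols = ["C"] * n_atoms
    if isinstance(charge_pattern, str):
        if charge_pattern == "zero":
            charges = np.zeros(n_atoms)
        elif charge_pattern == "alternating":
            charges = q * (-1.0) ** np.arange(n_atoms)
        else:
            raise ValueError(f"unknown charge pattern {charge_pattern!r}")
    else:
        charges = np.asarray(charge_pattern, float)
        if charges.shape != (n_atoms,):
            raise ValueError("charge pattern length mismatch")
    if apex:
        symbols.append("N")
        coords = np.vstack([coords, [circum + 1.34, 0.0, 0.0]])
        charges = np.append(charges, 0.0)
    return Molecule(name=name, symbols=symbols, coords=coords, charges=charges,
                    net_charge=float(charges.sum()),
                    ring_systems=[list(range(n_atoms))] if n_atoms >= 5 else [])


def synth_eq1_table(spec: SynthSpec) -> pd.DataFrame:
    """Descriptor/energy table following the bilinear maximum-stacking form.

    Heterocycle features are drawn uniformly (N_HA in [5, 16], ESP_max in
    [−10, 40] kcal/mol — bracketing the descriptor ranges of druglike
    heterocycles); nucleobase descriptors come from the bundled constants.
    Observed energies are model(c1, c2) plus Gaussian noise.
    """
    c1 = float(spec.params.get("c1", -0.05))
    c2 = float(spec.params.get("c2", -0.01))
    rng = np.random.default_rng(spec.seed)
    bases = list(NUCLEOBASE_DESCRIPTORS)
    n_ha_het = rng.integers(5, 17, size=spec.n)
    esp_max_het = rng.uniform(-10.0, 40.0, size=spec.n)
    nucs = rng.choice(bases, size=spec.n)
    n_ha_nuc = np.array([NUCLEOBASE_DESCRIPTORS[b]["n_ha"] for b in nucs])
    esp_range_nuc = np.array([NUCLEOBASE_DESCRIPTORS[b]["esp_range"] for b in nucs])
    e = (c1 * n_ha_het * n_ha_nuc + c2 * esp_max_het * esp_range_nuc
         + rng.normal(0.0, spec.noise_sigma, size=spec.n))
    return pd.DataFrame({
        "pair_id": [f"het{i}-{b}" for i, b in enumerate(nucs)],
        "n_ha_het": n_ha_het.astype(float),
        "n_ha_nuc": n_ha_nuc.astype(float),
        "esp_max_het": esp_max_het,
        "esp_range_nuc": esp_range_nuc,
        "e_max": e,
    })


def synth_mm_dataset(spec: SynthSpec) -> pd.DataFrame:
    """Random-pose dimer dataset with a known Coulomb+LJ ground truth.

    Toy charged rings are stacked in fully random poses; each row carries
    the decomposed pair sums and a reference energy generated by the scaled
    potential with planted constants (c_r, c_a) plus Gaussian noise, so
    scaling fits can be validated by parameter recovery.
    """
    c_r = float(spec.params.get("c_r", 1.0))
    c_a = float(spec.params.get("c_a", 1.0))
    het = toy_ring(5, 1.37, "alternating", q=0.12, name="toy-het", apex=True)
    nuc = toy_ring(6, 1.39, "alternating", q=0.15, name="toy-nuc")
    lj_het = assign_lj(het)
    lj_nuc = assign_lj(nuc)
    dimers = sample_frsd(het, nuc, spec.n, seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for d in dimers:
        s = pair_sums(d, lj_nuc, lj_het)
        e_ref = interaction_energy(s, c_r, c_a) + rng.normal(0.0, spec.noise_sigma)
        rows.append({
            "pose_id": d.pose_id, "e_coul": s.e_coul, "s_rep": s.s_rep,
            "s_att": s.s_att, "e_vdw_h": s.e_vdw_h, "e_ref": e_ref,
        })
    cols = ["pose_id", "e_coul", "s_rep", "s_att", "e_vdw_h", "e_ref"]
    return pd.DataFrame(rows, columns=cols)


def synth_component_table(spec: SynthSpec) -> pd.DataFrame:
    """SAPT-style component table with controllable correlation structure.

    Each component is loading·t + sigma·noise around a shared latent t, and
    the total is the exact per-row sum of the four components, so the
    population r²(X, Total) values follow from the chosen loadings and
    noise scales (larger loading relative to its noise → stronger
    correlation with the total).
    """
    loadings = np.asarray(spec.params.get("loadings", [1.0, 0.5, 0.3, 0.8]), float)
    sigmas = np.asarray(spec.params.get("sigmas", [0.2, 0.2, 0.2, 0.2]), float)
    if loadings.shape != (4,) or sigmas.shape != (4,):
        raise ValueError("loadings and sigmas must each have 4 entries")
    if (sigmas < 0).any():
        raise ValueError("infeasible correlation structure: negative sigma")
    if np.all(loadings == 0) and np.all(sigmas == 0):
        raise ValueError("infeasible correlation structure: all-zero components")
    rng = np.random.default_rng(spec.seed)
    t = rng.normal(size=spec.n)
    comps = loadings[None, :] * t[:, None] + sigmas[None, :] * rng.normal(size=(spec.n, 4))
    df = pd.DataFrame(comps, columns=["elec", "exch", "ind", "disp"])
    df.insert(0, "pose_id", [f"pose{i}" for i in range(spec.n)])
    df.insert(0, "pair_id", "synth")
    df["total"] = df[["elec", "exch", "ind", "disp"]].sum(axis=1)
    return df


# documented per-pair local-minima counts of the bundled fixture
SI_FIXTURE_COUNTS = {
    ("het1", "A"): 3, ("het1", "G"): 6, ("het2", "A"): 4, ("het2", "G"): 5,
}


def si_fixture() -> dict[str, pd.DataFrame]:
    """Small deterministic tables in the schemas the SI-style ingesters expect.

    Returns {'energies', 'components', 'descriptors'} DataFrames (~40 rows
    total) generated in-code: 'energies' holds per-pose binding/interaction
    energies for the pair/count layout in :data:`SI_FIXTURE_COUNTS`;
    'components' rows satisfy Elec+Exch+Ind+Disp = Total exactly.  Real SI
    exports drop into the same schemas through DatasetTable column maps.
    """
    rng = np.random.default_rng(20250327)
    energy_rows = []
    for (h, b), count in SI_FIXTURE_COUNTS.items():
        e_bind = np.round(-rng.uniform(3.0, 12.0, count), 2)
        for k in range(count):
            e_int = e_bind[k] - round(float(rng.uniform(0.1, 0.4)), 2)
            energy_rows.append({
                "pair_id": f"{h}-{b}", "pose_id": f"min{k}", "het": h, "nuc": b,
                "e_bind": e_bind[k], "e_int": e_int,
            })
    energies = pd.DataFrame(energy_rows)
    comp = synth_component_table(SynthSpec(seed=7, n=20)).drop(columns=["pair_id"])
    comp.insert(0, "pair_id", "het1-A")
    descriptors = pd.DataFrame({
        "mol_id": [f"het{i}" for i in range(1, 6)],
        "n_ha": [5, 6, 9, 10, 11.0],
        "esp_max": np.round(rng.uniform(5.0, 30.0, 5), 2),
        "esp_min": np.round(-rng.uniform(5.0, 20.0, 5), 2),
    })
    descriptors["esp_range"] = descriptors["esp_max"] - descriptors["esp_min"]
    descriptors["esp_mean"] = np.round(
        (descriptors["esp_max"] + descriptors["esp_min"]) / 4, 2)
    return {"energies": energies, "components": comp, "descriptors": descriptors}
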