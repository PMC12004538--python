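import numpy as np
import pandas as pd
import pytest

from stackd.chemstruct import Molecule
from stackd.mmstack import (
    COULOMB_KCAL,
    LJParams,
    ParameterError,
    ScaledMMModel,
    assign_lj,
    evaluate_dataset,
    fit_scaling,
    interaction_energy,
    pair_sums,
)
from stackd.stackgeom import StackPose, StackedDimer, place_stacked
from stackd.synthdata import SynthSpec, synth_mm_dataset, toy_ring


def diatomic_dimer(r, symbols=("C", "C"), charges=(0.0, 0.0)):
    """Two single atoms stacked at distance r (built directly, not via poses)."""
    a = Molecule(name="a", symbols=[symbols[0]], coords=[[0.0, 0.0, 0.0]],
                 charges=[charges[0]], net_charge=charges[0])
    b = Molecule(name="b", symbols=[symbols[1]], coords=[[0.0, 0.0, r]],
                 charges=[charges[1]], net_charge=charges[1])
    pose = StackPose(0.0, 0.0, r, 0.0)
    return StackedDimer(nucleobase=a, heterocycle=b, pose=pose)


class TestAssignLJ:
    def test_uniform_carbon_ring(self, hexagon):
        params = assign_lj(hexagon, {"C": (1.9080, 0.0860)})
        assert np.all(params.rmin_half == 1.9080)
        assert np.all(params.epsilon == 0.0860)

    def test_unmapped_element_names_atom(self):
        mol = Molecule(name="se", symbols=["C", "Se"],
                       coords=[[0, 0, 0], [1.9, 0, 0]])
        with pytest.raises(ParameterError, match="Se"):
            assign_lj(mol, {"C": (1.9, 0.086)})

    def test_default_table_benzene_cardinality(self):
        from stackd.chemstruct import read_structure
        mol = Molecule(name="c6", symbols=["C"] * 6 + ["H"] * 6,
                       coords=np.random.default_rng(0).normal(size=(12, 3)))
        params = assign_lj(mol)
        assert len(params.rmin_half) == 12


class TestPairSums:
    def test_lj_minimum_identity(self):
        # at r = r_min the vdW pair energy is exactly -epsilon
        table = {"C": (1.9080, 0.0860)}
        r_min = 2 * 1.9080
        d = diatomic_dimer(r_min)
        p = assign_lj(d.nucleobase, table), assign_lj(d.heterocycle, table)
        s = pair_sums(d, *p)
        assert s.s_rep - s.s_att == pytest.approx(-0.0860, abs=1e-12)

    def test_zero_charges_zero_coulomb(self, asym_ring, hexagon):
        d = place_stacked(asym_ring, hexagon, StackPose(0, 0, 3.3, 20.0))
        d.nucleobase.charges[:] = 0.0
        d.heterocycle.charges[:] = 0.0
        s = pair_sums(d, assign_lj(d.nucleobase), assign_lj(d.heterocycle))
        assert s.e_coul == 0.0

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(12)
        qa, qb = rng.uniform(-0.3, 0.3, 4), rng.uniform(-0.3, 0.3, 4)
        a = Molecule(name="a", symbols=["C", "N", "H", "O"],
                     coords=rng.normal(scale=1.5, size=(4, 3)),
                     charges=qa, net_charge=float(qa.sum()))
        b = Molecule(name="b", symbols=["C", "H", "S", "C"],
                     coords=rng.normal(scale=1.5, size=(4, 3)) + [0, 0, 4.0],
                     charges=qb, net_charge=float(qb.sum()))
        d = StackedDimer(nucleobase=a, heterocycle=b,
                         pose=StackPose(0, 0, 4.0, 0))
        pa, pb = assign_lj(a), assign_lj(b)
        s = pair_sums(d, pa, pb)
        e_coul = s_rep = s_att = e_h = 0.0
        for i in range(4):
            for j in range(4):
                r = np.linalg.norm(a.coords[i] - b.coords[j])
                e_coul += COULOMB_KCAL * qa[i] * qb[j] / r
                rmin = pa.rmin_half[i] + pb.rmin_half[j]
                eps = np.sqrt(pa.epsilon[i] * pb.epsilon[j])
                rep = eps * rmin**12 / r**12
                att = 2 * eps * rmin**6 / r**6
                if a.symbols[i] != "H" and b.symbols[j] != "H":
                    s_rep += rep
                    s_att += att
                else:
                    e_h += rep - att
        assert s.e_coul == pytest.approx(e_coul, abs=1e-10)
        assert s.s_rep == pytest.approx(s_rep, abs=1e-10)
        assert s.s_att == pytest.approx(s_att, abs=1e-10)
        assert s.e_vdw_h == pytest.approx(e_h, abs=1e-10)

    def test_split_consistency_at_unit_scaling(self, asym_ring, hexagon):
        # scaled energy at (1,1) equals the unsplit Coulomb + LJ sum
        d = place_stacked(asym_ring, hexagon, StackPose(0.4, -0.6, 3.2, 35.0))
        pa = assign_lj(d.nucleobase)
        pb = assign_lj(d.heterocycle)
        s = pair_sums(d, pa, pb)
        e = interaction_energy(s, 1.0, 1.0)
        # independent unsplit sum
        dm = np.linalg.norm(d.nucleobase.coords[:, None] - d.heterocycle.coords[None],
                            axis=-1)
        rmin = pa.rmin_half[:, None] + pb.rmin_half[None, :]
        eps = np.sqrt(np.outer(pa.epsilon, pb.epsilon))
        lj = (eps * rmin**12 / dm**12 - 2 * eps * rmin**6 / dm**6).sum()
        coul = (COULOMB_KCAL * np.outer(d.nucleobase.charges,
                                        d.heterocycle.charges) / dm).sum()
        assert e == pytest.approx(coul + lj, abs=1e-10)

    def test_rigid_transform_invariance(self, asym_ring, hexagon, random_rigid):
        d = place_stacked(asym_ring, hexagon, StackPose(0.4, -0.6, 3.2, 35.0))
        pa, pb = assign_lj(d.nucleobase), assign_lj(d.heterocycle)
        e0 = interaction_energy(pair_sums(d, pa, pb))
        r, t = random_rigid(4)
        d.nucleobase = d.nucleobase.transformed(r, t)
        d.heterocycle = d.heterocycle.transformed(r, t)
        assert interaction_energy(pair_sums(d, pa, pb)) == pytest.approx(e0, abs=1e-9)

    def test_overlapping_atoms_rejected(self):
        d = diatomic_dimer(1e-9)
        p = assign_lj(d.nucleobase), assign_lj(d.heterocycle)
        with pytest.raises(ZeroDivisionError):
            pair_sums(d, *p)


class TestInteractionEnergy:
    def test_repulsive_only_is_positive(self):
        from stackd.mmstack import PairSums
        s = PairSums(e_coul=0.0, s_rep=3.0, s_att=5.0, e_vdw_h=0.0)
        assert interaction_energy(s, c_r=2.0, c_a=0.0) == 6.0

    def test_linearity_in_constants(self):
        from stackd.mmstack import PairSums
        s = PairSums(e_coul=-1.0, s_rep=3.0, s_att=5.0, e_vdw_h=0.5)
        base = interaction_energy(s, 0.9, 1.2) - s.e_coul - s.e_vdw_h
        scaled = interaction_energy(s, 1.8, 2.4) - s.e_coul - s.e_vdw_h
        assert scaled == pytest.approx(2 * base)


class TestFitScaling:
    def test_generative_recovery(self):
        df = synth_mm_dataset(SynthSpec(seed=21, n=80,
                                        params={"c_r": 0.9, "c_a": 1.2}))
        fit = fit_scaling(df)
        assert fit.c_r == pytest.approx(0.9, abs=1e-9)
        assert fit.c_a == pytest.approx(1.2, abs=1e-9)
        assert fit.rmse_after < 1e-9

    def test_unscaled_references_recover_unity(self):
        df = synth_mm_dataset(SynthSpec(seed=22, n=60))
        fit = fit_scaling(df)
        assert fit.c_r == pytest.approx(1.0, abs=1e-9)
        assert fit.c_a == pytest.approx(1.0, abs=1e-9)

    def test_fit_never_worse_than_unscaled(self):
        df = synth_mm_dataset(SynthSpec(seed=23, n=120, noise_sigma=0.5,
                                        params={"c_r": 1.1, "c_a": 1.3}))
        fit = fit_scaling(df)
        assert fit.rmse_after <= fit.rmse_before

    def test_residuals_orthogonal_to_design(self):
        df = synth_mm_dataset(SynthSpec(seed=24, n=100, noise_sigma=0.4))
        fit = fit_scaling(df)
        pred = (df["e_coul"] + df["e_vdw_h"] + fit.c_r * df["s_rep"]
                - fit.c_a * df["s_att"])
        resid = (df["e_ref"] - pred).to_numpy()
        for col in ("s_rep", "s_att"):
            x = df[col].to_numpy()
            assert abs(resid @ x) / (np.linalg.norm(resid) * np.linalg.norm(x)) < 1e-8

    def test_collinear_columns_rejected(self):
        df = pd.DataFrame({
            "e_coul": [0.0, 0.0, 0.0], "s_rep": [1.0, 2.0, 3.0],
            "s_att": [2.0, 4.0, 6.0], "e_vdw_h": [0.0, 0.0, 0.0],
            "e_ref": [-1.0, -2.0, -3.0],
        })
        with pytest.raises(np.linalg.LinAlgError):
            fit_scaling(df)


class TestEvaluateDataset:
    def test_perfect_model(self):
        df = synth_mm_dataset(SynthSpec(seed=25, n=40))
        rmse, r2 = evaluate_dataset(df, 1.0, 1.0)
        assert rmse == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_streaming_rmse(self):
        df = synth_mm_dataset(SynthSpec(seed=26, n=50, noise_sigma=0.7))
        rmse, _ = evaluate_dataset(df, 1.0, 1.0)
        # independent streaming computation
        total, n = 0.0, 0
        for _, row in df.iterrows():
            pred = row.e_coul + row.e_vdw_h + row.s_rep - row.s_att
            total += (pred - row.e_ref) ** 2
            n += 1
        assert rmse == pytest.approx(np.sqrt(total / n), abs=1e-12)

    def test_charge_source_mismatch_warns(self):
        df = synth_mm_dataset(SynthSpec(seed=27, n=30))
        fit = fit_scaling(df, charge_source="resp-hf")
        with pytest.warns(UserWarning, match="charge-model-specific"):
            evaluate_dataset(df, charge_source="am1-bcc", fit=fit)

    def test_noise_floor_recovered(self):
        df = synth_mm_dataset(SynthSpec(seed=28, n=1000, noise_sigma=0.3,
                                        params={"c_r": 0.95, "c_a": 1.15}))
        fit = fit_scaling(df)
        assert abs(fit.rmse_after - 0.3) / 0.3 < 0.10


class TestSklearnInterface:
    def test_estimator_contract(self):
        from sklearn.base import clone

        df = synth_mm_dataset(SynthSpec(seed=29, n=50,
                                        params={"c_r": 0.9, "c_a": 1.2}))
        model = ScaledMMModel()
        clone(model)
        model.fit(df, df["e_ref"])
        assert model.c_r_ == pytest.approx(0.9, abs=1e-9)
        pred = model.predict(df)
        assert np.abs(pred - df["e_ref"].to_numpy()).max() < 1e-8
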