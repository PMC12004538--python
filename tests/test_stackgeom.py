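import numpy as np
import pytest

from stackd.chemstruct import Molecule
from stackd.stackgeom import (
    GeometryError,
    StackPose,
    canonical_frame,
    fit_plane,
    locus_assign,
    perturb_nrsd,
    place_stacked,
    pose_metrics,
    sample_frsd,
)
from stackd.synthdata import toy_ring


def hexagon_coords(radius=1.39):
    ang = 2 * np.pi * np.arange(6) / 6
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


class TestFitPlane:
    def test_planar_hexagon(self, hexagon):
        fit = fit_plane(hexagon)
        assert fit.rms_deviation == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.normal, [0, 0, 1])

    def test_lifted_atom_matches_svd_oracle(self):
        coords = hexagon_coords()
        coords[2, 2] += 0.3
        mol = Molecule(name="bent", symbols=["C"] * 6, coords=coords)
        fit = fit_plane(mol)
        # independent oracle: smallest singular value of centered coords
        centered = coords - coords.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert fit.rms_deviation == pytest.approx(s[2] / np.sqrt(6), abs=1e-12)

    def test_two_atoms_rejected(self):
        mol = Molecule(name="di", symbols=["C", "C"], coords=[[0, 0, 0], [1, 0, 0]])
        with pytest.raises(GeometryError):
            fit_plane(mol)

    def test_collinear_rejected(self):
        mol = Molecule(name="line", symbols=["C"] * 4,
                       coords=[[i, 0.0, 0.0] for i in range(4)])
        with pytest.raises(GeometryError):
            fit_plane(mol)


class TestCanonicalFrame:
    def test_idempotent(self, asym_ring):
        c = canonical_frame(asym_ring)
        again = canonical_frame(c)
        assert np.abs(again.coords - c.coords).max() < 1e-9

    def test_rigid_transform_invariance(self, asym_ring, random_rigid):
        c0 = canonical_frame(asym_ring)
        for seed in range(5):
            r, t = random_rigid(seed)
            c = canonical_frame(asym_ring.transformed(r, t))
            assert np.abs(c.coords - c0.coords).max() < 1e-6

    def test_preserves_distances(self, asym_ring):
        c = canonical_frame(asym_ring)
        d0 = np.linalg.norm(asym_ring.coords[:, None] - asym_ring.coords[None], axis=-1)
        d1 = np.linalg.norm(c.coords[:, None] - c.coords[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_glycosidic_n_in_third_quadrant(self):
        mol = toy_ring(6, 1.39, "zero", name="base")
        mol.symbols[2] = "N"
        mol.glycosidic_n = 2
        c = canonical_frame(mol, nucleobase=True)
        x, y = c.coords[2][:2]
        assert x < 0 and y < 0

    def test_missing_glycosidic_annotation(self, hexagon):
        with pytest.raises(GeometryError, match="glycosidic"):
            canonical_frame(hexagon, nucleobase=True)


class TestPlaceStacked:
    def test_centered_pose(self, hexagon):
        d = place_stacked(hexagon, hexagon, StackPose(0, 0, 3.25, 0))
        sep, lateral, tilt, _ = pose_metrics(d)
        assert sep == pytest.approx(3.25, abs=1e-9)
        assert lateral == pytest.approx(0.0, abs=1e-9)
        assert tilt == pytest.approx(0.0, abs=1e-9)

    def test_theta_360_identity(self, asym_ring, hexagon):
        d0 = place_stacked(asym_ring, hexagon, StackPose(0.5, 0.2, 3.3, 0.0))
        d1 = place_stacked(asym_ring, hexagon, StackPose(0.5, 0.2, 3.3, 360.0))
        assert np.abs(d0.heterocycle.coords - d1.heterocycle.coords).max() < 1e-9

    def test_parallel_plane_invariant(self, asym_ring, hexagon):
        d = place_stacked(asym_ring, hexagon, StackPose(1.0, -2.0, 3.1, 123.0, face=-1))
        n1 = fit_plane(d.nucleobase).normal
        n2 = fit_plane(d.heterocycle).normal
        angle = np.arccos(np.clip(abs(n1 @ n2), -1, 1))
        assert angle <= 1e-6

    def test_dz_zero_rejected(self):
        with pytest.raises(ValueError):
            StackPose(0, 0, 0.0, 0)

    @pytest.mark.parametrize("face", [1, -1])
    def test_pose_round_trip(self, asym_ring, hexagon, face):
        pose = StackPose(0.8, -1.4, 3.31, 77.5, face=face)
        d = place_stacked(asym_ring, hexagon, pose)
        sep, _, tilt, theta = pose_metrics(d)
        assert sep == pytest.approx(pose.dz, abs=1e-6)
        assert tilt == pytest.approx(0.0, abs=1e-6)
        assert theta == pytest.approx(pose.theta, abs=1e-6)


class TestGenerators:
    def test_empty(self, asym_ring, hexagon):
        assert sample_frsd(asym_ring, hexagon, 0, seed=1) == []
        base = place_stacked(asym_ring, hexagon, StackPose(0, 0, 3.25, 0))
        assert perturb_nrsd(base, 0, seed=1) == []

    def test_negative_n(self, asym_ring, hexagon):
        with pytest.raises(ValueError):
            sample_frsd(asym_ring, hexagon, -1, seed=0)

    def test_frsd_bounds_full_protocol_size(self, asym_ring, hexagon):
        dimers = sample_frsd(asym_ring, hexagon, 2700, seed=42)
        assert len(dimers) == 2700
        for d in dimers:
            assert abs(d.pose.dx) <= 2.5 and abs(d.pose.dy) <= 2.5
            assert 3.0 <= d.pose.dz <= 3.5
            assert 0.0 <= d.pose.theta < 360.0

    def test_frsd_mean_separation(self, asym_ring, hexagon):
        dimers = sample_frsd(asym_ring, hexagon, 10000, seed=7)
        mean_dz = np.mean([d.pose.dz for d in dimers])
        # 3-sigma band of the mean of U(3.0, 3.5) at n=10000
        assert abs(mean_dz - 3.25) < 0.01

    def test_seeded_determinism(self, asym_ring, hexagon):
        a = sample_frsd(asym_ring, hexagon, 25, seed=11)
        b = sample_frsd(asym_ring, hexagon, 25, seed=11)
        for da, db in zip(a, b):
            assert da.pose == db.pose
            assert np.array_equal(da.heterocycle.coords, db.heterocycle.coords)

    def test_nrsd_deltas_within_bounds(self, asym_ring, hexagon):
        base = place_stacked(asym_ring, hexagon, StackPose(0.3, -0.2, 3.25, 40.0))
        for d in perturb_nrsd(base, 500, seed=5):
            assert abs(d.pose.dx - 0.3) <= 0.5
            assert abs(d.pose.dy + 0.2) <= 0.5
            assert abs(d.pose.dz - 3.25) <= 0.25
            dtheta = (d.pose.theta - 40.0 + 180.0) % 360.0 - 180.0
            assert abs(dtheta) <= 15.0

    def test_nrsd_zero_ranges_reproduce_pose(self, asym_ring, hexagon):
        base = place_stacked(asym_ring, hexagon, StackPose(0.3, -0.2, 3.25, 40.0))
        out = perturb_nrsd(base, 3, seed=9, lateral=0.0, vertical=0.0, rotation=0.0)
        for d in out:
            assert d.pose.dx == base.pose.dx
            assert d.pose.dy == base.pose.dy
            assert d.pose.dz == base.pose.dz
            assert d.pose.theta == pytest.approx(base.pose.theta, abs=1e-12)


class TestPoseMetrics:
    def test_tilt_by_construction(self, asym_ring, hexagon):
        d = place_stacked(asym_ring, hexagon, StackPose(0, 0, 3.3, 0))
        t = np.deg2rad(10.0)
        rot = np.array([[1, 0, 0],
                        [0, np.cos(t), -np.sin(t)],
                        [0, np.sin(t), np.cos(t)]])
        centroid = d.heterocycle.heavy_coords().mean(axis=0)
        d.heterocycle = d.heterocycle.transformed(
            rot, centroid - rot @ centroid)
        _, _, tilt, _ = pose_metrics(d)
        assert tilt == pytest.approx(10.0, abs=1e-6)

    def test_rigid_invariance(self, asym_ring, hexagon, random_rigid):
        d = place_stacked(asym_ring, hexagon, StackPose(0.7, -1.1, 3.3, 37.0))
        m0 = np.array(pose_metrics(d))
        r, t = random_rigid(8)
        d.nucleobase = d.nucleobase.transformed(r, t)
        d.heterocycle = d.heterocycle.transformed(r, t)
        assert np.abs(np.array(pose_metrics(d)) - m0).max() < 1e-6


class TestLocusAssign:
    def test_over_atom(self, asym_ring):
        nuc = toy_ring(6, 1.39, "zero")
        nuc_c = canonical_frame(nuc)
        ax, ay = nuc_c.coords[3][:2]
        d = place_stacked(asym_ring, nuc, StackPose(ax, ay, 3.25, 0))
        # move the ring centroid exactly over atom 3
        ring_xy = d.heterocycle.coords[d.heterocycle.ring_systems[0]][:, :2].mean(axis=0)
        d.heterocycle.coords[:, 0] += ax - ring_xy[0]
        d.heterocycle.coords[:, 1] += ay - ring_xy[1]
        loci = locus_assign(d)
        assert loci[0].feature == 3
        assert loci[0].distance < 1e-9

    def test_over_bond_midpoint(self, asym_ring):
        nuc = canonical_frame(toy_ring(6, 1.39, "zero"))
        mid = (nuc.coords[0][:2] + nuc.coords[1][:2]) / 2
        d = place_stacked(asym_ring, nuc, StackPose(0, 0, 3.25, 0))
        ring_xy = d.heterocycle.coords[d.heterocycle.ring_systems[0]][:, :2].mean(axis=0)
        d.heterocycle.coords[:, 0] += mid[0] - ring_xy[0]
        d.heterocycle.coords[:, 1] += mid[1] - ring_xy[1]
        loci = locus_assign(d)
        assert loci[0].feature in [(0, 1), (1, 0)]
        assert loci[0].distance < 1e-9

    def test_matches_brute_force(self, asym_ring, hexagon):
        from stackd.chemstruct import infer_bonds

        dimers = sample_frsd(asym_ring, hexagon, 200, seed=13)
        for d in dimers:
            loci = locus_assign(d)
            nuc = d.nucleobase
            feats = [(int(i), tuple(nuc.coords[i][:2])) for i in nuc.heavy_indices]
            for i, j in infer_bonds(nuc.symbols, nuc.coords):
                if nuc.symbols[i] != "H" and nuc.symbols[j] != "H":
                    feats.append(((i, j), tuple((nuc.coords[i][:2] + nuc.coords[j][:2]) / 2)))
            for ring, locus in zip(d.heterocycle.ring_systems, loci):
                cxy = d.heterocycle.coords[ring][:, :2].mean(axis=0)
                best = min(feats, key=lambda f: np.hypot(f[1][0] - cxy[0], f[1][1] - cxy[1]))
                d_best = np.hypot(best[1][0] - cxy[0], best[1][1] - cxy[1])
                assert locus.distance == pytest.approx(d_best, abs=1e-9)
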