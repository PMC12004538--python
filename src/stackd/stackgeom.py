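"""Canonical molecular frames and stacked-dimer construction.

A stacked dimer is defined in the nucleobase frame: the nucleobase heavy-atom
plane is z = 0 with the glycosidic nitrogen in the third quadrant, and the
heterocycle is placed plane-parallel at height ``dz`` with lateral offset
(dx, dy) and an in-plane rotation theta.  Two pose generators reproduce the
random-dimer protocols used to build benchmark sets: fully random parallel
dimers (lateral displacements up to ±2.5 Å, vertical separation
3.25 ± 0.25 Å, random orientation) and near-minimum perturbations
(±0.5 Å lateral, ±0.25 Å vertical, ±15° rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chemstruct import Molecule, infer_bonds

__all__ = [
    "GeometryError",
    "PlaneFit",
    "StackPose",
    "StackedDimer",
    "LocusAssignment",
    "fit_plane",
    "canonical_frame",
    "place_stacked",
    "sample_frsd",
    "perturb_nrsd",
    "pose_metrics",
    "locus_assign",
    "FRSD_LATERAL_MAX",
    "FRSD_DZ_RANGE",
    "NRSD_LATERAL_MAX",
    "NRSD_DZ_MAX",
    "NRSD_THETA_MAX",
]

# random-pose protocol bounds (Å, degrees)
FRSD_LATERAL_MAX = 2.5
FRSD_DZ_RANGE = (3.0, 3.5)
NRSD_LATERAL_MAX = 0.5
NRSD_DZ_MAX = 0.25
NRSD_THETA_MAX = 15.0

CLASH_CUTOFF = 2.0  # heavy-heavy Å; poses below are flagged, not rejected


class GeometryError(ValueError):
    """Degenerate geometry (too few atoms, collinear, missing annotation)."""


@dataclass(frozen=True)
class PlaneFit:
    """Least-squares plane through the heavy atoms."""

    normal: np.ndarray
    point: np.ndarray  # heavy-atom centroid
    rms_deviation: float


@dataclass(frozen=True)
class StackPose:
    """Rigid placement of a heterocycle over a canonical-frame nucleobase."""

    dx: float
    dy: float
    dz: float
    theta: float  # degrees about +z
    face: int = 1

    def __post_init__(self) -> None:
        if self.dz <= 0:
            raise ValueError("pose.dz must be positive")
        if self.face not in (1, -1):
            raise ValueError("face must be +1 or -1")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)


@dataclass
class StackedDimer:
    nucleobase: Molecule
    heterocycle: Molecule
    pose: StackPose
    pose_id: str = ""
    clash_flag: bool = False


@dataclass(frozen=True)
class LocusAssignment:
    """Nearest nucleobase feature (atom or bond midpoint) to a ring centroid."""

    centroid_xy: tuple[float, float]
    feature: int | tuple[int, int]  # atom index or bond (i, j)
    distance: float


# ---------------------------------------------------------------------------
# plane fitting and canonical frames


def fit_plane(mol: Molecule) -> PlaneFit:
    """Least-squares plane through the heavy atoms via SVD.

    Minimises the sum of squared perpendicular distances; the normal is
    oriented toward +z when possible (sign fixed upstream by
    :func:`canonical_frame` for full determinism).
    """
    pts = mol.heavy_coords()
    if pts.shape[0] < 3:
        raise GeometryError("plane fit needs >= 3 heavy atoms")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise GeometryError("heavy atoms are collinear")
    normal = vt[2] / np.linalg.norm(vt[2])
    if normal[2] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(normal=normal, point=centroid, rms_deviation=rms)


def _fix_sign(vec: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Deterministic sign for a frame axis: third-moment of the projections,
    falling back to an index-weighted first moment for symmetric layouts."""
    proj = pts @ vec
    m3 = float(np.sum(proj**3))
    if abs(m3) > 1e-8:
        return vec if m3 > 0 else -vec
    m1w = float(np.sum((np.arange(len(proj)) + 1.0) * proj))
    if abs(m1w) > 1e-8:
        return vec if m1w > 0 else -vec
    return vec


def canonical_frame(mol: Molecule, nucleobase: bool = False) -> Molecule:
    """Rigidly move a (near-)planar molecule into its canonical frame.

    Heavy-atom centroid at the origin and plane normal along +z.  The
    in-plane orientation comes from the heavy-atom principal axes with
    moment-based sign fixes, so the result is invariant under any proper
    rigid transform of the input and idempotent.  For nucleobases
    (``nucleobase=True`` or a ``glycosidic_n`` annotation) the frame is
    instead rotated about z so the glycosidic nitrogen sits on the 225°
    diagonal of the third quadrant (x < 0, y < 0), matching the standard
    base orientation used for stacking maps.
    """
    if nucleobase and mol.glycosidic_n is None:
        raise GeometryError("nucleobase orientation requested but glycosidic_n unset")
    plane = fit_plane(mol)
    pts = mol.heavy_coords() - plane.point
    # in-plane principal axes of the heavy atoms
    inplane = pts - np.outer(pts @ plane.normal, plane.normal)
    cov = inplane.T @ inplane
    w, v = np.linalg.eigh(cov)
    w = np.sort(w)
    # in-plane eigenvalues are w[1] <= w[2] (w[0] is the out-of-plane one);
    # a (near-)degenerate pair (symmetric molecules) makes the eigenvectors
    # arbitrary, so fall back to an index-weighted direction, which is
    # deterministic and covariant under rigid motion
    degenerate = (w[2] - w[1]) <= 1e-6 * max(w[2], 1e-12)
    if degenerate:
        e1 = ((np.arange(len(inplane)) + 1.0) @ inplane)
    else:
        e1 = v[:, np.argmax(np.linalg.eigh(cov)[0])]
    e1 = e1 - (e1 @ plane.normal) * plane.normal
    n1 = np.linalg.norm(e1)
    if n1 < 1e-10:  # pathological: fall back to first off-centroid atom
        e1 = inplane[np.argmax(np.linalg.norm(inplane, axis=1))]
        n1 = np.linalg.norm(e1)
    e1 = _fix_sign(e1 / n1, inplane)
    e2 = np.cross(plane.normal, e1)
    e2 = _fix_sign(e2, inplane)
    e3 = np.cross(e1, e2)  # right-handed; may flip the nominal normal
    rot = np.vstack([e1, e2, e3])
    out = mol.transformed(rot, -rot @ plane.point)
    use_glyco = mol.glycosidic_n is not None
    if use_glyco:
        gx, gy = out.coords[mol.glycosidic_n][:2]
        ang = np.arctan2(gy, gx)
        target = np.deg2rad(225.0)
        c, s = np.cos(target - ang), np.sin(target - ang)
        rz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        out = out.transformed(rz, np.zeros(3))
    return out


# ---------------------------------------------------------------------------
# dimer construction


def _rot_z(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180° about x: presents the other face


def _min_heavy_distance(a: Molecule, b: Molecule) -> float:
    pa, pb = a.heavy_coords(), b.heavy_coords()
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def place_stacked(het: Molecule, nuc: Molecule, pose: StackPose,
                  pose_id: str = "", assume_canonical: bool = False) -> StackedDimer:
    """Construct a parallel stacked dimer from a pose.

    Both monomers are first canonicalised, guaranteeing exactly parallel
    heavy-atom planes; the heterocycle is then (optionally) face-flipped,
    rotated by theta about +z and translated to (dx, dy, dz).
    ``assume_canonical`` skips the (idempotent) canonicalisation when the
    caller has already done it — a pose-generator fast path.
    """
    if assume_canonical:
        nuc_c, het_c = nuc, het
    else:
        nuc_c = canonical_frame(nuc)
        het_c = canonical_frame(het)
    rot = _rot_z(pose.theta)
    if pose.face == -1:
        rot = rot @ _FLIP_X
    het_p = het_c.transformed(rot, np.array([pose.dx, pose.dy, pose.dz]))
    dimer = StackedDimer(nucleobase=nuc_c, heterocycle=het_p, pose=pose,
                         pose_id=pose_id)
    dimer.clash_flag = _min_heavy_distance(nuc_c, het_p) < CLASH_CUTOFF
    return dimer


def sample_frsd(het: Molecule, nuc: Molecule, n: int, seed: int) -> list[StackedDimer]:
    """Fully random stacked dimers.

    dx, dy ~ U(−2.5, 2.5) Å; dz ~ U(3.0, 3.5) Å; theta ~ U(0, 360)°; the
    stacking face is drawn uniformly.  Sterically clashing poses (any
    intermolecular heavy-atom pair under 2.0 Å) are flagged, not rejected,
    so requested dataset sizes are exact.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    het_c, nuc_c = canonical_frame(het), canonical_frame(nuc)
    out = []
    for k in range(n):
        pose = StackPose(
            dx=rng.uniform(-FRSD_LATERAL_MAX, FRSD_LATERAL_MAX),
            dy=rng.uniform(-FRSD_LATERAL_MAX, FRSD_LATERAL_MAX),
            dz=rng.uniform(*FRSD_DZ_RANGE),
            theta=rng.uniform(0.0, 360.0),
            face=int(rng.choice([1, -1])),
        )
        out.append(place_stacked(het_c, nuc_c, pose, pose_id=f"frsd-{k}",
                                 assume_canonical=True))
    return out


def perturb_nrsd(dimer: StackedDimer, n: int, seed: int,
                 lateral: float = NRSD_LATERAL_MAX,
                 vertical: float = NRSD_DZ_MAX,
                 rotation: float = NRSD_THETA_MAX) -> list[StackedDimer]:
    """Nearby random stacked dimers around an (optimised) pose.

    Independent axis-wise displacements up to ±0.5 Å laterally and
    ±0.25 Å vertically, plus a rotation up to ±15° about the vertical
    axis, all relative to the input pose.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    base = dimer.pose
    het_c = canonical_frame(dimer.heterocycle)
    nuc_c = canonical_frame(dimer.nucleobase)
    out = []
    for k in range(n):
        pose = StackPose(
            dx=base.dx + rng.uniform(-lateral, lateral),
            dy=base.dy + rng.uniform(-lateral, lateral),
            dz=base.dz + rng.uniform(-vertical, vertical),
            theta=base.theta + rng.uniform(-rotation, rotation),
            face=base.face,
        )
        out.append(place_stacked(het_c, nuc_c, pose,
                                 pose_id=f"{dimer.pose_id or 'nrsd'}-{k}",
                                 assume_canonical=True))
    return out


# ---------------------------------------------------------------------------
# pose measurement


def pose_metrics(dimer: StackedDimer) -> tuple[float, float, float, float]:
    """(separation Å, lateral offset Å, tilt °, theta °) of a dimer.

    Separation is the heterocycle heavy-atom centroid height above the
    nucleobase plane; tilt is the angle between the two plane normals in
    [0, 90]°; theta is recovered as the optimal in-plane rotation carrying
    the heterocycle's canonical frame onto its placed coordinates (defined
    up to the heterocycle's own rotational symmetry).
    """
    pn = fit_plane(dimer.nucleobase)
    ph = fit_plane(dimer.heterocycle)
    sep = float(abs((ph.point - pn.point) @ pn.normal))
    delta = ph.point - pn.point
    lateral = float(np.linalg.norm(delta - (delta @ pn.normal) * pn.normal))
    cos_t = abs(float(np.clip(pn.normal @ ph.normal, -1.0, 1.0)))
    tilt = float(np.degrees(np.arccos(cos_t)))
    # theta: in-plane Procrustes of canonical het vs placed het
    nuc_axes = _frame_axes(dimer.nucleobase)
    het_canon = canonical_frame(dimer.heterocycle)
    placed = (dimer.heterocycle.heavy_coords() - ph.point) @ nuc_axes.T
    ref = het_canon.heavy_coords() - het_canon.heavy_coords().mean(axis=0)
    if dimer.pose.face == -1:
        ref = ref @ _FLIP_X  # construction flips first, then rotates
    num = float(np.sum(ref[:, 0] * placed[:, 1] - ref[:, 1] * placed[:, 0]))
    den = float(np.sum(ref[:, 0] * placed[:, 0] + ref[:, 1] * placed[:, 1]))
    theta = float(np.degrees(np.arctan2(num, den))) % 360.0
    return sep, lateral, tilt, theta


def _frame_axes(mol: Molecule) -> np.ndarray:
    """Rows are the molecule's canonical axes expressed in world coordinates."""
    canon = canonical_frame(mol)
    pts = mol.heavy_coords() - mol.heavy_coords().mean(axis=0)
    ref = canon.heavy_coords() - canon.heavy_coords().mean(axis=0)
    # rigid Kabsch: find R with ref = pts @ R.T  =>  R rows are axes
    h = pts.T @ ref
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    return r


# ---------------------------------------------------------------------------
# stacking loci


def locus_assign(dimer: StackedDimer) -> list[LocusAssignment]:
    """Assign each heterocycle ring centroid to its nearest nucleobase feature.

    Stacked energy minima cluster over a discrete set of loci that sit over
    nucleobase atoms and bonds; this projects each ring centroid into the
    nucleobase plane and reports the nearest heavy atom or heavy-atom bond
    midpoint (ties within 1e-9 Å resolve to the atom).
    """
    nuc = dimer.nucleobase
    heavy = nuc.heavy_indices
    atom_xy = nuc.coords[heavy][:, :2]
    bonds = [
        (i, j) for i, j in infer_bonds(nuc.symbols, nuc.coords)
        if nuc.symbols[i] != "H" and nuc.symbols[j] != "H"
    ]
    bond_xy = np.array(
        [(nuc.coords[i][:2] + nuc.coords[j][:2]) / 2 for i, j in bonds]
    ) if bonds else np.empty((0, 2))
    rings = dimer.heterocycle.ring_systems or [list(range(len(dimer.heterocycle)))]
    out = []
    for ring in rings:
        cxy = dimer.heterocycle.coords[ring][:, :2].mean(axis=0)
        d_atom = np.linalg.norm(atom_xy - cxy, axis=1)
        ia = int(np.argmin(d_atom))
        best_feat: int | tuple[int, int] = int(heavy[ia])
        best_d = float(d_atom[ia])
        if len(bond_xy):
            d_bond = np.linalg.norm(bond_xy - cxy, axis=1)
            ib = int(np.argmin(d_bond))
            if d_bond[ib] < best_d - 1e-9:  # ties go to the atom
                best_feat = bonds[ib]
                best_d = float(d_bond[ib])
        out.append(LocusAssignment(centroid_xy=(float(cxy[0]), float(cxy[1])),
                                   feature=best_feat, distance=best_d))
    return out
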