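# Methods

This note records the models implemented in `stackd`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generators do and do not emulate.

## Geometry: frames, dimers, pose generators

**Canonical frame.** A (near-)planar molecule is moved so its heavy-atom
centroid sits at the origin and the least-squares plane normal (smallest
singular vector of the centered heavy-atom coordinates) lies along +z. The
in-plane orientation comes from the heavy-atom principal axes; axis signs
are fixed by the third moment of the projections, falling back to an
index-weighted first moment when the third moment vanishes (symmetric
layouts), and the frame is completed right-handed. When the two in-plane
eigenvalues are degenerate (regular polygons, benzene) the principal axes
are arbitrary, so the x-axis is taken from an index-weighted coordinate sum
instead. All of these choices are covariant under proper rigid motion, which
gives the two properties the rest of the package relies on: canonicalisation
is idempotent, and any rigidly transformed copy of a molecule lands on the
same canonical coordinates. For nucleobases the in-plane rotation is instead
fixed by placing the glycosidic nitrogen on the 225° diagonal (x < 0,
y < 0), the standard orientation for nucleobase stacking maps.

**Stacked dimers.** A pose is (dx, dy, dz, θ, face): the heterocycle is
canonicalised, optionally flipped 180° about x (face = −1), rotated by θ
about +z and translated to (dx, dy, dz) over the canonical nucleobase. By
construction the heavy-atom planes are exactly parallel and the centroid
height equals dz. `pose_metrics` inverts the construction (separation,
lateral offset, tilt, and θ via a 2D Procrustes fit), exact up to the
heterocycle's own rotational symmetry; on constructed dimers the round trip
is accurate to ~1e-13.

**Random poses.** Fully random stacked dimers draw dx, dy ~ U(−2.5, 2.5) Å,
dz ~ U(3.0, 3.5) Å, θ ~ U(0, 360)°, and the stacking face uniformly; the
"3.25 ± 0.25 Å" vertical band is read as a uniform distribution to match
the "up to ±" phrasing of the lateral bounds. Near-minimum perturbations
apply independent axis-wise displacements up to ±0.5 Å laterally and
±0.25 Å vertically plus a rotation up to ±15°; "lateral axes" is read
axis-wise rather than radially (a radial reading would shrink the sampled
box). Poses with any intermolecular heavy-atom distance under 2.0 Å are
flagged rather than rejected, so a requested dataset size is delivered
exactly. Each generator call owns one `numpy` Generator seeded by the
caller; identical inputs give bit-identical pose lists.

**Stacking loci.** Each heterocycle ring centroid is projected into the
nucleobase plane and assigned to the nearest feature among heavy atoms and
heavy-atom bond midpoints (bonds inferred from covalent radii with a 1.2×
cutoff); ties within 1e-9 Å resolve to the atom.

## ESP plane descriptors

The ESP is evaluated on a rectangular grid in the plane z = h (default
h = 3.25 Å, the distance at which these descriptors are defined), masked to
the union of per-atom circles of van der Waals radius (Bondi set bundled:
H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å; overridable). Descriptors are
statistics over the masked nodes only: ESP_max, ESP_min, ESP_mean and
ESP_range = ESP_max − ESP_min, plus the heavy-atom count N_HA.

Two backends produce the field. The native backend is a point-charge
Coulomb sum, ESP(r) = 332.0637 · Σ q_i/|r − r_i| (q in e, r in Å, ESP in
kcal/mol); it is exact for the charge model given and linear in the
charges. QM-quality fields are imported as Gaussian cube files and sampled
by trilinear interpolation (orthogonal cubes only; Hartree → kcal/mol
conversion happens once at ingestion). The default grid spacing of 0.1 Å
is a numerical choice: halving it changes ESP_max and ESP_range of the
bundled fixtures by under 0.1 kcal/mol. Descriptors can be computed for
both faces; the reported face is the one with larger ESP_max, which is
moot for the mirror-symmetric planar aromatics that dominate in practice.

Descriptor constants for the five nucleobases (ESP_range 13.1 (A), 24.3
(G), 22.8 (C), 16.1 (T), 17.7 (U) kcal/mol; N_HA 10/11/8/9/8) are bundled
as package data so the predictive model never needs a QM engine.

## Maximum-stacking model

The strongest possible stacking interaction of a heterocycle–nucleobase
pair is modelled bilinearly in size and electrostatics:

    E_max = c1 · (N_HA^het · N_HA^nuc) + c2 · (ESP_max^het · ESP_range^nuc).

The functional form is exposed as a named feature map (descriptor table →
design matrix), so variants (an intercept, size-normalised terms) can be
registered without touching the fitting code; the bilinear map is the
shipped default. Fitting is linear least squares — the global RMSE optimum
for any form linear in its coefficients. r² is the squared Pearson
correlation between predicted and observed energies (this field's
reporting convention), and a zero-variance degenerate case reports r² = 0
with a warning rather than erroring. Binding energies are negative
throughout; "maximum stacking" means most negative. A dipole-moment
baseline is deliberately not implemented: ESP-derived descriptors are the
point of the model, and dipole models are known to predict stacking poorly.

Library screening evaluates the fitted model for every (heterocycle,
nucleobase) combination; a 1854-entry library screens against all five
nucleobases in well under a second.

## Scaled MM interaction energies

The MM energy of a rigid dimer is strictly intermolecular Coulomb + 12-6
Lennard-Jones: no cutoffs, no 1–4 terms, no intramolecular contributions,
no solvent. Conventions are AMBER-style: A = ε·r_min¹², B = 2ε·r_min⁶,
Lorentz–Berthelot combination (arithmetic r_min/2, geometric ε). Tables
supplied in σ/ε form must be converted explicitly (r_min = 2^(1/6) σ).

Fixed-charge force fields underbind stacked aromatics; the correction
implemented here scales the repulsive and attractive vdW sums over
heavy-atom pairs by two atom-type-independent constants:

    E(C_R, C_A) = E_coul + E_vdw,H + C_R·S_rep − C_A·S_att,

with pairs involving hydrogen always at C_R = C_A = 1. Because E is linear
in (C_R, C_A), the RMSE-optimal constants solve a 2×2 normal-equation
system exactly; the fit can never be worse than the unscaled potential,
and residuals are orthogonal to the design columns. Scaling constants
compensate in part for charge-model error, so a `ScalingFit` records its
charge source and warns when applied across charge models. Numeric
constants per force field/charge model are not bundled: they must be refit
from reference interaction-energy tables.

## Dataset statistics

All correlations are squared Pearson on raw unweighted rows. The component
analysis reports, for each SAPT component X, r²(X, E_int) and the
leave-one-out r²(E_int − X, E_int): a component is determinative when its
removal collapses the correlation. Per-pair summaries use "most negative =
strongest" for the maximum binding energy. The tautomer shift is
ΔE(het···nuc) = ΔE(het) + [BE(t2···nuc) − BE(t1···nuc)]; it is
antisymmetric under swapping the tautomer labels, and a sign change
relative to ΔE(het) flags a swapped preferred tautomer. Stacking
efficiency is 100·E_pose/E_max rounded half away from zero to an integer
percent, matching the granularity at which pose quality is usually quoted.

## Synthetic data and what passing tests show

The generators are pure functions of a `SynthSpec` (seed, n, noise level,
generative parameters). They emulate the *structure* of real stacking
datasets — planar charged aromatics, bilinear descriptor/energy tables,
Coulomb+LJ reference energies with planted (C_R, C_A), component tables
with a latent-factor correlation structure whose total is the exact
component sum — with Gaussian homoscedastic noise, the weakest assumption
that supports RMSE-recovery tests. Feature ranges bracket druglike
heterocycles (5–16 heavy atoms, ESP_max in [−10, 40] kcal/mol).

They do not emulate QM energy surfaces, charge penetration, anisotropic
electrostatics, or the real distribution of stacked minima. Passing the
recovery tests therefore demonstrates that the estimators are correct and
numerically stable (exact recovery at zero noise, noise-floor RMSE at
finite noise), not that the models reach any particular accuracy on real
dimer data; the benchmark-reproduction tests against the published dimer
tables cover that, and run only when those tables are present under
`data/si/`.

## Problem sizes and numerical tolerances

Default test and acceptance runs use 200–2700 poses, 1000–2000-row
regression tables and 5000-row component tables — sizes at which the
sampling checks (mean separation within the 3-σ band, RMSE within 10% of
the noise floor) are sharp while the whole suite stays fast. Geometric
identities are asserted at 1e-6 to 1e-9 Å, energy identities at 1e-10 to
1e-12 kcal/mol, and statistical recoveries at the tolerance implied by
their sampling variance. Degenerate inputs (collinear heavy atoms, empty
masks, zero-variance correlates, collinear design columns, overlapping
atoms) raise typed errors or warn-and-continue as documented per function.

## Known limitations

Gas-phase, rigid, single-nucleobase dimers only: no solvation or
desolvation costs, no hydrogen-bonded base pairs, no entropic effects, no
geometry optimisation (optimised-dimer datasets are ingested, not
produced). The point-charge ESP backend inherits the charge model's
limitations; quantitative descriptor work should use imported QM grids.
Ring perception for connectivity-free formats is geometric and can
misassign rings in pathological geometries.
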