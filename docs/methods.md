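# Methods

## Signal model and tensor estimation

A single diffusion tensor per voxel models the diffusion-weighted signal as

    S_i = S0 · exp(−b_i · g_iᵀ D g_i)

with `g_i` the unit gradient direction, `b_i` the diffusion weighting
(s/mm²) and `D` a symmetric 3×3 tensor (mm²/s). Taking logs gives the
per-direction apparent diffusion coefficient `ADC_i = −(1/b_i)·ln(S_i/S0) =
g_iᵀ D g_i`, linear in the six unique components of `D`. With one `b=0`
measurement and at least six non-collinear weighted directions the system
is identifiable; we solve it by ordinary least squares on log-signals
(pseudo-inverse of the fixed design matrix, vectorized over voxels).
Weighted least squares would change nothing at the noise levels the
phantoms use and is not implemented.

Numerical guards: `S0` is the mean of the `b=0` volumes; voxels with
`S0 ≤ 0` or outside the mask get zero tensors; signals below `1e-6·S0` are
floored before the log; b-values below 50 s/mm² count as `b=0` (scanners
emit small nonzero values). Eigenvalues are sorted descending and negative
values (possible under noise) are clamped to zero *before* any derived
measure; the clamp count is recorded on the eigensystem object.

Derived maps: fractional anisotropy

    FA = sqrt(3/2) · sqrt(Σ(λi − λ̄)²) / sqrt(Σλi²),   FA = 0 where Σλi² = 0,

and the Westin shape measures `Cl = (λ1−λ2)/λ1`, `Cp = (λ2−λ3)/λ1`,
`Cs = λ3/λ1`, which satisfy `Cl + Cp + Cs = 1` whenever `λ1 > 0` and are
all set to 0 (voxel unusable) where `λ1 = 0`.

## Direction rules

All tracking runs in world millimeters through the NIfTI affine; a point
belongs to voxel `floor(inv(affine)·p)` (half-open cells, 0-based indices).

* **FACT**: `v_out = ±e1`, sign chosen so `v_out·v_in ≥ 0`; an exactly
  perpendicular tie breaks toward `+e1`. Eigenvectors are axial, so ±e1 are
  equivalent everywhere and consumers must not rely on the solver's sign.
* **TEND**: `v_out = normalize(D̂ v_in)` with `D̂ = D/λ1`. `D̂` is
  positive-semidefinite, so the result never opposes `v_in` and no extra
  sign rule is needed. A vanishing deflection signals termination.
* **FTACTD**: `v_out = normalize(Cl·e1 + Cp·D̂ v_in)` with `e1`
  sign-aligned to `v_in` first. The two raw terms have incommensurate
  units (`e1` unitless, `D·v_in` in mm²/s); dividing `D` by its λ1 at the
  query point makes both terms order one so the Westin weights act as
  intended. The weights are *not* renormalized (`Cl + Cp ≤ 1`); only the
  final vector is unit-normalized, which makes any common positive scaling
  of the weights irrelevant. A vanishing blend (isotropic tensor:
  `Cl = Cp = 0`) passes `v_in` through unchanged; such regions are below
  any sensible FA threshold and terminate on that test instead.

Both limits are exact, not approximate: `Cp = 0` (prolate, `λ2 = λ3`)
reduces FTACTD to FACT, and `Cl = 0` (oblate) reduces it to TEND. The test
suite checks both equivalences at the whole-tractogram level to 1e-9 mm.

## Propagation, termination, merging

Fixed-step Euler integration: `p ← p + step·v`. Fields are sampled at
arbitrary points by trilinear interpolation of the six tensor components
(corners clamped at grid edges), with the eigensystem, FA, Cl and Cp
recomputed *from the interpolated tensor* — interpolating derived scalars
instead would break the partition identity and the limit-case
equivalences. A `nearest` mode reads the voxel tensor directly for
FACT-style fidelity. Interpolation of coaxial prolate tensors (straight
bundle plus isotropic background) stays exactly prolate, which is why the
prolate-limit equivalence holds on interpolated fields too.

Seeds are the centers of voxels with `FA > fa_threshold` inside the mask
(additional per-voxel seeds, if requested, are drawn uniformly in the
voxel cell from the run's RNG seed; the default of one center seed is fully
deterministic). From each seed two half-tracks start along `+e1` and `−e1`;
the merged streamline is `reverse(backward) + seed + forward`. A half-track
stops when the candidate point leaves the mask or grid, when interpolated
FA at the candidate falls to or below the threshold (the candidate is *not*
appended, so every retained vertex satisfies the FA constraint), when the
turn between consecutive directions exceeds `angle_threshold` (the first
step of each half-track has no previous direction and is exempt), or when
the half-track reaches `max_length/2` (capping each half independently
keeps tracking equivariant under grid reflections). Merged streamlines
shorter than `min_length` are rejected — a normal outcome, not an error.

Default parameters: FA threshold 0.2 (used for both seeding and
termination), angle threshold 45°, step 1 mm, length window [10, 600] mm,
trilinear interpolation, one seed per voxel. These are standard operating
points for deterministic DTI tractography; step sizes of 0.5–2 mm and FA
0.1–0.3 behave monotonically as expected (tighter FA → fewer seeds; wider
angle → no shorter mean length; both properties are tested).

## Phantoms

Phantoms are 30³ grids of 2 mm isotropic voxels (desk scale). The
acquisition is one `b=0` plus 32 directions at `b = 1000 s/mm²`; the
direction table was generated once by electrostatic repulsion with
antipodal symmetry on the sphere and is shipped as a constant
(design-matrix condition number 1.58). Bundle tensors are
`R·diag(1.7, 0.3, 0.3)e-3·Rᵀ` mm²/s oriented along the local tangent
(FA ≈ 0.80, white-matter-like); the background is isotropic 0.7e-3 mm²/s
(gray-matter-like). Geometries:

* **straight** — a 40 mm cylinder (radius 4 mm) along x;
* **curved** — a quarter-circle arc (radius ≈ 21 mm) in the xy midplane,
  tensors tangent to the arc;
* **crossing** — two 50 mm cylinders through the grid center at a chosen
  angle (default 60°).

Voxels in the crossing overlap hold the *oblate single-tensor equivalent*
of the two populations: eigenvalues `((λ1+λ2)/2, (λ1+λ2)/2, λ3)` with the
degenerate pair spanning the crossing plane. Rationale: a single tensor
cannot represent two orientations; its fit in a crossing voxel is
disk-shaped with no meaningful in-plane eigenvector, and this construction
reproduces that regime exactly at every crossing angle (at 90° it equals
the arithmetic mean of the two bundle tensors). The naive arithmetic mean
is *prolate along the bisector* at oblique angles (Cl = 0.52 at 60°),
which would make every tensor-based tracker — adaptive or not — follow the
bisector and exit into the mirror bundle; it tests the geometry of the
phantom rather than the behavior of the direction rules.

Each bundle's ground truth comprises its voxel mask, its centerline
(world mm), and two endpoint ROIs: the two end voxel layers of the tube
plus one layer beyond the tip, so streamlines that stop at the FA falloff
just outside the bundle still register. ROI membership of an endpoint is
voxel containment, no dilation.

Noise is Rician: `S' = sqrt((S+n1)² + n2²)`, `n1, n2 ~ N(0, σ²)`, seeded.
At high SNR `E[S'] ≈ S + σ²/(2S)`; the simulator is checked against this
expansion by Monte Carlo. The crossing comparison uses `σ = 20` at
`S0 = 1000` (SNR 50, a routine clinical b=0 noise level) so that repeated
runs with different noise seeds give a genuine distributional comparison.

What the phantoms do **not** emulate: partial-volume fractions other than
the binary tube masks, axon dispersion, T2/relaxation contrast, eddy/motion
artifacts, susceptibility distortion, multi-shell acquisitions, and
realistic brain geometry. Passing results therefore demonstrate the
*mechanism* (correct continuation through disk-shaped crossing regions,
exact limit behavior, constraint compliance) — not clinical performance on
in-vivo data.

## Evaluation

Streamlines are classified by their two endpoints: **VC** when they occupy
the two distinct ROIs of one ground-truth bundle, **IC** when both
endpoints are in ROIs that no bundle pairs (both endpoints inside one and
the same ROI counts as NC — nothing is connected), **NC** otherwise.
**VB** counts bundles with ≥1 VC streamline; **IB** counts distinct
non-ground-truth ROI pairs with ≥1 IC streamline. Percentages are over all
retained streamlines and partition to 100 by construction. Length
statistics (count, min/max/mean, mm) use the polyline lengths. Fuller
Tractometer-style scoring (bundle-overlap, overreach) is out of scope.

## Problem sizes

The test suite and the acceptance script run entirely on the phantoms
above: 144 random tensors for the fit round-trip, 30³ grids for tracking
(≈ 240–610 streamlines per run), five noise seeds for the crossing
comparison, and 10⁴ Monte-Carlo draws for the noise-bias check. A full
acceptance run completes in about a minute on one CPU.

## Known limitations

* Euler integration only; no Runge-Kutta option.
* The per-point Python propagation loop favors clarity over speed
  (≈ 3 s per crossing-phantom tractogram); whole-brain in-vivo use would
  want a vectorized or compiled inner loop.
* The FTACTD weights are used as published, without renormalizing
  `Cl + Cp` to 1; since only the direction of the blend matters this
  affects nothing at the two limits but does scale the relative influence
  of the terms in mixed-shape voxels.
* Single-tensor model throughout: three-way crossings, kissing or fanning
  configurations are outside what any of the implemented methods can
  represent.
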