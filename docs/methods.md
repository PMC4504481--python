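# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test problems do and do not demonstrate.

## The scoring model

A binding pocket is described from one or more *vantage points* (origins)
placed 30 Å behind the pocket center P. For every pocket shell point (a
grid cell of the detected pocket that touches the protein wall) a ray is
recorded in spherical coordinates (ρ, θ, φ) relative to its origin: ρ is
the distance at which the ray meets the protein surface. A candidate ligand
pose is evaluated by casting the same rays at the ligand, modeled as the
union of its atomic spheres with radii scaled by 0.9 (the
`-atom_radius_scale` convention), and comparing distances ray by ray:

* both surfaces hit, pocket first — underpacking, weight c1 (fixed 1.00);
* ligand hit first — steric clash, weight c2;
* pocket hit, ligand missed — ligand too small, count × c3;
* boundary-layer ray hits the ligand — ligand outside the pocket, count × c4.

The *boundary layer* is a one-cell shell of solvent cells around the pocket
mouth; rays to it carry no pocket distance and exist only to penalize
ligand volume outside the site. A boundary ray that also misses the ligand
contributes nothing: the alternative reading (a constant per such ray) is
pose-independent and cannot affect ranking, so it is not implemented.

With electrostatics enabled the score adds c5 · Σᵢ qᵢφ(xᵢ) over ligand
atoms, where φ is trilinearly interpolated from a conditioned potential
grid (below). Because every weight multiplies one disjoint group of rays,
the unweighted group sums (the *component energies*) fully determine the
score under any weights; this identity is test-pinned to 1e-9 and is what
makes weight fitting on cached components exact rather than approximate.

Units are mixed by construction: c1/c2 scale Å sums, c3/c4 scale counts,
c5 scales kT/e·e; the weights absorb the units.

### Weight presets

| preset | c2 | c3 | c4 | c5 |
|---|---|---|---|---|
| original | 3.12 | 13.32 | 8.13 | — |
| rank-fit, shape only (default) | 1.7 | 4.2 | 4.4 | — |
| rank-fit, with electrostatics | 1.6 | 2.0 | 0.8 | 0.025 |

Legacy flag names (`steric_weight`, `missing_point_weight`,
`extra_point_weight`, `esp_weight`) are accepted as aliases for c2–c5.

## Pocket detection

A LIGSITE-style scan on a regular grid (default spacing 0.5 Å, matching the
potential grid). Cells within (atom radius + 1.4 Å probe) of any atom are
INTERIOR. A remaining cell is POCKET if it sees protein in both directions
along at least 4 of 7 scan axes (3 lattice axes + 4 cube diagonals) and
lies within 12 Å of a target-residue atom; both numbers are configuration
knobs. A one-cell shell of solvent cells adjacent to POCKET becomes the
BOUNDARY layer. P is the centroid of POCKET cells; the bounding box of
POCKET ∪ BOUNDARY cells is the docking translation search space, and the
box to which the potential grid is masked.

The enclosure threshold of 4 means a true hemispherical dimple (enclosed
along at most the two tangential lattice axes) is *not* a pocket; the
method targets pockets with at least some overhang, and the test cavities
are carved slightly sub-surface so their deep cells are diagonal-enclosed.
For self-dock benchmarks the "near" restriction can be driven by a bound
ligand instead of target residues (`--bound-ligand --lig-grid`), with a
tighter cutoff, which trims solvent lobes past the cavity mouth out of the
pocket. This mirrors the bound-ligand-centered grid option of the original
workflow and is how the packaged self-dock experiments are run.

## Origins

O₁ is placed 30 Å from P, by one of: the P→protein-centroid direction
(default); the normal of the least-squares plane through the shell points,
taking the solution nearer the protein center (flat sites); the summed
shell-point→P vector (deep sites); or a user residue direction. In
multi-origin mode O₂–O₅ are O₁ rotated ±45° about P around two axes w = u×v
and z = u×w (u = P→O₁; v uses a seeded random point, so the frame is
reproducible). Each shell/boundary point is assigned to its nearest origin
only — five origins redistribute the rays and never increase their count.
Ties in the nearest-origin assignment go to the lowest origin index.

Each origin's spherical frame has +z pointing at P and x chosen as the
world axis least parallel to z, orthogonalized; the frame is a pure
function of (origin, P), so a ray-file's angles are self-contained.

## Electrostatic grid conditioning

Potential grids (imported OpenDX, e.g. from APBS, or the built-in
screened-Coulomb generator φ = Σ q/(4 max(r, 0.5 Å)²), a distance-dependent
dielectric ε = 4r) are conditioned in a fixed order: clamp to ±10 kT/e,
zero nodes inside receptor atom spheres, set nodes outside the pocket box
to +100. Clamping precedes masking so the +100 sentinel survives; the
operation is idempotent and the conditioned value domain is
[−10, 10] ∪ {0} ∪ {+100}. Queries beyond the stored grid also return +100,
so the outside penalty has no holes. Trilinear interpolation is written
out explicitly (8-corner blend): it is exact on trilinear polynomials and
bounded by the corner values, and the out-of-hull rule above is part of
the scoring semantics, not an interpolation detail. The Coulomb generator
is a stand-in for a finite-difference Poisson–Boltzmann solve that
preserves the full data path (grid → condition → interpolate → sum);
production grids should be imported.

## Docking search

Global-best particle swarm over a 7-vector: translation (bounded by the
pocket box), three Euler angles (ZYX composition, wrapped modulo 2π), and
a continuous conformer coordinate κ that rounds half-up to a conformer
index (reflected at [1, n]). Hyperparameters are the standard
constriction-style values — inertia 0.7298, cognitive = social = 1.49618,
velocities clamped to half the per-dimension range, positions reflected at
bounds — our choice, exposed as module constants. Swarm attraction uses
plain coordinate differences even for the periodic angle dimensions:
per-angle shortest-arc pulls split the swarm across equivalent Euler
representations of the same rotation and converge measurably worse.
Defaults are 100 particles and 100 steps.
All randomness flows from one seed; results are bit-reproducible. The
legacy sequential protocol freezes κ and runs one trajectory per
conformer with an independent derived seed, returning the best.

Euler angles gimbal-lock at ry = ±π/2; at this search granularity (the
swarm needs ~15° accuracy, not gradients) this is acceptable and is the
parameterization the 7-number particle layout implies.

## Weight fitting

For each target, one native pose plus a library of random decoy poses
(uniform translation in the search box, Haar-uniform orientation, uniform
conformer) are reduced to component energies. The objective is the sum
over targets of the native's rank (1 = lowest score; ties average) among
its poses. Nelder–Mead runs in log-weight space (positivity for free) with
c1 held at 1; because the objective is piecewise constant, the simplex is
started wide (edge 2 in log-space) and restarted from seeded points around
the unit-weight scale, keeping the best point ever evaluated — the fit
therefore never returns a point worse than its init. Leave-one-out
cross-validation over targets reports per-weight mean ± sd and held-out
native ranks. Rank direction, tie handling, and counting the native among
its own pose pool are pinned choices, each covered by a test.

Desk-scale defaults are 5 targets × 20 decoy ligands × 100 poses; the
full-scale geometry (25 × 650 × 1000) is supported but not exercised by
the test suite.

## Synthetic fixtures and what they show

Fixtures are sphere-cluster pseudo-molecules: the scoring and search
layers see only spheres and charges, so chemical realism adds nothing to
correctness testing. Real PDB/SDF/MOL2/DX inputs go through the same I/O
paths.

* `make_ligand` grows a compact connected cluster (bonded distances
  1.4–1.8 Å, minimum separation 1.4 Å, carbon-like 1.7 Å spheres) and then
  extends a short tail so the shape has no approximate two-fold symmetry —
  a near-symmetric blob makes pose recovery ill-posed regardless of the
  scoring function, because a flipped pose is genuinely almost as
  complementary.
* `make_complementary_receptor` tiles wall spheres along outward normals
  of the ligand's union surface at an offset chosen so the probe-inflated
  interior boundary tracks the 0.9-scaled ligand surface to within one
  grid cell, leaving a mouth cone open. The generating pose is therefore a
  certified near-optimum of the shape score: all terms are non-negative
  and the true pose keeps each near its discretization floor. The
  remaining true-pose score is dominated by cell-diagonal straddle
  (±√3·spacing/2 per ray, amplified by oblique incidence) and by grazing
  rays near the ligand silhouette; it is a construction floor, not a
  scoring error.
* `make_well_receptor` builds a slab with a steep cylindrical well whose
  side walls are invisible to a single origin behind the pocket — the
  geometry that motivates multiple vantage points; visibility is measured
  by marching rays through the pocket grid.
* `make_spherical_pocket_receptor` carves a sub-surface spherical cavity
  used by the pocket-detection tests; `make_convex_receptor` is the
  no-pocket control.

Passing self-dock tests show that the score's global minimum sits at the
constructed optimum and that the swarm finds it reliably at the stated
budget. They do not show chemical accuracy, robustness to receptor
flexibility, conformer-generation quality, or performance on real,
partially complementary pockets.

## Problem sizes

The packaged experiments are sized for a single CPU: self-dock uses a
15-atom ligand, 5 conformers, ~1100 rays at 0.5 Å spacing, 100 particles ×
300 steps × 10 seeds; the conformer-selection comparison uses matched
evaluation budgets (~18k pose evaluations per protocol); weight-fit
recovery uses 5 targets × 20 decoys and a 10³-point lattice oracle. These
sizes were chosen so the full suite reruns in minutes while leaving each
experiment's effect unambiguous.

## Known limitations

* The ligand surface is always the union of scaled atomic spheres
  (closed-form ray intersections); no solvent-excluded-surface model.
* `-origin_cutoff` is accepted and stored but has no documented semantics
  to implement.
* The Coulomb grid generator is not a Poisson–Boltzmann solver; ionic
  strength and dielectric boundaries are out of scope.
* No post-docking all-atom minimization; the receptor is rigid.
* GPU execution is out of scope; the batched NumPy kernels are the CPU
  analogue of the original's per-ray parallelism.
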