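# Methods

## The question and the model

Microfracture surgery perforates the subchondral bone plate with small
holes to let marrow stem cells reach a cartilage defect.  Clinical
guidance spaces the holes 3–4 mm apart, but tighter spacing recruits
more cells, so the mechanical question is whether dense hole packing
destabilises the plate under physiological load.  `microfx` answers it
with a voxel finite-element model of a simplified osteochondral block:

* geometry — a rectangular block, 16 × 16 mm laterally, made of a
  0.3 mm dense subchondral plate on top of 7.7 mm of homogenised
  trabecular bone (8 mm total height);
* materials — isotropic linear elasticity, plate E = 17 GPa, trabecular
  E = 700 MPa, Poisson ratio 0.3 for both, plate yield stress 135 MPa;
* holes — vertical cylinders, 1 mm diameter, 4 mm deep (they fully
  perforate the 0.3 mm plate), on a square grid inside a central
  8 × 8 mm defect region, at edge-to-edge spacings of 1, 1.5, 2, 2.5,
  3, 4 and 5 mm, plus an intact (hole-free) configuration;
* load — 147 N (quiet two-legged stance, one condyle) applied to the
  articular surface, bottom face fixed in all three directions;
* outputs — per configuration, the peak and 99.9th-percentile von Mises
  stress in the plate, the peak displacement, and the safety factor
  peak / yield.

Units are mm, N and MPa throughout (1 N/mm² = 1 MPa), with z measured
downward from the articular surface.

## Parameters the source study leaves open

Several geometric inputs are not measurable quantities but modelling
choices, and the results should be read with them in mind (they are
embedded in every generated report):

* **Hole diameter, 1 mm.**  Typical microfracture awl scale; also the
  only round value compatible with a 1 mm edge-to-edge spacing group.
* **Spacing convention, edge-to-edge.**  "Distance between holes" is
  taken as the clear bone bridge between hole walls, so the
  centre-to-centre pitch is spacing + diameter.  A 1 mm spacing with
  1 mm holes is then geometrically valid, which the centre-to-centre
  reading would forbid.  Centre-to-centre is available as an option.
* **Defect region 8 × 8 mm, block 16 × 16 mm.**  A clinically plausible
  lesion with ≥ 4 mm of margin to the block boundary.  The defect
  region bounds the hole *centres*: a surgeon fills the lesion to its
  rim, so boundary holes may overhang the lesion edge by one radius
  (they must still fit inside the block).  With this convention the
  packing counts are 25, 16, 9, 9, 9, 4 and 4 holes for the seven
  spacings — counts are emergent from packing, never inputs.
* **Load footprint.**  The physical joint transmits load through a
  rounded-on-flat frictionless contact.  In a single-block model this
  is replaced by a statically equivalent traction on the top face;
  uniform over the whole face by default, with uniform-patch and
  Hertzian-patch profiles available.  Nodal force shares always sum to
  the total force exactly, and hole openings carry no traction.
* **Trabecular Poisson ratio 0.3.**  The source material table says
  0.3 while its text says 0.25; the table value is the default and
  either can be set.

Because of these open parameters the pipeline's stress values are
bounds and spacing trends, not point predictions; no claim is made of
reproducing any particular published MPa value.  The headline,
checkable claim is the stability bound: every configuration's plate
peak stays far below the 135 MPa yield, so every safety factor is far
below 1.

## Discretisation

The block is voxelised on a regular grid (anisotropic voxels allowed:
finer vertically so the 0.3 mm plate always gets at least two elements
through its thickness — configurations that violate this are rejected).
Voxel counts are `ceil(extent / requested size)` per axis, so the grid
covers the block exactly and is never coarser than requested.  Each
voxel is labelled by the region of its centroid (deterministic, no
volume-fraction thresholds), and every solid voxel becomes one 8-node
hexahedral element; the mesh must form a single face-connected
component or a `DiscontinuityError` is raised.

Two presets exist: `fast` (0.4 mm lateral / 0.15 mm vertical; the
intact block is a 40 × 40 × 54 grid of 86 400 elements) and `fine`
(0.1 mm isotropic).  At the fast preset a 1 mm hole spans only
2.5 voxels, which is below the four-voxels-across-the-diameter rule a
well-resolved hole wants; the configuration therefore warns rather than
refuses, because the eight-configuration experiment is meant to run in
minutes on one CPU and the quantity of interest is a bound, not a local
stress value.  The convergence study (`analysis/04_convergence.py`)
quantifies what the coarse walls cost: the robust (99.9th-percentile)
plate stress settles under refinement, while the raw peak on drilled
configurations keeps creeping upward because stair-stepped hole walls
create re-entrant corner singularities.  That is also why both numbers
are reported, with the raw maximum as the headline for conservatism.

## Elasticity solver

Trilinear hexahedra with full 2 × 2 × 2 Gauss quadrature; with at least
two elements through the plate, shear locking of the thin stiff layer
is accepted and verified against the closed-form column.  On voxel
meshes all elements of a layer are congruent, so one element matrix per
layer is computed and the global sparse matrix is assembled directly in
node-pair (27-stencil) form.  Dirichlet constraints are imposed by
elimination; degree-of-freedom ordering is lexicographic in the node
lattice, so repeated runs are bit-identical.

Systems up to 100k free dofs use sparse LU.  Larger systems use
conjugate gradients preconditioned by a geometric multigrid V-cycle
built on the voxel node lattice (trilinear prolongation between 2×
coarsened lattices, Galerkin coarse operators, one damped-Jacobi pre-
and post-smoothing sweep, direct factorisation once the coarsest level
drops below ~12k dofs).  The V-cycle is symmetric positive definite, as
CG requires, and handles the 24× plate/trabecular stiffness contrast in
roughly 90–140 iterations at the fast preset.  The relative residual
must reach the configured tolerance (default 1e-8) or the solve fails
loudly with its residual history; reactions are computed at constrained
dofs and their sum must balance the applied load to 1e-6 relative
before any result is accepted.

Stress is recovered once per element at the centroid (no nodal
averaging or extrapolation — deterministic, and artefacts at voxel
corners stay local); von Mises follows from the deviatoric invariant.
Layer peaks break ties toward the lowest element index.

## Safety factor convention

The safety factor is reported as peak stress / yield stress, with
values below 1 read as safe — the convention under which the published
per-group numbers are self-consistent (e.g. 52.8/135 = 0.39,
71.8/135 = 0.53), even though the usual engineering definition is the
inverse.  Two published groups (4 mm: 52.7 MPa vs printed 0.41; 5 mm:
55 MPa vs printed 0.39) do not satisfy peak/135 and look transposed;
the arithmetic flags them and does not force a match.

## Verification

Three independent checks back the solver, all in
`microfx.benchmarks` and asserted by the test suite:

* **Patch test.**  Homogeneous block, ν = 0, uniform pressure, roller
  base (vertical support plus the minimal rigid-mode pins): trilinear
  elements represent constant-strain states exactly, so σ_zz = −p to
  machine precision at any resolution.  The roller variant exists only
  for such fixtures; the study configuration always uses the fully
  fixed base.
* **Two-layer column.**  With ν = 0 in both layers the block is two
  springs in series: mean top settlement (F/A)(t_p/E_p + t_t/E_t)
  ≈ 6.33 µm at 147 N, matched to 0.1 % (the only discretisation error
  is the position of the layer interface within one voxel).
* **Kirsch plate.**  Thin slab with a circular through-hole under
  remote uniaxial tension, voxelized as a quarter model with symmetry
  planes.  The stress concentration is measured where the analytic
  solution defines it — the element column on the symmetry plane
  through the hole shoulder — giving 2.62 at 0.4 mm voxels (12.6 % low
  of the exact 3.0) improving to 2.81 (6.5 %) at 0.2 mm.  The global
  maximum is deliberately not the metric: on stair-stepped voxel walls
  it rides on artificial corner spikes that grow under refinement.

In addition, on meshes of ≤ 8 elements the assembled stiffness and the
solved displacements are compared entry-wise against a dense
brute-force implementation (independent 3 × 3 × 3 quadrature, dense
LAPACK solve) kept in the test suite.

## Synthetic micro-CT phantom

Real inputs to this kind of study are micro-CT scans (here emulated at
18 µm voxels).  The phantom module generates a grayscale volume — a
fully dense plate of the requested thickness (17 slices at 0.3 mm /
18 µm) over a trabecular structure modelled as a Gaussian random field
smoothed to a configurable correlation length (default 0.1 mm, roughly
a trabecular half-spacing) and thresholded at the quantile that hits
the target bone volume fraction (default BV/TV 0.3, realised within
±0.02) — plus additive Gaussian noise.  Segmentation is plain
intensity thresholding; layer labelling detects the top bone surface
per lateral column and labels bone within the plate thickness of it as
plate.  A fixed seed makes volumes bit-identical.

A thresholded random field at BV/TV 0.3 contains small floating bone
islands (as real segmentations do), so the image path includes the
standard cleanup of keeping only the largest face-connected component
before meshing (`largest_connected_component`); at moderate noise this
removes a few percent of voxels and yields a solvable mesh, whereas a
noisy scan under an aggressive threshold shatters into thousands of
components whose largest holds well under 1 % of the bone — cleanup
cannot rescue it, which is precisely the failure that motivates the
parametric block model.

The phantom exists to exercise the image→mesh path, not to claim
histomorphometric realism: it has no beam hardening, no partial-volume
blur, no anisotropic trabecular architecture.  Consequently, passing
its tests shows the pipeline handles scan-like labelled volumes and
reproduces the canonical failure mode — high noise plus an aggressive
threshold disconnects the plate from the trabecular network, making
the stiffness matrix singular — but says nothing about segmentation
accuracy on real scans.  Scanner settings (40 kVp, 200 µA, 200 ms,
0.5 mm Al filter) are carried as metadata only.

## Problem sizes and numerical defaults

The shipped analyses use the fast preset (86 400 elements for the
intact block, ~277k dofs; the full eight-configuration experiment is a
few minutes of CPU), solver tolerance 1e-8, equilibrium check 1e-6,
and a three-step convergence ladder up to 0.25 mm / 0.1 mm voxels
(~327k elements for a drilled configuration).  The `fine` preset
(0.1 mm isotropic, ~2.0M elements intact) uses the same code paths and
is provided for workstation-scale runs.

## Known limitations

* Stair-stepped hole walls make the raw peak stress mesh-dependent;
  rely on the robust peak for trend reading (the safety-factor margin
  here is so large — factors ~0.02 at full-face loading vs the
  published ~0.4–0.5 under concentrated contact — that the distinction
  does not affect the stability conclusion).
* Single-block equivalent traction instead of two-body frictionless
  contact; no cartilage, no meniscus, no bone damage around the holes,
  no material nonlinearity or anisotropy.
* The fully fixed base slightly overconstrains lateral expansion at
  the bottom; immaterial for plate-level quantities 8 mm away.
* Linear elasticity means every stress scales exactly with the load;
  147 N is quiet stance, and gait or impact loads would scale the
  safety factors proportionally.
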