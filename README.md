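# microfx

Voxel finite-element analysis of how microfracture hole spacing affects
the structural stability of the subchondral bone plate.

## The problem

Microfracture surgery treats knee cartilage defects by punching small
holes through the subchondral bone plate so marrow stem cells can reach
the lesion.  More (closer) holes recruit more cells, but surgeons are
told to keep holes 3–4 mm apart on purely empirical grounds — does
dense hole packing actually endanger the plate mechanically?

`microfx` answers this with a linear-elastic finite-element model of a
simplified osteochondral block: a 0.3 mm dense plate
(E = 17 GPa, yield σ_y = 135 MPa) over 7.7 mm of homogenised trabecular
bone (E = 700 MPa), 16 × 16 mm laterally, loaded with 147 N (quiet
stance) on the articular surface and fixed at the base.  Cylindrical
holes (⌀ 1 mm, 4 mm deep) are drilled on a square grid in a central
8 × 8 mm defect at edge-to-edge spacings of 1, 1.5, 2, 2.5, 3, 4 and
5 mm; the eighth configuration is the intact plate.  For each
configuration the pipeline reports the peak von Mises stress in the
plate, σ_vm = √(½[(σxx−σyy)² + (σyy−σzz)² + (σzz−σxx)²] + 3(σxy²+σyz²+σzx²)),
and the safety factor SF = σ_peak / σ_y (this study's convention:
SF < 1 means the plate stays below yield).

The package also ships a synthetic micro-CT phantom module (18 µm
voxels, dense plate over a thresholded Gaussian-random-field trabecular
structure) that exercises the full image → segmentation → layer
labelling → hexahedral mesh path real scans would follow, including
the classic failure mode where noisy segmentation disconnects the
plate from the trabecular network and makes the analysis singular.

Numerics: each solid voxel becomes an 8-node trilinear hexahedron;
systems beyond 100k free dofs are solved by conjugate gradients with a
geometric multigrid V-cycle preconditioner built on the voxel lattice.
Everything is deterministic — same configuration, same bytes out.

## Worked example

Running `python analysis/03_hole_spacing_experiment.py` (equivalently,
`run_spacing_experiment(preset="fast", seed=0)` from Python) prints, at
the fast preset (0.4 mm / 0.15 mm voxels) with the full-face 147 N
traction:

```
 label  spacing_mm  hole_count  peak_vm_plate_MPa  robust_peak_vm_plate_MPa  peak_displacement_mm  safety_factor  safety_factor_2dp
intact         NaN           0               2.16                     2.159              0.005884          0.016               0.02
   1mm           1          25              2.612                     2.612              0.006209        0.01935               0.02
 1.5mm         1.5          16              2.665                     2.665              0.006142        0.01974               0.02
   2mm           2           9              2.778                     2.778              0.006039        0.02058               0.02
 2.5mm         2.5           9              2.588                     2.588              0.005997        0.01917               0.02
   3mm           3           9              2.588                     2.588              0.005995        0.01917               0.02
   4mm           4           4              2.473                     2.473              0.005933        0.01832               0.02
   5mm           5           4              2.509                     2.509              0.005946        0.01858               0.02

worst group: 2mm at 2.78 MPa (safety factor 0.021); yield stress 135 MPa.
All safety factors are below 1: hole spacing does not destabilise the plate
under this load, matching the study's conclusion.
```

Reading: drilling holes raises the plate's peak stress only modestly
(intact 2.16 MPa → worst case 2.78 MPa at 2 mm spacing), and every
safety factor is two orders of magnitude below 1 — under this load and
with a full-face contact footprint, hole spacing does not destabilise
the plate.  Absolute stresses scale with the assumed contact footprint
(a concentrated patch raises them; `LoadCase(application="hertzian_patch", ...)`),
which is why the deliverable claim is the below-yield bound and the
spacing trend rather than any particular MPa value; every report embeds
its geometric assumptions (`hole diameter, defect size, load mode, …`)
for exactly this reason.

The numbered drivers under `analysis/` run the full story:
`01_phantom_to_mesh.py` (image → mesh path and its failure mode),
`02_benchmarks.py` (patch test exact to machine precision; two-layer
column settlement 6.33 µm matching the series-spring closed form to
<0.1 %; plate-with-hole stress concentration 2.62 → 2.81 vs the exact
3.0 under refinement), `03_hole_spacing_experiment.py` (the table
above), `04_convergence.py` (voxel-size ladder).  Tables land in
`results/`, bulky VTK/TIFF output in `scratch/`.

## Layout

```
src/microfx/
  geometry.py    block, materials, hole patterns, load cases, config I/O
  voxelmesh.py   voxelization, hex meshing, boundary node sets
  elasticity.py  element stiffness, assembly, multigrid-CG solver
  stress.py      stress recovery, von Mises, layer peaks, safety factors
  phantom.py     synthetic micro-CT volumes, segmentation, layer labels
  pipeline.py    eight-configuration experiment, convergence study
  benchmarks.py  patch test, two-layer column, Kirsch plate
  io.py          VTK / TIFF / raw-volume readers and writers
analysis/        numbered drivers (see above)
docs/methods.md  model, assumptions, numerics, limitations
tests/           pytest suite with an independent dense-solver oracle
```
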