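# Methods

`coroflow` models how coronary side branches shape simulated hemodynamics.
The pipeline has four stages: synthetic coronary anatomy, biplane
angiographic imaging and 3D reconstruction, lattice-Boltzmann blood flow,
and endothelial shear stress (ESS) analysis with complete-versus-pruned
model comparisons. This note records the models, the defaults and why,
the numerical choices, and what the synthetic experiments do and do not
show about patient data.

## Synthetic coronary trees

Patient angiograms are not shippable, so the package generates its own
anatomy: rooted trees of centerline polylines with per-point radii (mm).
The left template is a left main (LM, 4.5 mm diameter) bifurcating into a
LAD (110 mm, 3.6 tapering to 1.4 mm) and an LCx (80 mm, 3.2 to 1.4 mm)
with diagonal and obtuse-marginal side branches; the right template is a
single RCA trunk with marginal/PDA-type branches. Defaults are adult
physiologic ranges; `scale` shrinks lengths uniformly for desk-scale
runs without leaving physiologic diameter ranges. Key rules:

* **Side-branch inclusion.** Every generated side branch has an ostial
  diameter above 1 mm, matching the inclusion rule of clinical
  angiographic reconstructions; requests below it are rejected unless
  explicitly overridden.
* **Tapering.** Radii decrease linearly with arclength per segment.
* **Stenoses.** A focal stenosis multiplies the diameter by a C1 cosine
  bell reaching (1 − severity) at the lesion center. The bell is a
  modeling choice: lesion shape is otherwise unconstrained.
* **Tortuosity.** Centerlines carry smooth random transverse wander
  (cubic-spline interpolated control offsets), capped at 4% of segment
  length so short segments stay vessel-like.
* A fixed integer seed makes every tree bitwise reproducible.

What the generator does *not* emulate: cardiac motion, lumen
ellipticity, plaque eccentricity, branch-count/length distributions of
any specific patient cohort, or image noise textures. Conclusions drawn
from these trees are about the pipeline's behavior, not about any
patient population.

## Biplane projection and 3D reconstruction

Projection is cone-beam: a point X-ray source, an image-intensifier
plane, clinical RAO/LAO and cranial/caudal angles composed as
Rx(cranial) @ Rz(LAO) applied to the +y beam axis, isocenter at the
world origin. Projected width = 2 × radius × SID/depth / pixel size.
The two views must be separated by more than 45 degrees, the constraint
under which two-view reconstruction is well posed.

Reconstruction recovers a tree from two labeled centerline projections:

1. **Correspondence.** For each segment, points are matched across views
   by dynamic programming over monotone (order-preserving) alignments
   with the epipolar residual as cost; vessel centerlines are ordered
   curves, so the monotone DP is optimal and deterministic. Segments
   visible in only one view are excluded with a warning.
2. **Triangulation.** Each matched pair becomes the midpoint of the
   common perpendicular between the two back-projected rays; the miss
   distance is kept as a per-point quality metric. Rays closer than 1
   degree to parallel are interpolated from neighbors instead.
3. **Diameters.** radius = width × pixel size × depth / (2 × SID),
   averaged over the views; disagreement above 5% is logged.

Branch topology (parenthood, attachment fractions) is carried through
the projection labels — the algorithm assumes operator-identified
vessels, not blind cross-branch matching. The noise-free round trip
(generate → project → reconstruct) recovers centerlines to numerical
precision, which is the module's primary acceptance property; robustness
is probed with Gaussian pixel jitter.

## Surface, voxels, pruning

Tubes are lofted by an implicit union of rounded-cone distance fields
sampled on a grid and extracted with marching cubes; flat inlet/outlet
caps are cut by clipping half-spaces local to each open end. This
blends bifurcations watertight without fragile boolean mesh operations.
Voxelization classifies voxel centers by ray-crossing parity per lattice
column; the largest 26-connected fluid component is kept and the
inlet/outlet disks are identified from the cap metadata. Pruning
removes labeled branches (with their subtrees) or truncates segments at
a given arclength, leaving all remaining geometry bitwise unchanged —
this is how matched (MCM) models are derived from complete (CCM) ones.

Mesh-to-mesh agreement is quantified by a sampled symmetric Hausdorff
distance with exact point-to-triangle distances over nearest-centroid
candidates (10^4 samples by default, seed-fixed); rigid alignment uses
Kabsch N-point registration.

## Lattice-Boltzmann solver

D3Q19 lattice, two-relaxation-time (TRT) collision that reduces to BGK
when both relaxation times coincide. Blood is Newtonian with dynamic
viscosity 4 cP and density 1060 kg/m^3 (overridable); walls are rigid.

* **Unit mapping.** The time step is set so a configurable expected peak
  velocity maps to a target lattice Mach number (default 0.1); the
  symmetric relaxation time follows from nu = c_s^2 (tau − 1/2) dt and
  must land in (0.5, 2].
* **Walls.** Interpolated (Bouzidi, linear) bounce-back on cut links;
  the link-wall intersection fraction q is computed by exact ray-triangle
  casting against the lofted surface (q = 1/2, i.e. halfway bounce-back,
  when no surface is attached).
* **Inlet.** Equilibrium velocity boundary imposing a Poiseuille profile
  scaled by a periodic waveform; the profile is normalized so the imposed
  volumetric inflow is exactly v_mean × pi R^2. The boundary density is
  taken from the interior neighbor (a self-determined density starves
  the inlet). Defaults: 0.25 m/s steady (average diastole), 0.28 m/s
  pulsatile cycle mean, period 0.8 s. The packaged waveform is a
  two-phase, diastolic-dominant profile with mean exactly 1 and is fully
  user-replaceable.
* **Outlets.** Lumped-parameter (resistance) boundaries: P_k = P_ref +
  Q_k R_k with an under-relaxed running estimate of Q_k (factor 0.05,
  updated every 5 steps). The total resistance is mean aortic pressure /
  total mean flow, apportioned by Murray's law (R_i proportional to
  d_i^-3, exponent configurable) so the parallel combination equals the
  total exactly. In a velocity-driven domain only outlet pressure
  differences matter, so the common mode is gauged out to keep lattice
  densities near unity.
* **Flux measurement.** Outlet/inlet volumetric flows are the discrete
  fluxes through a few full lattice planes just inside each opening
  (inset past the oblique cap's reach), averaged; this keeps global mass
  closure on tree runs to under about 1%.
* **Body force.** Guo forcing with a periodic axis option supports
  fully developed, pressure-gradient-driven benchmark flows free of
  entrance effects. Interpolated bounce-back leaks mass very slowly, so
  closed (body-force-driven) runs pin total mass to its reference.
* **Wall shear stress.** The deviatoric stress is reconstructed from
  non-equilibrium moments. The wall-adjacent node's own moments carry a
  large near-boundary error at low tau, so the traction is sampled at
  the two nodes one and two spacings inward along the (area-weighted,
  smoothed) surface normal and linearly extrapolated onto the wall.
  On the 20-voxel-per-diameter tube benchmark this reproduces the
  analytic wall shear within about 3%.
* **Stabilization on coarse grids.** Poststenotic jets on desk-scale
  grids are under-resolved (grid Reynolds numbers in the hundreds);
  tree runs therefore use a fixed antisymmetric relaxation time
  (tau_minus = 1) plus a Smagorinsky eddy viscosity (C^2 = 0.01) from
  the local non-equilibrium stress. Both are disabled in the
  resolution-validated laminar benchmarks, where they would bias the
  viscosity. The staircase wall at first order and this stabilization
  are the dominant accuracy limiters of coarse runs; results from them
  are treated as directional, not quantitative.

A 0D Poiseuille resistor network of the same tree (centerline-integrated
8 mu / (pi r^4) resistances in series with the outlet resistances) serves
as the independent cross-check for flow splits: the 3D solver reproduces
its splits within a few percent, and a symmetric bifurcation splits
50/50 to within 1%.

## ESS analysis

* **TAESS** is the trapezoidal time average of |tangential traction|
  over exactly one cardiac cycle.
* **Sectioning.** Centerlines are resampled every 0.3 mm; each wall
  sample is assigned to the nearest section of its own segment and
  sections average their samples (empty sections are flagged NaN, never
  silently dropped). A ~600 mm tree yields about 2000 sections.
* **Point-to-point comparison.** Sections are matched between two models
  by (segment label, arclength index) — not nearest-neighbor in space,
  which could cross branches. Complete-model-only sections are excluded
  and listed. The headline statistic is the fraction of matched pairs
  whose |difference| exceeds 0.5 Pa.
* **Strata.** Sections are binned into low (<1 Pa), intermediate
  (1–<2 Pa), high (2–<3 Pa) and very high (>=3 Pa) ESS bands. A value
  exactly on a boundary goes to the higher band; the edges are
  configurable. The pro-atherogenic low-TAESS indicator threshold is
  exposed as a single 2 Pa cutoff.
* **Outflow.** Per-outlet cycle-mean flows (ml/s) grouped into major
  vessels by tree ancestry.
* **Statistics.** Kolmogorov–Smirnov normality screen per group, then a
  two-tailed Student t test (2 groups), Kruskal–Wallis (unpaired >= 3)
  or Friedman (paired >= 3, equal blocks required); significance at
  p < 0.05, summaries as mean ± SEM.

## The ablation experiment

The central experiment prunes side branches from a stenosed LAD-like
tree and watches trunk wall shear rise. The canonical anatomy
(`pipeline.lad_ablation_tree`) is a 45 mm trunk tapering 3.2 to 1.1 mm
with a proximal cosine-bell stenosis (50% diameter) and three ~2 mm
diagonal branches in the proximal half — sized, using the package's own
0D network model, so the branches drain the physiologic majority of
ostial inflow and the distal trunk runs slow, as in a real left coronary
tree. All four models (3, 2, 1, 0 branches) share the same inlet
velocity: the matched-inflow protocol at the trunk ostium. Expected and
observed behavior: trunk-averaged TAESS increases monotonically as
branches are removed, with the branch-free model at least twice the
complete model, and trunk outflow rises in step. The desk-scale runs
use a 0.3 mm grid, a shortened 0.1–0.12 s cycle and 2 cycles so the
experiment completes in minutes on one CPU; this raises the Womersley
number relative to a physiologic 0.8 s cycle, which affects the waveform
shape of the traction but not the direction or ordering of the
time-averaged comparison.

## Problem sizes and determinism

Default desk-scale runs use trees a few centimeters long, 0.15–0.3 mm
voxels (10^4–10^5 fluid nodes), and two simulated cycles; the analytic
tube benchmark runs 20 voxels per diameter and 30k lattice steps. A
single seed drives every stochastic stage (tree synthesis, projection
jitter, Hausdorff sampling); two runs of the same configuration produce
byte-identical reports, which the test suite checks by checksum.

## Known limitations

* First-order staircase wall representation away from the interpolated
  links; coarse-grid tree runs are directional.
* No fluid–structure interaction, non-Newtonian rheology, or turbulence
  modeling; eddy-viscosity stabilization is a numerical device, not an
  LES claim.
* Reconstruction assumes labeled (operator-identified) vessels in both
  views and a single static frame; no motion, no automatic segmentation.
* The lumped outlet model has a single resistance per outlet (no
  compliance or inertance), so diastolic-systolic phase behavior of the
  microcirculation is not represented.
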