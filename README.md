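# coroflow

Synthetic coronary trees, biplane-angiographic 3D reconstruction, and
lattice-Boltzmann blood-flow simulation, built to answer one question:
**how much do the side branches that most simulation studies discard
change the endothelial shear stress (ESS) on the vessel wall?**

Patient-specific hemodynamic models are usually built from a single
reconstructed conduit (the *matched-conduit model*, MCM). The real
artery sheds flow into diagonals and marginals along its whole length.
This package builds both the *complete coronary model* (CCM) and its
branch-pruned MCM counterpart from the **same** geometry, runs both
under the same inflow, and quantifies the ESS difference section by
section.

## The model

- **Anatomy** (`coroflow.vasctree`): parametric left (LM → LAD/LCx with
  diagonal/obtuse-marginal branches) and right (RCA) trees with
  physiologic tapering, >1 mm side-branch inclusion, and cosine-bell
  stenoses; cone-beam projection of the tree onto two gantry views
  (RAO/LAO, cranial/caudal) with magnification and pixel quantization.
- **Reconstruction** (`coroflow.reconstruct3d`): epipolar-constrained
  monotone correspondence between the two views, common-perpendicular
  ray triangulation, magnification-corrected diameter recovery, and
  ground-truth error reports.
- **Geometry** (`coroflow.geomkit`): implicit lofting of a tree into a
  watertight surface mesh, ray-parity voxelization with inlet/outlet
  cap labeling, branch pruning (CCM → MCM), centerline sectioning,
  symmetric Hausdorff distance and n-point rigid registration oracles.
- **Flow** (`coroflow.lbmflow`): D3Q19 two-relaxation-time lattice
  Boltzmann with Guo forcing, Bouzidi interpolated bounce-back using
  exact ray-cast wall-link fractions, equilibrium velocity inlets with
  a physiologic coronary waveform, lumped resistance outlets allocated
  by Murray's law, optional Smagorinsky stabilization for stenotic
  jets, and wall shear stress extracted from non-equilibrium moments
  with two-point extrapolation to the true wall. A 0D Poiseuille
  resistor network provides an independent flow-split oracle.
- **Analysis** (`coroflow.essanalysis`): time-averaged ESS (TAESS) over
  the final cycle, 0.3 mm circumferential section averaging, CCM↔MCM
  point-to-point matching on the shared centerline, ESS strata
  ([<1, 1–2, 2–3, ≥3] Pa) and nonparametric statistics.
- **Orchestration** (`coroflow.pipeline`, CLI `coroflow`): the full
  seeded study — synthesize → project → reconstruct → mesh → voxelize →
  simulate CCM and MCM → compare — plus the side-branch ablation
  series and a Hausdorff identification matrix.

## Worked example

`examples/03_tube_validation.py` drives a rigid 1.5 mm-radius tube with
the analytic Poiseuille pressure gradient for blood (4 cP) at 20 voxels
per diameter and compares against the exact solution:

```text
centerline velocity 0.5537 m/s   (analytic 2 v_mean = 0.560)
mean wall shear     2.915 Pa     (analytic 4 mu v/R = 2.987)
flow rate           1.953 ml/s (analytic 1.979)
```

`examples/04_branch_ablation.py` is the headline experiment: a stenosed
LAD-like trunk with three diagonal branches is simulated pulsatilely,
then re-simulated with 2, 1 and 0 branches at the same inlet velocity:

```text
 model  trunk TAESS (Pa)  0D prediction  trunk outflow (ml/s)
LAD  3              6.52           3.48                 0.256
LAD  2              8.04           3.82                 0.381
LAD  1              9.61           5.21                 0.637
LAD  0             16.05          15.04                 1.766

branch-free / complete TAESS ratio: 2.46x
```

Dropping the side branches forces the whole inflow through the trunk
and more than doubles the computed trunk shear — a single-conduit model
systematically overestimates ESS. The package's independent 0D
resistor-network oracle predicts the same ordering.

`examples/02_reconstruct_from_views.py` shows the imaging round trip:

```text
noise-free round trip: centerline RMSE 7.99e-14 mm, diameter MAE 1.57e-15 mm
jitter 0.5 px: RMSE 0.118 mm (graceful, roughly linear degradation)
jitter 1.0 px: RMSE 0.278 mm
jitter 2.0 px: RMSE 0.598 mm
```

The other examples cover tree synthesis and projection (01), the full
CCM-vs-MCM study end to end (05), and Hausdorff-based model
identification (06).

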