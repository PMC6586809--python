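"""End-to-end study orchestration.

``run_full_study`` reproduces the side-branch study design on synthetic
anatomy: synthesize a stenosed left-coronary-like tree, image it onto two
gantry views, reconstruct it in 3D, loft/voxelize, simulate the complete
model (CCM), the branch-pruned matched model (MCM), and the LAD-only
ablation series (LAD 3 -> 0 side branches, with the sub-model inflow
matched to the flow entering the LAD in the complete model), then reduce
everything to TAESS section profiles, point-to-point comparisons, strata
and outflow reports.

``run_hd_matrix`` reproduces the model-identification design: a set of
trees and their perturbed copies, cross-compared by symmetric Hausdorff
distance; correct identification shows up as a dominant diagonal.

Every stage artifact is persisted under the run directory; rerunning with
the same config and seed is bitwise deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import essanalysis, geomkit, lbmflow, reconstruct3d, vasctree

__all__ = ["RunConfig", "run_full_study", "run_hd_matrix"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One study run; a single seed governs every stochastic stage."""

    seed: int = 0
    # tree
    template: str = "left"
    tree_scale: float = 0.4
    n_diagonals: int = 3
    n_marginals: int = 1
    stenosis_segment: str = "LAD"
    stenosis_fraction: float = 0.22
    stenosis_length_mm: float = 6.0
    stenosis_severity: float = 0.5
    # gantry
    gantry_a: tuple = (-30.0, 20.0)
    gantry_b: tuple = (40.0, -15.0)
    projection_jitter_px: float = 0.0
    # geometry
    mesh_pitch_mm: Optional[float] = None
    voxel_mm: float = 0.25
    # solver
    inlet_mode: str = "pulsatile"
    mean_velocity: Optional[float] = None
    period_s: float = 0.8
    n_cycles: int = 2
    target_mach: float = 0.1
    u_max_phys: float = 1.5
    tau_minus: Optional[float] = 1.0   # TRT stabilizer on coarse grids
    smagorinsky_c2: float = 0.01       # eddy-viscosity stabilizer (0 = off)
    aortic_pressure_mmhg: float = 90.0
    total_flow_mls: float = 2.0
    murray_exponent: float = 3.0
    steady_tol: float = 1e-5
    samples_per_cycle: int = 24
    # analysis
    section_spacing_mm: float = 0.3
    delta_threshold_pa: float = 0.5
    band_edges_pa: tuple = (1.0, 2.0, 3.0)
    # ablations
    mcm_remove: tuple = ("Diag2", "Diag3", "OM1")
    lad_series: tuple = (3, 2, 1, 0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("gantry_a", "gantry_b", "band_edges_pa", "mcm_remove", "lad_series"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _build_tree(config: RunConfig) -> vasctree.VesselTree:
    params = vasctree.TreeParams(
        scale=config.tree_scale, n_diagonals=config.n_diagonals,
        n_marginals=config.n_marginals,
        stenoses=[vasctree.StenosisSpec(
            segment=config.stenosis_segment,
            center_arclength_fraction=config.stenosis_fraction,
            length_mm=config.stenosis_length_mm,
            severity=config.stenosis_severity)]
        if config.stenosis_severity > 0 else [],
    )
    return vasctree.generate_tree(config.template, params, seed=config.seed)


def _gantry(config: RunConfig) -> vasctree.GantryGeometry:
    return vasctree.GantryGeometry(
        vasctree.GantryView(*config.gantry_a),
        vasctree.GantryView(*config.gantry_b))


def _inlet(config: RunConfig, mean_velocity: Optional[float] = None) -> lbmflow.InletSpec:
    return lbmflow.InletSpec(mode=config.inlet_mode,
                             mean_velocity=mean_velocity or config.mean_velocity,
                             period=config.period_s)


def simulate_tree(tree, config: RunConfig, mean_velocity: Optional[float] = None,
                  total_flow_mls: Optional[float] = None):
    """Mesh, voxelize and run one model; returns (surface, profile of
    section-averaged TAESS, transient result, sections)."""
    surface = geomkit.loft_mesh(tree, pitch=config.mesh_pitch_mm)
    grid = geomkit.voxelize(surface, config.voxel_mm, tree)
    state = lbmflow.build_lattice(grid, lbmflow.FluidConfig(),
                                  target_mach=config.target_mach,
                                  u_max_phys=config.u_max_phys,
                                  tau_minus=config.tau_minus)
    state.smagorinsky_c2 = config.smagorinsky_c2
    inlet = _inlet(config, mean_velocity)
    outlets = lbmflow.assign_resistances(
        tree, config.aortic_pressure_mmhg * lbmflow.MMHG_PA,
        (total_flow_mls or config.total_flow_mls) * 1e-6,
        murray_exponent=config.murray_exponent)
    wallset = lbmflow.WallSampleSet(state, surface)
    result = lbmflow.run_transient(state, inlet, outlets,
                                   n_cycles=config.n_cycles, wallset=wallset,
                                   samples_per_cycle=config.samples_per_cycle)
    ta = essanalysis.taess(result.wss)
    sections = geomkit.section_centerline(tree, config.section_spacing_mm)
    profile = essanalysis.circumferential_average(
        ta, wallset.positions_mm, wallset.labels, tree, sections)
    return surface, profile, result, sections


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _trunk_mean_taess(profile: essanalysis.SectionProfile, trunk: str) -> float:
    sel = [i for i, l in enumerate(profile.labels)
           if l == trunk and np.isfinite(profile.taess[i])]
    return float(np.mean(profile.taess[sel]))


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def run_full_study(config: RunConfig, outdir) -> dict:
    """Execute synth -> project -> reconstruct -> mesh -> voxelize ->
    simulate (CCM, MCM, LAD-k series) -> analyze; returns the consolidated
    report (also written to ``outdir/report.json`` with a checksum)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                    "stages": {}}

    # --- synthesize and image -------------------------------------------
    truth = _build_tree(config)
    truth.to_json(out / "tree_truth.json")
    gantry = _gantry(config)
    proj_a, proj_b = vasctree.project_tree(truth, gantry)
    if config.projection_jitter_px > 0:
        proj_a = vasctree.degrade_projection(proj_a, config.projection_jitter_px,
                                             0.0, seed=config.seed + 1)
        proj_b = vasctree.degrade_projection(proj_b, config.projection_jitter_px,
                                             0.0, seed=config.seed + 2)
    proj_a.to_json(out / "view_a.json")
    proj_b.to_json(out / "view_b.json")

    # --- reconstruct -----------------------------------------------------
    recon = reconstruct3d.reconstruct(proj_a, proj_b, gantry)
    recon.to_json(out / "tree_recon.json")
    eval_rep = reconstruct3d.evaluate_reconstruction(recon, truth)
    report["stages"]["reconstruction"] = {
        "rmse_mm": eval_rep.rmse_mm,
        "diameter_mae_mm": eval_rep.diameter_mae_mm,
        "per_segment_rmse_mm": eval_rep.per_segment_rmse_mm,
    }

    # --- CCM -------------------------------------------------------------
    surface_ccm, prof_ccm, res_ccm, _ = simulate_tree(recon, config)
    surface_ccm.export_stl(out / "ccm.stl")
    prof_ccm.to_frame().to_csv(out / "ccm_sections.csv", index=False)
    flow_ccm = essanalysis.outflow_report(res_ccm.flows_mls, res_ccm.flow_times,
                                          recon, res_ccm.inlet_flow_mls)

    # --- MCM -------------------------------------------------------------
    removable = [n for n in config.mcm_remove if recon.has_segment(n)]
    mcm_tree = geomkit.prune(recon, geomkit.PruneSpec.remove(*removable))
    mcm_tree.to_json(out / "tree_mcm.json")
    surface_mcm, prof_mcm, res_mcm, _ = simulate_tree(mcm_tree, config)
    prof_mcm.to_frame().to_csv(out / "mcm_sections.csv", index=False)
    flow_mcm = essanalysis.outflow_report(res_mcm.flows_mls, res_mcm.flow_times,
                                          mcm_tree, res_mcm.inlet_flow_mls)

    # --- CCM vs MCM ------------------------------------------------------
    pair = essanalysis.compare_point_to_point(prof_ccm, prof_mcm,
                                              threshold=config.delta_threshold_pa)
    strata = essanalysis.stratify(pair, band_edges=config.band_edges_pa)
    report["stages"]["ccm_vs_mcm"] = {
        "n_pairs": pair.n_pairs,
        "n_excluded": len(pair.excluded),
        "exceedance_fraction": pair.exceedance_fraction(),
        "threshold_pa": config.delta_threshold_pa,
        "strata": strata.to_frame().to_dict(orient="list"),
        "outflow_ccm_mls": flow_ccm.per_vessel_mls,
        "outflow_mcm_mls": flow_mcm.per_vessel_mls,
        "total_outflow_ccm_mls": flow_ccm.total_mls,
        "total_outflow_mcm_mls": flow_mcm.total_mls,
        "mass_error_ccm": flow_ccm.mass_error(),
        "periodicity_residual_ccm": res_ccm.periodicity_residual,
    }

    # --- LAD ablation series --------------------------------------------
    trunk = config.stenosis_segment
    lad_full = geomkit.extract_subtree(recon, trunk)
    branch_names = [s.name for s in lad_full.segments if s.name != trunk]
    branch_order = sorted(
        branch_names,
        key=lambda n: lad_full.segment(n).parent_arclength_fraction)
    # inflow matched to the flow entering the trunk in the complete model
    q_trunk = sum(q for label, q in flow_ccm.per_outlet_mls.items()
                  if label == trunk or label in branch_names)
    r_ost = float(lad_full.segment(trunk).radii[0])
    v_match = (q_trunk * 1e-6) / (np.pi * (r_ost * 1e-3) ** 2)
    series = {}
    for k in config.lad_series:
        keep = branch_order[:k]
        drop = [n for n in branch_order if n not in keep]
        tree_k = geomkit.prune(lad_full, geomkit.PruneSpec.remove(*drop)) \
            if drop else lad_full
        _, prof_k, res_k, _ = simulate_tree(
            tree_k, config, mean_velocity=v_match,
            total_flow_mls=q_trunk)
        flow_k = essanalysis.outflow_report(res_k.flows_mls, res_k.flow_times,
                                            tree_k, res_k.inlet_flow_mls)
        series[f"LAD{k}"] = {
            "trunk_mean_taess_pa": _trunk_mean_taess(prof_k, trunk),
            "outflow_mls": flow_k.per_outlet_mls,
            "inlet_flow_mls": float(np.mean(res_k.inlet_flow_mls)),
        }
    report["stages"]["lad_series"] = {
        "matched_inflow_mls": q_trunk,
        "matched_mean_velocity_ms": v_match,
        "models": series,
    }

    blob = json.dumps(report, sort_keys=True, default=_json_default, indent=1)
    report["checksum"] = hashlib.sha256(blob.encode()).hexdigest()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, default=_json_default, indent=1)
    return report


# ---------------------------------------------------------------------------
# the branch-ablation experiment (LAD 3 -> 0 side branches)
# ---------------------------------------------------------------------------

def lad_ablation_tree(trunk_len: float = 45.0, d_prox: float = 3.2,
                      d_dist: float = 1.1,
                      branch_fracs=(0.20, 0.32, 0.45),
                      d_branch_ost: float = 2.0, d_branch_dist: float = 1.5,
                      branch_len: float = 14.0, sten_frac: float = 0.12,
                      sten_len: float = 5.0, severity: float = 0.5) -> vasctree.VesselTree:
    """The canonical stenosed LAD-with-side-branches anatomy used for the
    ablation study: a tapering trunk with a proximal stenosis and three
    proximal-to-mid diagonal branches sized so the branches carry the
    physiologic majority of the ostial inflow (the distal LAD of a real
    left coronary tree is largely drained by its side branches)."""
    n = int(trunk_len) + 1
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, trunk_len, n)])
    radii = np.linspace(d_prox / 2, d_dist / 2, n)
    segs = [vasctree.VesselSegment(0, "LAD", pts, radii)]
    for k, frac in enumerate(branch_fracs):
        z0 = frac * trunk_len
        a = np.deg2rad(50.0)
        dir_ = np.array([np.sin(a) * np.cos(k * 2.1),
                         np.sin(a) * np.sin(k * 2.1), np.cos(a)])
        bpts = np.array([0.0, 0.0, z0]) + np.outer(
            np.linspace(0, branch_len, 15), dir_)
        br = np.linspace(d_branch_ost / 2, d_branch_dist / 2, 15)
        segs.append(vasctree.VesselSegment(k + 1, f"Diag{k+1}", bpts, br,
                                           parent_id=0,
                                           parent_arclength_fraction=frac))
    tree = vasctree.VesselTree(segs, 0)
    if severity > 0:
        tree = vasctree.apply_stenosis(
            tree, vasctree.StenosisSpec("LAD", sten_frac, sten_len, severity))
    return tree


def predicted_trunk_taess(tree: vasctree.VesselTree, q_in: float,
                          aortic_pressure: float = 90.0 * lbmflow.MMHG_PA,
                          mu: float = 0.004) -> float:
    """0D (Poiseuille network) prediction of the trunk-averaged wall shear:
    tau(s) = 4 mu Q(s) / (pi r(s)^3) with Q(s) from the resistor network.
    The fast design-stage counterpart of the 3D ablation result."""
    outs = lbmflow.assign_resistances(tree, aortic_pressure, q_in)
    flows = lbmflow.poiseuille_network_flows(tree, outs, q_in, mu=mu)
    seg = tree.segment("LAD")
    arc = vasctree.polyline_arclength(seg.points)
    s_grid = np.linspace(0, arc[-1], 200)
    q = np.full_like(s_grid, q_in)
    for c in tree.children_of(seg.id):
        s_att = c.parent_arclength_fraction * arc[-1]
        q[s_grid > s_att] -= flows[c.name]
    r = np.interp(s_grid, arc, seg.radii) * 1e-3
    tau = 4 * mu * (q / (np.pi * r ** 2)) / r
    return float(tau.mean())


def run_branch_ablation(voxel_mm: float = 0.3, period_s: float = 0.12,
                        n_cycles: int = 2, mean_velocity: float = 0.25,
                        u_max_phys: float = 3.0, total_flow_mls: float = 2.0,
                        samples_per_cycle: int = 16,
                        series=(3, 2, 1, 0), tree=None) -> dict:
    """Pulsatile LBM runs of the LAD ablation series at matched inflow.

    All models share the same inlet velocity (the inflow at the LAD ostium
    of the complete model, per the matched-inflow protocol); side branches
    are removed one by one, most distal first.  Returns per-model
    trunk-averaged TAESS, outflow per outlet, and mass balance."""
    tree = tree if tree is not None else lad_ablation_tree()
    branch_names = sorted((s.name for s in tree.segments if s.name != "LAD"),
                          key=lambda n: tree.segment(n).parent_arclength_fraction)
    cfg = RunConfig(voxel_mm=voxel_mm, inlet_mode="pulsatile",
                    mean_velocity=mean_velocity, period_s=period_s,
                    n_cycles=n_cycles, u_max_phys=u_max_phys,
                    total_flow_mls=total_flow_mls,
                    samples_per_cycle=samples_per_cycle)
    out = {"models": {}, "predicted_0d": {}}
    q_in = mean_velocity * np.pi * (tree.segment("LAD").radii[0] * 1e-3) ** 2
    for k in series:
        drop = branch_names[k:]
        tree_k = geomkit.prune(tree, geomkit.PruneSpec.remove(*drop)) \
            if drop else tree
        _, prof_k, res_k, _ = simulate_tree(tree_k, cfg)
        flow_k = essanalysis.outflow_report(res_k.flows_mls, res_k.flow_times,
                                            tree_k, res_k.inlet_flow_mls)
        out["models"][f"LAD{k}"] = {
            "trunk_mean_taess_pa": _trunk_mean_taess(prof_k, "LAD"),
            "outflow_mls": flow_k.per_outlet_mls,
            "trunk_outflow_mls": flow_k.per_outlet_mls.get("LAD"),
            "inlet_flow_mls": float(np.mean(res_k.inlet_flow_mls)),
            "mass_error": flow_k.mass_error(),
            "periodic": res_k.periodic,
        }
        out["predicted_0d"][f"LAD{k}"] = predicted_trunk_taess(tree_k, q_in)
    return out


# ---------------------------------------------------------------------------
# Hausdorff identification matrix
# ---------------------------------------------------------------------------

def _perturb_tree(tree: vasctree.VesselTree, sd_mm: float, seed: int):
    rng = np.random.default_rng(seed)
    out = tree.copy()
    for seg in out.segments:
        n = len(seg.points)
        # smooth correlated jitter so the copy stays vessel-like
        raw = rng.normal(0.0, sd_mm, (n, 3))
        k = np.ones(5) / 5.0
        for c in range(3):
            raw[:, c] = np.convolve(raw[:, c], k, mode="same")
        seg.points = seg.points + raw
    return out


def run_hd_matrix(n_trees: int = 5, perturb_sd_mm: float = 0.4, seed: int = 0,
                  tree_scale: float = 0.35, n_samples: int = 3000) -> dict:
    """Cross-compare ``n_trees`` synthetic trees against perturbed copies
    (the 'second modality' stand-ins) by symmetric Hausdorff distance.

    Returns the HD matrix and the fraction of rows whose minimum lies on
    the diagonal (1.0 = every model matched to its own counterpart)."""
    if n_trees < 3:
        raise ValueError("need at least 3 trees")
    params = vasctree.TreeParams(scale=tree_scale, n_diagonals=2, n_marginals=1)
    trees = [vasctree.generate_tree("left", params, seed=seed + 10 * i)
             for i in range(n_trees)]
    meshes = [geomkit.loft_mesh(t) for t in trees]
    perturbed = [geomkit.loft_mesh(_perturb_tree(t, perturb_sd_mm, seed + 999 + i))
                 for i, t in enumerate(trees)]
    hd = np.zeros((n_trees, n_trees))
    for i in range(n_trees):
        for j in range(n_trees):
            hd[i, j] = geomkit.hausdorff(meshes[i], perturbed[j],
                                         n_samples=n_samples, seed=seed)
    diag_min = np.argmin(hd, axis=1) == np.arange(n_trees)
    return {"hd_matrix_mm": hd, "diagonal_dominance": float(diag_min.mean()),
            "n_trees": n_trees, "perturb_sd_mm": perturb_sd_mm}
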