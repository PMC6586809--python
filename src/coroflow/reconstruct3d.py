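"""3D vessel reconstruction from a pair of 2D angiographic projections.

Given two labeled centerline projections and the C-arm gantry geometry,
the reconstruction (i) matches centerline points across views along
epipolar lines with an order-preserving dynamic program, (ii)
triangulates each matched pair as the midpoint of the common
perpendicular between the two back-projected rays, and (iii) recovers
cross-sectional radii from the projected vessel widths and the local
cone-beam magnification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .vasctree import (GantryGeometry, GantryView, VesselSegment, VesselTree,
                       ViewProjection)

__all__ = [
    "EpipolarMatch",
    "ReconstructionReport",
    "correspond_points",
    "triangulate",
    "recover_diameters",
    "reconstruct",
    "evaluate_reconstruction",
]


@dataclass
class EpipolarMatch:
    """Order-preserving point correspondences for one segment."""

    label: str
    segment_id: int
    pairs: np.ndarray        # (M, 2) int: index in view A, index in view B
    residuals_px: np.ndarray  # (M,) epipolar residual of each pair
    parent_id: int | None = None
    parent_arclength_fraction: float = 0.0

    def validate(self) -> None:
        if np.any(self.residuals_px < 0):
            raise ValueError("epipolar residuals must be >= 0")
        if np.any(np.diff(self.pairs[:, 0]) <= 0) or np.any(np.diff(self.pairs[:, 1]) <= 0):
            raise ValueError("matches must be strictly increasing in both views")


@dataclass
class ReconstructionReport:
    per_segment_rmse_mm: dict
    per_segment_diameter_mae_mm: dict
    n_matched_points: dict
    rmse_mm: float = 0.0
    diameter_mae_mm: float = 0.0


# ---------------------------------------------------------------------------
# epipolar residuals
# ---------------------------------------------------------------------------

def _epipolar_residual_matrix(view_a: GantryView, view_b: GantryView,
                              pts_a: np.ndarray, pts_b: np.ndarray) -> np.ndarray:
    """res[i, j]: pixel distance in view B from point j to the epipolar line
    of view-A point i."""
    n_a = len(pts_a)
    lines = np.empty((n_a, 3))  # line coefficients (a, b, c): a*u + b*v + c = 0
    for i in range(n_a):
        origin, d = view_a.backproject_ray(pts_a[i])
        p1, _ = view_b.project_points(origin + 0.2 * view_a.sod_mm * d)
        p2, _ = view_b.project_points(origin + 1.8 * view_a.sod_mm * d)
        p1, p2 = p1[0], p2[0]
        a, b = p2[1] - p1[1], p1[0] - p2[0]
        norm = np.hypot(a, b)
        if norm < 1e-12:
            a, b, norm = 1.0, 0.0, 1.0
        lines[i] = (a / norm, b / norm, -(a * p1[0] + b * p1[1]) / norm)
    u, v = pts_b[:, 0], pts_b[:, 1]
    return np.abs(lines[:, 0, None] * u[None, :]
                  + lines[:, 1, None] * v[None, :]
                  + lines[:, 2, None])


def _monotone_dp(cost: np.ndarray) -> np.ndarray:
    """Monotone (DTW-style) alignment through a cost matrix; returns the
    strictly-increasing matched pairs (the diagonal moves of the optimal
    path)."""
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    move = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up (i-1), 2 left (j-1)
    acc[0, 0] = cost[0, 0]
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        move[i, 0] = 1
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        move[0, j] = 2
    for i in range(1, n):
        row_prev, row = acc[i - 1], acc[i]
        for j in range(1, m):
            best = row_prev[j - 1]; mv = 0
            if row_prev[j] < best:
                best = row_prev[j]; mv = 1
            if row[j - 1] < best:
                best = row[j - 1]; mv = 2
            row[j] = best + cost[i, j]
            move[i, j] = mv
    # backtrack
    pairs = []
    i, j = n - 1, m - 1
    pairs.append((i, j))
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
            pairs.append((i, j))
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    pairs = np.array(pairs[::-1], dtype=int)
    # keep strictly increasing pairs in both indices
    keep = np.ones(len(pairs), dtype=bool)
    last = (-1, -1)
    for k, (a, b) in enumerate(pairs):
        if a <= last[0] or b <= last[1]:
            keep[k] = False
        else:
            last = (a, b)
    return pairs[keep]


def correspond_points(proj_a: ViewProjection, proj_b: ViewProjection,
                      gantry: GantryGeometry) -> list[EpipolarMatch]:
    """Match centerline points across the two views, per labeled segment.

    Uses dynamic programming over monotone (order-preserving) alignments
    with the epipolar residual as pointwise cost.  Segments visible in
    only one view are excluded with a warning, mirroring the exclusion of
    vessels not identifiable in both angiograms.
    """
    gantry.validate()
    view_a, view_b = gantry.views()
    labels_a = set(proj_a.labels())
    labels_b = set(proj_b.labels())
    only = labels_a.symmetric_difference(labels_b)
    if only:
        warnings.warn(f"segments visible in only one view excluded: {sorted(only)}")
    matches = []
    for label in [s.name for s in proj_a.segments if s.name in labels_b]:
        sa, sb = proj_a.segment(label), proj_b.segment(label)
        cost = _epipolar_residual_matrix(view_a, view_b, sa.points_px, sb.points_px)
        pairs = _monotone_dp(cost)
        res = cost[pairs[:, 0], pairs[:, 1]]
        m = EpipolarMatch(label=label, segment_id=sa.segment_id, pairs=pairs,
                          residuals_px=res, parent_id=sa.parent_id,
                          parent_arclength_fraction=sa.parent_arclength_fraction)
        m.validate()
        matches.append(m)
    return matches


# ---------------------------------------------------------------------------
# triangulation
# ---------------------------------------------------------------------------

def ray_midpoint(o1, d1, o2, d2, min_angle_deg: float = 1.0):
    """Midpoint of the common perpendicular between two rays, and the
    miss distance between them.  Raises for near-parallel rays."""
    d1 = np.asarray(d1) / np.linalg.norm(d1)
    d2 = np.asarray(d2) / np.linalg.norm(d2)
    cosang = abs(float(d1 @ d2))
    if cosang > np.cos(np.deg2rad(min_angle_deg)):
        raise ValueError("rays nearly parallel; triangulation ill-conditioned")
    r = np.asarray(o2) - np.asarray(o1)
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ r, d2 @ r
    denom = a * c - b * b
    t1 = (d * c - b * e) / denom
    t2 = (b * d - a * e) / denom
    p1 = o1 + t1 * d1
    p2 = o2 + t2 * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def triangulate(matches: list[EpipolarMatch], gantry: GantryGeometry,
                proj_a: ViewProjection, proj_b: ViewProjection) -> VesselTree:
    """Back-project each matched pixel pair and intersect the rays.

    Returns a centerline-only tree (placeholder radii of 1 mm); the
    per-point triangulation gap (ray miss distance, mm) is retained on
    the tree as ``triangulation_gaps``.  Near-parallel pairs are
    interpolated from their neighbors rather than triangulated.
    """
    view_a, view_b = gantry.views()
    segs, gaps = [], {}
    for m in matches:
        sa, sb = proj_a.segment(m.label), proj_b.segment(m.label)
        pts3 = np.zeros((len(m.pairs), 3))
        gap = np.zeros(len(m.pairs))
        bad = []
        for k, (i, j) in enumerate(m.pairs):
            o1, d1 = view_a.backproject_ray(sa.points_px[i])
            o2, d2 = view_b.backproject_ray(sb.points_px[j])
            try:
                pts3[k], gap[k] = ray_midpoint(o1, d1, o2, d2)
            except ValueError:
                bad.append(k)
        if bad:
            good = np.setdiff1d(np.arange(len(m.pairs)), bad)
            if len(good) < 2:
                warnings.warn(f"segment {m.label}: too few well-conditioned rays; dropped")
                continue
            for axis in range(3):
                pts3[bad, axis] = np.interp(bad, good, pts3[good, axis])
            gap[bad] = np.interp(bad, good, gap[good])
        segs.append(VesselSegment(
            id=m.segment_id, name=m.label, points=pts3,
            radii=np.ones(len(pts3)), parent_id=m.parent_id,
            parent_arclength_fraction=m.parent_arclength_fraction))
        gaps[m.label] = gap
    roots = [s for s in segs if s.parent_id is None]
    if len(roots) != 1:
        raise ValueError("reconstruction did not yield exactly one root segment")
    tree = VesselTree(segments=segs, root_segment_id=roots[0].id)
    tree.triangulation_gaps = gaps  # type: ignore[attr-defined]
    return tree


def recover_diameters(tree: VesselTree, proj_a: ViewProjection,
                      proj_b: ViewProjection, gantry: GantryGeometry,
                      matches: list[EpipolarMatch],
                      disagreement_warn: float = 0.05) -> VesselTree:
    """Fill radii from projected widths and the reconstructed depth.

    radius = width_px * pixel_mm * depth / (2 * SID), averaged over the
    two views; view disagreement beyond ``disagreement_warn`` (fractional)
    is logged via ``warnings``.
    """
    view_a, view_b = gantry.views()
    out = tree.copy()
    by_label = {m.label: m for m in matches}
    for seg in out.segments:
        m = by_label[seg.name]
        sa, sb = proj_a.segment(seg.name), proj_b.segment(seg.name)
        wa = sa.widths_px[m.pairs[:, 0]]
        wb = sb.widths_px[m.pairs[:, 1]]
        if np.any(wa <= 0) or np.any(wb <= 0):
            raise ValueError(f"segment {seg.name}: nonpositive projected width")
        depth_a = (seg.points - view_a.source) @ view_a.axis
        depth_b = (seg.points - view_b.source) @ view_b.axis
        ra = wa * view_a.pixel_mm * depth_a / (2.0 * view_a.sid_mm)
        rb = wb * view_b.pixel_mm * depth_b / (2.0 * view_b.sid_mm)
        rel = np.abs(ra - rb) / np.maximum(0.5 * (ra + rb), 1e-12)
        if np.any(rel > disagreement_warn):
            warnings.warn(
                f"segment {seg.name}: view radius disagreement up to "
                f"{rel.max() * 100:.1f}% (mean of views used)")
        seg.radii = 0.5 * (ra + rb)
    return out


def reconstruct(proj_a: ViewProjection, proj_b: ViewProjection,
                gantry: GantryGeometry) -> VesselTree:
    """Full reconstruction: correspond, triangulate, recover diameters."""
    matches = correspond_points(proj_a, proj_b, gantry)
    skel = triangulate(matches, gantry, proj_a, proj_b)
    return recover_diameters(skel, proj_a, proj_b, gantry, matches)


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

def evaluate_reconstruction(recon: VesselTree, truth: VesselTree,
                            n_resample: int = 200) -> ReconstructionReport:
    """Per-segment centerline RMSE and diameter MAE after arclength
    resampling to common points.  Requires matching segment labels."""
    from .vasctree import resample_polyline

    labels_r = {s.name for s in recon.segments}
    labels_t = {s.name for s in truth.segments}
    missing = sorted(labels_r.symmetric_difference(labels_t))
    if missing:
        raise ValueError(f"segment labels do not match: {missing}")
    rmse, dmae, npts = {}, {}, {}
    sq_all, ad_all, n_all = 0.0, 0.0, 0
    for st in truth.segments:
        sr = recon.segment(st.name)
        pr, rr = resample_polyline(sr.points, sr.radii, n_resample)
        pt, rt = resample_polyline(st.points, st.radii, n_resample)
        sq = np.sum((pr - pt) ** 2, axis=1)
        rmse[st.name] = float(np.sqrt(sq.mean()))
        dmae[st.name] = float(np.abs(2 * rr - 2 * rt).mean())
        npts[st.name] = len(sr.points)
        sq_all += sq.sum(); ad_all += np.abs(2 * rr - 2 * rt).sum(); n_all += n_resample
    return ReconstructionReport(
        per_segment_rmse_mm=rmse, per_segment_diameter_mae_mm=dmae,
        n_matched_points=npts,
        rmse_mm=float(np.sqrt(sq_all / n_all)),
        diameter_mae_mm=float(ad_all / n_all))
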