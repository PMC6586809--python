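"""Synthetic coronary artery trees and their biplane angiographic projection.

The tree generator is the stand-in for patient imaging: it emits left
(LM -> LAD/LCx with diagonal and obtuse-marginal branches) or right (RCA
trunk with marginal/PDA branches) coronary centerline trees with
anatomical tapering, side branches above the 1 mm inclusion threshold,
and optional focal stenoses.  The projection operator images a tree onto
two C-arm gantry views with a cone-beam (perspective) model.

Coordinates are millimetres in a right-handed patient frame
(x = patient left, y = anterior, z = cranial); the gantry isocenter is
the world origin.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "VesselSegment",
    "VesselTree",
    "StenosisSpec",
    "TreeParams",
    "GantryView",
    "GantryGeometry",
    "ProjectedSegment",
    "ViewProjection",
    "generate_tree",
    "apply_stenosis",
    "project_tree",
    "degrade_projection",
    "polyline_arclength",
    "resample_polyline",
]

MIN_SIDE_BRANCH_DIAMETER_MM = 1.0  # inclusion rule: side branches > 1 mm


# ---------------------------------------------------------------------------
# polyline helpers
# ---------------------------------------------------------------------------

def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength (mm) along an (N, 3) polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, radii: np.ndarray, n: int):
    """Resample a polyline (and per-point radii) to ``n`` arclength-uniform points."""
    s = polyline_arclength(points)
    t = np.linspace(0.0, s[-1], n)
    new_pts = np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])
    new_r = np.interp(t, s, radii)
    return new_pts, new_r


def _tangents(points: np.ndarray) -> np.ndarray:
    d = np.gradient(points, axis=0)
    n = np.linalg.norm(d, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return d / n


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """One vessel segment: an ordered 3D centerline with per-point radii.

    ``parent_arclength_fraction`` locates the ostium on the parent's
    centerline as a fraction of the parent's total arclength.
    """

    id: int
    name: str
    points: np.ndarray          # (N, 3) mm
    radii: np.ndarray           # (N,) mm
    parent_id: Optional[int] = None
    parent_arclength_fraction: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)

    @property
    def length(self) -> float:
        return float(polyline_arclength(self.points)[-1])

    def arclength(self) -> np.ndarray:
        return polyline_arclength(self.points)

    def tangents(self) -> np.ndarray:
        return _tangents(self.points)

    def validate(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"segment {self.name}: points must be (N, 3)")
        if len(self.points) < 2:
            raise ValueError(f"segment {self.name}: polyline needs >= 2 points")
        if len(self.radii) != len(self.points):
            raise ValueError(f"segment {self.name}: len(radii) != len(points)")
        step = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(step <= 0):
            raise ValueError(f"segment {self.name}: consecutive points must be distinct")
        if np.any(self.radii <= 0):
            raise ValueError(f"segment {self.name}: all radii must be > 0")


@dataclass
class StenosisSpec:
    """A focal stenosis: smooth diameter reduction centered on a segment.

    ``severity`` is the fractional diameter reduction in (0, 1); e.g. 0.5
    halves the local diameter (75% area reduction) at the lesion center.
    """

    segment: str                      # segment name
    center_arclength_fraction: float  # in (0, 1)
    length_mm: float
    severity: float

    def validate(self) -> None:
        if not (0.0 <= self.severity < 1.0):
            raise ValueError(f"stenosis severity must be in [0, 1), got {self.severity}")
        if self.length_mm <= 0:
            raise ValueError("stenosis length must be > 0")
        if not (0.0 < self.center_arclength_fraction < 1.0):
            raise ValueError("stenosis center fraction must be in (0, 1)")


@dataclass
class VesselTree:
    """Rooted tree of vessel segments; the inlet is the root's first point."""

    segments: list[VesselSegment]
    root_segment_id: int
    units: str = "mm"
    stenoses: list[StenosisSpec] = field(default_factory=list)

    # -- lookup ------------------------------------------------------------
    def segment(self, key) -> VesselSegment:
        for s in self.segments:
            if s.id == key or s.name == key:
                return s
        raise KeyError(f"no segment {key!r}")

    def has_segment(self, name: str) -> bool:
        return any(s.name == name for s in self.segments)

    @property
    def root(self) -> VesselSegment:
        return self.segment(self.root_segment_id)

    def children_of(self, seg_id: int) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent_id == seg_id]

    def terminal_segments(self) -> list[VesselSegment]:
        """Segments whose distal end is an open outlet (no child continues
        from the very end of the centerline; mid-segment side branches do
        not close a segment's own outlet)."""
        continued = {s.parent_id for s in self.segments
                     if s.parent_id is not None and s.parent_arclength_fraction >= 0.999}
        return [s for s in self.segments if s.id not in continued]

    def n_outlets(self) -> int:
        return len(self.terminal_segments())

    def total_length(self) -> float:
        return float(sum(s.length for s in self.segments))

    def ostium_point(self, seg: VesselSegment) -> np.ndarray:
        """World position of a segment's attachment on its parent."""
        parent = self.segment(seg.parent_id)
        s = parent.arclength()
        t = seg.parent_arclength_fraction * s[-1]
        return np.array([np.interp(t, s, parent.points[:, k]) for k in range(3)])

    # -- invariants --------------------------------------------------------
    def validate(self, check_taper: bool = True) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        roots = [s for s in self.segments if s.parent_id is None]
        if len(roots) != 1 or roots[0].id != self.root_segment_id:
            raise ValueError("tree must have exactly one root segment")
        for s in self.segments:
            s.validate()
            if s.parent_id is not None:
                self.segment(s.parent_id)  # parent must exist
                if not (0.0 <= s.parent_arclength_fraction <= 1.0):
                    raise ValueError(f"segment {s.name}: attachment fraction out of [0,1]")
                if 2 * s.radii[0] <= MIN_SIDE_BRANCH_DIAMETER_MM:
                    raise ValueError(
                        f"segment {s.name}: ostial diameter {2 * s.radii[0]:.2f} mm "
                        f"violates the > {MIN_SIDE_BRANCH_DIAMETER_MM} mm side-branch rule"
                    )
        self._check_acyclic()
        if check_taper:
            self._check_taper()

    def _check_acyclic(self) -> None:
        for s in self.segments:
            seen = {s.id}
            cur = s
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise ValueError("cycle in segment parenthood")
                seen.add(cur.parent_id)
                cur = self.segment(cur.parent_id)

    def _check_taper(self, tol: float = 1e-9) -> None:
        """Radii non-increasing along each segment outside declared stenosis zones."""
        for s in self.segments:
            arc = s.arclength()
            inc = np.diff(s.radii) > tol
            if not np.any(inc):
                continue
            mid = 0.5 * (arc[:-1] + arc[1:])
            allowed = np.zeros(len(mid), dtype=bool)
            for sten in self.stenoses:
                if sten.segment != s.name:
                    continue
                c = sten.center_arclength_fraction * arc[-1]
                lo, hi = c - sten.length_mm / 2, c + sten.length_mm / 2
                allowed |= (mid >= lo - tol) & (mid <= hi + tol)
            if np.any(inc & ~allowed):
                raise ValueError(f"segment {s.name}: radii increase outside a stenosis zone")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": self.units,
            "root_segment_id": self.root_segment_id,
            "stenoses": [dataclasses.asdict(s) for s in self.stenoses],
            "segments": [
                {
                    "id": s.id,
                    "name": s.name,
                    "points": s.points.tolist(),
                    "radii": s.radii.tolist(),
                    "parent_id": s.parent_id,
                    "parent_arclength_fraction": s.parent_arclength_fraction,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        segs = [
            VesselSegment(
                id=sd["id"],
                name=sd["name"],
                points=np.array(sd["points"], dtype=float),
                radii=np.array(sd["radii"], dtype=float),
                parent_id=sd.get("parent_id"),
                parent_arclength_fraction=sd.get("parent_arclength_fraction", 0.0),
            )
            for sd in d["segments"]
        ]
        stens = [StenosisSpec(**sd) for sd in d.get("stenoses", [])]
        return cls(segments=segs, root_segment_id=d["root_segment_id"],
                   units=d.get("units", "mm"), stenoses=stens)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "VesselTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def copy(self) -> "VesselTree":
        return VesselTree.from_dict(self.to_dict())

    def min_lumen_diameter(self) -> float:
        return float(min(2.0 * s.radii.min() for s in self.segments))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

@dataclass
class TreeParams:
    """Morphology parameters for the synthetic generator.

    Defaults are physiologic for adult human coronaries (lengths and
    proximal diameters in mm); side-branch ostial diameters stay above the
    1 mm inclusion threshold.  ``scale`` shrinks all lengths uniformly for
    desk-scale runs without leaving physiologic diameter ranges.
    """

    # left tree
    lm_length: float = 10.0
    lm_diameter: float = 4.5
    lad_length: float = 110.0
    lad_prox_diameter: float = 3.6
    lad_dist_diameter: float = 1.4
    lcx_length: float = 80.0
    lcx_prox_diameter: float = 3.2
    lcx_dist_diameter: float = 1.4
    n_diagonals: int = 3
    n_marginals: int = 2
    # right tree
    rca_length: float = 120.0
    rca_prox_diameter: float = 3.9
    rca_dist_diameter: float = 1.6
    n_rca_branches: int = 3
    # branches
    branch_length: float = 35.0
    branch_length_jitter: float = 0.25      # fractional
    branch_diameter_ratio: float = 0.65     # ostial diameter / local parent diameter
    branch_dist_diameter: float = 1.1
    branch_takeoff_deg: tuple = (35.0, 65.0)
    # shape
    tortuosity_mm: float = 2.0              # sd of smooth random centerline wander
    point_spacing_mm: float = 0.5
    scale: float = 1.0
    stenoses: list = field(default_factory=list)
    allow_small_branches: bool = False

    def validate(self) -> None:
        for st in self.stenoses:
            st.validate()
        ostial = self.branch_diameter_ratio * min(
            self.lad_prox_diameter, self.lcx_prox_diameter, self.rca_prox_diameter
        )
        if not self.allow_small_branches and self.branch_dist_diameter <= 0:
            raise ValueError("branch distal diameter must be > 0")


def _smooth_curve(rng, start, direction, length, wander_mm, spacing, n_ctrl=6):
    """A gently curving polyline: straight run + smooth random transverse wander."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    # keep curvature vessel-like: transverse wander bounded by segment length
    wander_mm = min(wander_mm, 0.04 * length)
    # orthonormal frame
    a = np.array([0.0, 0.0, 1.0])
    if abs(direction @ a) > 0.9:
        a = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(direction, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    t_ctrl = np.linspace(0.0, 1.0, n_ctrl)
    # zero wander at the origin so ostia stay put; taper-in at the start
    w1 = rng.normal(0.0, wander_mm, n_ctrl) * t_ctrl
    w2 = rng.normal(0.0, wander_mm, n_ctrl) * t_ctrl
    c1, c2 = CubicSpline(t_ctrl, w1), CubicSpline(t_ctrl, w2)
    n = max(int(round(length / spacing)) + 1, 8)
    t = np.linspace(0.0, 1.0, n)
    pts = (np.asarray(start)[None, :]
           + np.outer(t * length, direction)
           + np.outer(c1(t), e1) + np.outer(c2(t), e2))
    # resample to arclength-uniform spacing
    pts, _ = resample_polyline(pts, np.ones(len(pts)), n)
    return pts


def _taper_radii(points, d_prox, d_dist):
    """Linear-in-arclength radius taper from proximal to distal diameter."""
    s = polyline_arclength(points)
    frac = s / s[-1]
    return 0.5 * (d_prox + (d_dist - d_prox) * frac)


def _attach_branch(rng, tree, parent: VesselSegment, frac, name, seg_id, params: TreeParams):
    arc = parent.arclength()
    t = frac * arc[-1]
    origin = np.array([np.interp(t, arc, parent.points[:, k]) for k in range(3)])
    r_local = float(np.interp(t, arc, parent.radii))
    d_ost = 2.0 * r_local * params.branch_diameter_ratio
    if d_ost <= MIN_SIDE_BRANCH_DIAMETER_MM and not params.allow_small_branches:
        d_ost = MIN_SIDE_BRANCH_DIAMETER_MM + 0.1
    tang = parent.tangents()
    t_hat = np.array([np.interp(t, arc, tang[:, k]) for k in range(3)])
    t_hat /= np.linalg.norm(t_hat)
    # take-off direction: rotate parent tangent by a random angle in the cone,
    # about a random azimuth in the plane normal to the tangent
    a = np.array([0.0, 0.0, 1.0])
    if abs(t_hat @ a) > 0.9:
        a = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(t_hat, a); e1 /= np.linalg.norm(e1)
    e2 = np.cross(t_hat, e1)
    theta = np.deg2rad(rng.uniform(*params.branch_takeoff_deg))
    phi = rng.uniform(0, 2 * np.pi)
    direction = (np.cos(theta) * t_hat
                 + np.sin(theta) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    length = params.branch_length * params.scale * (
        1.0 + rng.uniform(-params.branch_length_jitter, params.branch_length_jitter))
    pts = _smooth_curve(rng, origin, direction, length,
                        params.tortuosity_mm * 0.5, params.point_spacing_mm)
    d_dist = min(params.branch_dist_diameter, d_ost * 0.95)
    radii = _taper_radii(pts, d_ost, d_dist)
    tree.segments.append(VesselSegment(
        id=seg_id, name=name, points=pts, radii=radii,
        parent_id=parent.id, parent_arclength_fraction=float(frac)))


def generate_tree(template: str, params: Optional[TreeParams] = None,
                  seed: int = 0) -> VesselTree:
    """Generate a synthetic left or right coronary tree.

    Parameters
    ----------
    template : {"left", "right"}
        "left": LM bifurcating into LAD and LCx, with diagonal and
        obtuse-marginal side branches.  "right": single RCA trunk with
        side branches.
    params : TreeParams
        Morphology; ``params.stenoses`` are applied after generation.
    seed : int
        Fixes all randomness; identical seeds give bitwise-identical trees.
    """
    if template not in ("left", "right"):
        raise ValueError("template must be 'left' or 'right'")
    params = params or TreeParams()
    params.validate()
    rng = np.random.default_rng(seed)
    sc = params.scale
    tree = VesselTree(segments=[], root_segment_id=0)
    next_id = 0

    if template == "left":
        # LM: runs patient-left and slightly anterior/caudal from the ostium
        lm_dir = np.array([1.0, 0.35, -0.25])
        lm_pts = _smooth_curve(rng, [0.0, 0.0, 0.0], lm_dir, params.lm_length * sc,
                               params.tortuosity_mm * 0.3, params.point_spacing_mm)
        lm = VesselSegment(0, "LM", lm_pts,
                           _taper_radii(lm_pts, params.lm_diameter, params.lm_diameter * 0.95))
        tree.segments.append(lm)
        next_id = 1
        end = lm_pts[-1]
        # LAD: anterior and caudal; LCx: lateral and posterior
        lad_dir = np.array([0.6, 0.7, -0.8]) + rng.normal(0, 0.05, 3)
        lcx_dir = np.array([0.9, -0.5, -0.5]) + rng.normal(0, 0.05, 3)
        lad_pts = _smooth_curve(rng, end, lad_dir, params.lad_length * sc,
                                params.tortuosity_mm, params.point_spacing_mm)
        lad = VesselSegment(next_id, "LAD", lad_pts,
                            _taper_radii(lad_pts, params.lad_prox_diameter,
                                         params.lad_dist_diameter),
                            parent_id=0, parent_arclength_fraction=1.0)
        tree.segments.append(lad); next_id += 1
        lcx_pts = _smooth_curve(rng, end, lcx_dir, params.lcx_length * sc,
                                params.tortuosity_mm, params.point_spacing_mm)
        lcx = VesselSegment(next_id, "LCx", lcx_pts,
                            _taper_radii(lcx_pts, params.lcx_prox_diameter,
                                         params.lcx_dist_diameter),
                            parent_id=0, parent_arclength_fraction=1.0)
        tree.segments.append(lcx); next_id += 1
        for k in range(params.n_diagonals):
            frac = (k + 1) / (params.n_diagonals + 1) * 0.8 + 0.08
            _attach_branch(rng, tree, lad, frac, f"Diag{k+1}", next_id, params)
            next_id += 1
        for k in range(params.n_marginals):
            frac = (k + 1) / (params.n_marginals + 1) * 0.8 + 0.08
            _attach_branch(rng, tree, lcx, frac, f"OM{k+1}", next_id, params)
            next_id += 1
    else:
        rca_dir = np.array([-0.8, 0.5, -0.6])
        rca_pts = _smooth_curve(rng, [0.0, 0.0, 0.0], rca_dir, params.rca_length * sc,
                                params.tortuosity_mm, params.point_spacing_mm)
        rca = VesselSegment(0, "RCA", rca_pts,
                            _taper_radii(rca_pts, params.rca_prox_diameter,
                                         params.rca_dist_diameter))
        tree.segments.append(rca)
        next_id = 1
        names = ["Conus", "AM1", "AM2", "PDA", "PLV"]
        for k in range(params.n_rca_branches):
            frac = (k + 1) / (params.n_rca_branches + 1) * 0.85 + 0.05
            _attach_branch(rng, tree, rca, frac, names[k % len(names)], next_id, params)
            next_id += 1

    for sten in params.stenoses:
        tree = apply_stenosis(tree, sten)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# stenosis
# ---------------------------------------------------------------------------

def apply_stenosis(tree: VesselTree, spec: StenosisSpec) -> VesselTree:
    """Return a copy of ``tree`` with a cosine-bell stenosis applied.

    The diameter multiplier is 1 at the lesion edges and (1 - severity)
    at the center, C1-smooth.  Overlapping stenoses on the same region of
    one segment are rejected.
    """
    spec.validate()
    if spec.severity == 0.0:
        return tree.copy()
    out = tree.copy()
    seg = out.segment(spec.segment)
    arc = seg.arclength()
    c = spec.center_arclength_fraction * arc[-1]
    lo, hi = c - spec.length_mm / 2.0, c + spec.length_mm / 2.0
    if lo < 0 or hi > arc[-1]:
        raise ValueError("stenotic region extends outside the segment")
    for prev in out.stenoses:
        if prev.segment != spec.segment:
            continue
        pc = prev.center_arclength_fraction * arc[-1]
        plo, phi = pc - prev.length_mm / 2.0, pc + prev.length_mm / 2.0
        if max(lo, plo) < min(hi, phi):
            raise ValueError("overlapping stenoses on the same region")
    u = (arc - c) / (spec.length_mm / 2.0)
    inside = np.abs(u) <= 1.0
    factor = np.ones_like(arc)
    factor[inside] = 1.0 - spec.severity * 0.5 * (1.0 + np.cos(np.pi * u[inside]))
    seg.radii = seg.radii * factor
    out.stenoses.append(spec)
    return out


def stenosis_diameter_profile(reference_diameter, arc, spec: StenosisSpec, seg_length):
    """Closed-form diameter profile of a stenosed segment (independent of
    :func:`apply_stenosis` internals only in the sense of being evaluable
    pointwise; used as the generator's taper+stenosis law)."""
    c = spec.center_arclength_fraction * seg_length
    u = (np.asarray(arc) - c) / (spec.length_mm / 2.0)
    factor = np.where(np.abs(u) <= 1.0,
                      1.0 - spec.severity * 0.5 * (1.0 + np.cos(np.pi * u)), 1.0)
    return reference_diameter * factor


# ---------------------------------------------------------------------------
# gantry and projection
# ---------------------------------------------------------------------------

@dataclass
class GantryView:
    """One C-arm view.

    ``alpha_deg``: RAO(-)/LAO(+) rotation about the patient's long (z) axis.
    ``beta_deg``: caudal(-)/cranial(+) angulation about the transverse (x) axis.
    The beam axis at alpha = beta = 0 is +y (posterior source, anterior
    intensifier); the frame is rotated by R = Rx(beta) @ Rz(alpha)
    (axial rotation first, then sagittal angulation).
    """

    alpha_deg: float
    beta_deg: float
    sod_mm: float = 750.0        # source-to-isocenter distance
    sid_mm: float = 1000.0       # source-to-image-intensifier distance
    pixel_mm: float = 0.2
    detector_px: tuple = (1024, 1024)   # (width, height)

    def validate(self) -> None:
        if min(self.sod_mm, self.sid_mm, self.pixel_mm) <= 0:
            raise ValueError("gantry distances and pixel size must be > 0")
        if self.sid_mm < self.sod_mm:
            raise ValueError("source-detector distance must be >= source-isocenter distance")

    def rotation(self) -> np.ndarray:
        a, b = np.deg2rad(self.alpha_deg), np.deg2rad(self.beta_deg)
        rz = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        rx = np.array([[1, 0, 0], [0, np.cos(b), -np.sin(b)], [0, np.sin(b), np.cos(b)]])
        return rx @ rz

    @property
    def axis(self) -> np.ndarray:
        """Unit beam axis, source -> detector."""
        return self.rotation() @ np.array([0.0, 1.0, 0.0])

    @property
    def source(self) -> np.ndarray:
        return -self.sod_mm * self.axis

    def detector_basis(self):
        r = self.rotation()
        e_u = r @ np.array([1.0, 0.0, 0.0])     # image u: to the patient's left at AP
        e_v = r @ np.array([0.0, 0.0, -1.0])    # image v: caudal (rows grow downward)
        return e_u, e_v

    def project_points(self, pts: np.ndarray):
        """Perspective-project (N,3) mm world points; returns (N,2) pixel
        coordinates and the per-point magnification SID / axial depth."""
        pts = np.atleast_2d(np.asarray(pts, float))
        s = self.source
        rel = pts - s
        depth = rel @ self.axis
        if np.any(depth <= 0):
            raise ValueError("point behind the X-ray source")
        mag = self.sid_mm / depth
        hit = s[None, :] + rel * mag[:, None]
        center = s + self.sid_mm * self.axis
        e_u, e_v = self.detector_basis()
        u_mm = (hit - center) @ e_u
        v_mm = (hit - center) @ e_v
        w, h = self.detector_px
        px = np.column_stack([u_mm / self.pixel_mm + w / 2.0,
                              v_mm / self.pixel_mm + h / 2.0])
        return px, mag

    def backproject_ray(self, px: np.ndarray):
        """Ray (origin, unit direction) through pixel coordinate ``px``."""
        w, h = self.detector_px
        u_mm = (px[0] - w / 2.0) * self.pixel_mm
        v_mm = (px[1] - h / 2.0) * self.pixel_mm
        center = self.source + self.sid_mm * self.axis
        e_u, e_v = self.detector_basis()
        target = center + u_mm * e_u + v_mm * e_v
        d = target - self.source
        return self.source, d / np.linalg.norm(d)


@dataclass
class GantryGeometry:
    """A biplane pair of views; the two beam axes must be > 45 degrees apart."""

    view_a: GantryView
    view_b: GantryView
    min_separation_deg: float = 45.0

    def separation_deg(self) -> float:
        c = float(np.clip(self.view_a.axis @ self.view_b.axis, -1.0, 1.0))
        return float(np.rad2deg(np.arccos(c)))

    def validate(self) -> None:
        self.view_a.validate()
        self.view_b.validate()
        sep = self.separation_deg()
        if sep <= self.min_separation_deg:
            raise ValueError(
                f"view separation {sep:.1f} deg violates the required "
                f"> {self.min_separation_deg:.0f} deg angular separation between views"
            )

    def views(self):
        return (self.view_a, self.view_b)

    def to_dict(self) -> dict:
        return {"view_a": dataclasses.asdict(self.view_a),
                "view_b": dataclasses.asdict(self.view_b),
                "min_separation_deg": self.min_separation_deg}

    @classmethod
    def from_dict(cls, d) -> "GantryGeometry":
        va = {**d["view_a"]}; vb = {**d["view_b"]}
        va["detector_px"] = tuple(va["detector_px"])
        vb["detector_px"] = tuple(vb["detector_px"])
        return cls(GantryView(**va), GantryView(**vb),
                   d.get("min_separation_deg", 45.0))


@dataclass
class ProjectedSegment:
    segment_id: int
    name: str
    points_px: np.ndarray   # (N, 2)
    widths_px: np.ndarray   # (N,)
    parent_id: Optional[int]
    parent_arclength_fraction: float


@dataclass
class ViewProjection:
    """A 2D angiogram-like projection of a tree in one gantry view."""

    view_index: int
    segments: list[ProjectedSegment]
    detector_px: tuple

    def segment(self, key) -> ProjectedSegment:
        for s in self.segments:
            if s.segment_id == key or s.name == key:
                return s
        raise KeyError(f"no projected segment {key!r}")

    def labels(self) -> list[str]:
        return [s.name for s in self.segments]

    def validate(self) -> None:
        w, h = self.detector_px
        for s in self.segments:
            if np.any(s.points_px[:, 0] < 0) or np.any(s.points_px[:, 0] > w) or \
               np.any(s.points_px[:, 1] < 0) or np.any(s.points_px[:, 1] > h):
                raise ValueError(f"segment {s.name}: projected outside detector bounds")
            if np.any(s.widths_px <= 0):
                raise ValueError(f"segment {s.name}: nonpositive projected width")

    def to_dict(self) -> dict:
        return {
            "view_index": self.view_index,
            "detector_px": list(self.detector_px),
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "name": s.name,
                    "points_px": s.points_px.tolist(),
                    "widths_px": s.widths_px.tolist(),
                    "parent_id": s.parent_id,
                    "parent_arclength_fraction": s.parent_arclength_fraction,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d) -> "ViewProjection":
        segs = [ProjectedSegment(
            segment_id=sd["segment_id"], name=sd["name"],
            points_px=np.array(sd["points_px"], float),
            widths_px=np.array(sd["widths_px"], float),
            parent_id=sd.get("parent_id"),
            parent_arclength_fraction=sd.get("parent_arclength_fraction", 0.0),
        ) for sd in d["segments"]]
        return cls(view_index=d["view_index"], segments=segs,
                   detector_px=tuple(d["detector_px"]))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ViewProjection":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def project_tree(tree: VesselTree, gantry: GantryGeometry):
    """Cone-beam projection of a tree onto the two gantry views.

    Projected vessel width at each centerline point is
    2 * radius * magnification / pixel size, with magnification
    SID / (axial depth of the point from the source).
    """
    gantry.validate()
    out = []
    for vi, view in enumerate(gantry.views()):
        psegs = []
        for seg in tree.segments:
            px, mag = view.project_points(seg.points)
            widths = 2.0 * seg.radii * mag / view.pixel_mm
            psegs.append(ProjectedSegment(
                segment_id=seg.id, name=seg.name, points_px=px, widths_px=widths,
                parent_id=seg.parent_id,
                parent_arclength_fraction=seg.parent_arclength_fraction))
        proj = ViewProjection(view_index=vi, segments=psegs,
                              detector_px=view.detector_px)
        proj.validate()
        out.append(proj)
    return tuple(out)


def degrade_projection(proj: ViewProjection, centerline_sd_px: float = 0.0,
                       width_sd_px: float = 0.0, seed: int = 0) -> ViewProjection:
    """Additive Gaussian jitter on projected centerline points and widths."""
    if centerline_sd_px < 0 or width_sd_px < 0:
        raise ValueError("jitter standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    segs = []
    for s in proj.segments:
        pts = s.points_px + rng.normal(0.0, centerline_sd_px, s.points_px.shape) \
            if centerline_sd_px > 0 else s.points_px.copy()
        wid = s.widths_px + rng.normal(0.0, width_sd_px, s.widths_px.shape) \
            if width_sd_px > 0 else s.widths_px.copy()
        wid = np.maximum(wid, 0.05)
        segs.append(ProjectedSegment(s.segment_id, s.name, pts, wid,
                                     s.parent_id, s.parent_arclength_fraction))
    return ViewProjection(view_index=proj.view_index, segments=segs,
                          detector_px=proj.detector_px)
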