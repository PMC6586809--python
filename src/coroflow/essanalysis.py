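"""Reduction of wall-shear fields to endothelial shear stress (ESS) reports.

Implements the analysis protocol used to compare complete (CCM) and
branch-pruned / matched (MCM) coronary models:

* TAESS: time-averaged magnitude of the tangential wall traction over one
  cardiac cycle (trapezoidal in time),
* circumferential averaging of TAESS onto 0.3 mm centerline sections,
* 2D cylindrical (arclength x angle) ESS maps of a single vessel,
* point-to-point comparison of matched sections between two models with a
  0.5 Pa difference threshold,
* stratification into low (<1 Pa), intermediate (1-<2 Pa), high
  (2-<3 Pa) and very high (>=3 Pa) ESS bands,
* per-vessel volumetric outflow summaries,
* the statistical test suite (Kolmogorov-Smirnov normality screen, then
  Student t / Kruskal-Wallis / Friedman as appropriate).

Band boundary convention: a value exactly on a boundary goes to the
higher band (configurable via ``band_edges``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .geomkit import CenterlineSections, RigidTransform
from .lbmflow import WSSField
from .vasctree import VesselTree

__all__ = [
    "SectionProfile",
    "PairComparison",
    "StrataReport",
    "OutflowReport",
    "DEFAULT_BAND_EDGES",
    "taess",
    "circumferential_average",
    "cylindrical_map",
    "compare_point_to_point",
    "stratify",
    "outflow_report",
    "stats_suite",
]

DEFAULT_BAND_EDGES = (1.0, 2.0, 3.0)   # Pa: low | intermediate | high | very high
BAND_NAMES = ("low", "intermediate", "high", "very_high")
PRO_ATHEROGENIC_CUTOFF_PA = 2.0        # low-TAESS indicator threshold


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SectionProfile:
    """Circumferentially averaged TAESS at each centerline section."""

    labels: list                  # per-section segment label
    arclength: np.ndarray         # mm within segment
    taess: np.ndarray             # Pa (NaN where the section caught no samples)
    counts: np.ndarray            # wall samples per section
    spacing: float = 0.3

    def __len__(self) -> int:
        return len(self.taess)

    def empty_sections(self) -> np.ndarray:
        return np.where(self.counts == 0)[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"segment": self.labels, "arclength_mm": self.arclength,
                             "taess_pa": self.taess, "n_samples": self.counts})


@dataclass
class PairComparison:
    """Matched section pairs between two models (e.g. CCM vs MCM)."""

    labels: list
    arclength: np.ndarray
    ess_a: np.ndarray              # Pa, first model (CCM)
    ess_b: np.ndarray              # Pa, second model (MCM)
    threshold: float               # Pa
    excluded: list                 # (label, reason) for non-matched sections

    @property
    def delta(self) -> np.ndarray:
        return self.ess_a - self.ess_b

    @property
    def n_pairs(self) -> int:
        return len(self.ess_a)

    def exceedance_fraction(self) -> float:
        """Fraction of pairs with |difference| > threshold."""
        return float(np.mean(np.abs(self.delta) > self.threshold))


@dataclass
class StrataReport:
    band_edges: tuple
    fractions_a: np.ndarray        # per band, first model
    fractions_b: np.ndarray
    mean_delta_per_band: np.ndarray   # mean (A - B) among pairs whose A-value is in band
    band_names: tuple = BAND_NAMES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"band": self.band_names,
                             "fraction_a": self.fractions_a,
                             "fraction_b": self.fractions_b,
                             "mean_delta_pa": self.mean_delta_per_band})


@dataclass
class OutflowReport:
    per_outlet_mls: dict           # outlet label -> mean flow over final cycle
    per_vessel_mls: dict           # major vessel -> summed mean flow
    total_mls: float
    inlet_mls: float

    def mass_error(self) -> float:
        return abs(self.total_mls - self.inlet_mls) / max(self.inlet_mls, 1e-12)


# ---------------------------------------------------------------------------
# TAESS
# ---------------------------------------------------------------------------

def taess(wss: WSSField, period: Optional[float] = None,
          tol: float = 0.05) -> np.ndarray:
    """Per-sample time average of |tangential traction| over one cycle.

    The samples must span exactly one period (trapezoidal rule end to
    end); raises if the record covers less than that."""
    t = wss.times
    if len(t) < 2:
        raise ValueError("need at least two time samples")
    span = t[-1] - t[0]
    if period is not None and abs(span - period) > tol * period:
        raise ValueError(f"samples span {span:.4f} s, not one full cycle "
                         f"({period:.4f} s)")
    mag = wss.magnitudes()          # (n_t, n)
    return np.trapezoid(mag, t, axis=0) / span


# ---------------------------------------------------------------------------
# sectioning
# ---------------------------------------------------------------------------

def _assign_sections(positions_mm, labels, tree: VesselTree,
                     sections: CenterlineSections):
    """Index of the owning section for each wall sample: nearest section of
    the sample's own segment (by projection onto that centerline)."""
    sec_idx = np.full(len(positions_mm), -1, dtype=int)
    labels = np.asarray(labels)
    for name in set(sections.labels):
        s_mask = np.where(labels == name)[0]
        if len(s_mask) == 0:
            continue
        sec_ids = sections.for_segment(name)
        kd = cKDTree(sections.points[sec_ids])
        _, j = kd.query(positions_mm[s_mask])
        sec_idx[s_mask] = sec_ids[j]
    return sec_idx


def circumferential_average(taess_samples: np.ndarray, positions_mm: np.ndarray,
                            sample_labels, tree: VesselTree,
                            sections: CenterlineSections) -> SectionProfile:
    """Arithmetic mean of the wall-sample TAESS within each 0.3 mm section.

    Samples are assigned to the nearest section of their owning segment;
    sections that catch no samples are flagged (NaN), not dropped."""
    idx = _assign_sections(positions_mm, sample_labels, tree, sections)
    n = len(sections)
    sums = np.bincount(idx[idx >= 0], weights=taess_samples[idx >= 0], minlength=n)
    counts = np.bincount(idx[idx >= 0], minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    return SectionProfile(labels=list(sections.labels),
                          arclength=sections.arclength.copy(),
                          taess=mean, counts=counts, spacing=sections.spacing)


def _transport_frames(points: np.ndarray, tangents: np.ndarray) -> np.ndarray:
    """Parallel-transport a reference normal along a centerline; returns
    (n, 3) unit normals continuous along the curve."""
    n = len(points)
    normals = np.zeros((n, 3))
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normals[0] = np.cross(t0, ref)
    normals[0] /= np.linalg.norm(normals[0])
    for i in range(1, n):
        v = np.cross(tangents[i - 1], tangents[i])
        s = np.linalg.norm(v)
        c = float(np.clip(tangents[i - 1] @ tangents[i], -1, 1))
        if s < 1e-12:
            normals[i] = normals[i - 1]
        else:
            v = v / s
            ang = np.arctan2(s, c)
            nn = normals[i - 1]
            normals[i] = (nn * np.cos(ang) + np.cross(v, nn) * np.sin(ang)
                          + v * (v @ nn) * (1 - np.cos(ang)))
        normals[i] -= (normals[i] @ tangents[i]) * tangents[i]
        normals[i] /= np.linalg.norm(normals[i])
    return normals


def cylindrical_map(taess_samples: np.ndarray, positions_mm: np.ndarray,
                    sample_labels, tree: VesselTree, segment: str,
                    sections: CenterlineSections, n_theta: int = 24):
    """2D (arclength x circumferential angle) ESS map of one vessel.

    The angular reference is parallel-transported along the centerline so
    the map is continuous; empty bins are filled by nearest-neighbor
    interpolation and reported in the returned mask."""
    sample_labels = np.asarray(sample_labels)
    sel = np.where(sample_labels == segment)[0]
    if len(sel) == 0:
        raise ValueError(f"no wall samples on segment {segment!r}")
    sec_ids = sections.for_segment(segment)
    pts = sections.points[sec_ids]
    tans = sections.tangents[sec_ids]
    normals = _transport_frames(pts, tans)
    binormals = np.cross(tans, normals)
    kd = cKDTree(pts)
    _, row = kd.query(positions_mm[sel])
    rel = positions_mm[sel] - pts[row]
    x = np.sum(rel * normals[row], axis=1)
    y = np.sum(rel * binormals[row], axis=1)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    col = np.minimum((theta / (2 * np.pi) * n_theta).astype(int), n_theta - 1)
    n_s = len(sec_ids)
    sums = np.zeros((n_s, n_theta))
    cnts = np.zeros((n_s, n_theta))
    np.add.at(sums, (row, col), taess_samples[sel])
    np.add.at(cnts, (row, col), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = sums / cnts
    empty = cnts == 0
    if empty.any() and (~empty).any():
        fi, fj = np.where(~empty)
        ei, ej = np.where(empty)
        kd2 = cKDTree(np.column_stack([fi, fj]))
        _, jn = kd2.query(np.column_stack([ei, ej]))
        grid[ei, ej] = grid[fi[jn], fj[jn]]
    s_axis = sections.arclength[sec_ids]
    theta_axis = (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
    return grid, s_axis, theta_axis, empty


# ---------------------------------------------------------------------------
# CCM / MCM comparison
# ---------------------------------------------------------------------------

def compare_point_to_point(ccm: SectionProfile, mcm: SectionProfile,
                           threshold: float = 0.5,
                           transform: Optional[RigidTransform] = None) -> PairComparison:
    """Match sections by (segment label, arclength index) and compare ESS.

    Sections present only in the complete model (pruned-away branches or
    truncated lengths) are excluded and listed with reasons; empty
    sections on either side are excluded too.  ``transform`` documents an
    optional rigid pre-alignment of the models (geometry matching is by
    label and arclength, so the transform does not alter pairing)."""
    if abs(ccm.spacing - mcm.spacing) > 1e-9:
        raise ValueError("profiles must be sectioned at the same spacing")
    key_b = {}
    for i, (lab, s) in enumerate(zip(mcm.labels, mcm.arclength)):
        key_b[(lab, int(round(s / mcm.spacing)))] = i
    labels, arcs, ea, eb, excluded = [], [], [], [], []
    for i, (lab, s) in enumerate(zip(ccm.labels, ccm.arclength)):
        j = key_b.get((lab, int(round(s / ccm.spacing))))
        if j is None:
            excluded.append((lab, float(s), "absent in matched model"))
            continue
        if not np.isfinite(ccm.taess[i]) or not np.isfinite(mcm.taess[j]):
            excluded.append((lab, float(s), "empty section"))
            continue
        labels.append(lab); arcs.append(s)
        ea.append(ccm.taess[i]); eb.append(mcm.taess[j])
    if not ea:
        raise ValueError("no common sections between the two profiles")
    return PairComparison(labels=labels, arclength=np.array(arcs),
                          ess_a=np.array(ea), ess_b=np.array(eb),
                          threshold=threshold, excluded=excluded)


def stratify(pair: PairComparison,
             band_edges: Sequence[float] = DEFAULT_BAND_EDGES) -> StrataReport:
    """Fraction of sections per ESS band for each model, and the mean
    (A - B) difference per band.  Boundary values go to the higher band;
    values >= the last edge are 'very high'."""
    if pair.n_pairs == 0:
        raise ValueError("empty pair comparison")
    edges = np.asarray(band_edges, float)

    def fractions(x):
        band = np.searchsorted(edges, x, side="right")
        return np.bincount(band, minlength=len(edges) + 1) / len(x)

    fa = fractions(pair.ess_a)
    fb = fractions(pair.ess_b)
    band_a = np.searchsorted(edges, pair.ess_a, side="right")
    mean_delta = np.array([
        pair.delta[band_a == b].mean() if np.any(band_a == b) else np.nan
        for b in range(len(edges) + 1)])
    return StrataReport(band_edges=tuple(edges), fractions_a=fa, fractions_b=fb,
                        mean_delta_per_band=mean_delta)


# ---------------------------------------------------------------------------
# outflow
# ---------------------------------------------------------------------------

def _major_vessel(tree: VesselTree, label: str,
                  majors=("LAD", "LCx", "RCA", "LM")) -> str:
    """Walk up the tree until a major trunk name is found."""
    seg = tree.segment(label)
    while True:
        if seg.name in majors:
            return seg.name
        if seg.parent_id is None:
            return seg.name
        seg = tree.segment(seg.parent_id)


def outflow_report(flows_mls: dict, flow_times: np.ndarray, tree: VesselTree,
                   inlet_flow_mls: Optional[np.ndarray] = None) -> OutflowReport:
    """Time-mean volumetric flow per outlet over the final cycle (ml/s),
    grouped into named major vessels by tree ancestry."""
    per_outlet = {}
    for label, series in flows_mls.items():
        if label is None or label == "":
            raise ValueError("unlabeled outlet in flow series")
        per_outlet[label] = float(np.trapezoid(series, flow_times)
                                  / (flow_times[-1] - flow_times[0]))
    per_vessel: dict = {}
    for label, q in per_outlet.items():
        mv = _major_vessel(tree, label)
        per_vessel[mv] = per_vessel.get(mv, 0.0) + q
    total = float(sum(per_outlet.values()))
    inlet = total
    if inlet_flow_mls is not None:
        inlet = float(np.trapezoid(inlet_flow_mls, flow_times)
                      / (flow_times[-1] - flow_times[0]))
    return OutflowReport(per_outlet_mls=per_outlet, per_vessel_mls=per_vessel,
                         total_mls=total, inlet_mls=inlet)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def stats_suite(groups: Sequence[np.ndarray], paired: bool = False,
                alpha: float = 0.05) -> dict:
    """The reporting statistics: KS normality per group, then a two-tailed
    Student t test (2 groups) or Kruskal-Wallis (unpaired, >= 3 groups) /
    Friedman (paired, >= 3 groups); mean +/- SEM summaries."""
    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    normality = []
    for g in groups:
        z = (g - g.mean()) / (g.std(ddof=1) if g.std(ddof=1) > 0 else 1.0)
        ks = stats.kstest(z, "norm")
        normality.append({"statistic": float(ks.statistic),
                          "p": float(ks.pvalue),
                          "normal": bool(ks.pvalue >= alpha)})
    summaries = [{"mean": float(g.mean()),
                  "sem": float(g.std(ddof=1) / np.sqrt(len(g))),
                  "n": len(g)} for g in groups]
    if len(groups) == 2:
        if np.array_equal(groups[0], groups[1]):
            test = {"name": "t", "statistic": 0.0, "p": 1.0}
        else:
            if paired:
                r = stats.ttest_rel(groups[0], groups[1])
            else:
                r = stats.ttest_ind(groups[0], groups[1])
            test = {"name": "t", "statistic": float(r.statistic),
                    "p": float(r.pvalue)}
    elif paired:
        sizes = {len(g) for g in groups}
        if len(sizes) != 1:
            raise ValueError("Friedman test requires equal block sizes")
        r = stats.friedmanchisquare(*groups)
        test = {"name": "friedman", "statistic": float(r.statistic),
                "p": float(r.pvalue)}
    else:
        r = stats.kruskal(*groups)
        test = {"name": "kruskal", "statistic": float(r.statistic),
                "p": float(r.pvalue)}
    test["significant"] = bool(test["p"] < alpha)
    return {"normality": normality, "summaries": summaries, "test": test,
            "alpha": alpha}
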