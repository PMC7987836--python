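"""Data-driven ROI identification from cortical activation maps.

Three-step algorithm operating on a vertex-level activation map:

1. **Centroid selection** — vertices whose mean activation over the
   analysis window exceeds a percentile threshold (default 95th) become
   candidate ROI centroids; weaker candidates within an exclusion radius
   (default 5 mm) of a stronger accepted candidate are dropped.
2. **Similarity growth** — from each centroid, contiguous vertices whose
   activation time course is within ``growth_sd_factor`` (default 0.5)
   SDs of the centroid's course join the ROI.  Courses are normalized by
   z-scoring over the window, so each has unit SD per timepoint; "within
   f SDs" then means the Euclidean distance between normalized courses is
   below f * sqrt(window length) — an RMS per-sample difference of f in
   SD units.  Contiguity is breadth-first reachability on a
   spatial-radius adjacency graph.
3. **Redundancy pruning** — ROIs whose normalized mean course lies within
   ``redundancy_sd_factor`` (default 0.9) SDs (same units) of a stronger
   (higher mean non-normalized activation) retained ROI are eliminated,
   so every retained signal carries unique predictive information for the
   Granger stage.  Orthogonal unit-SD courses sit at sqrt(2) SDs, so the
   0.5 / 0.9 factors admit only genuinely similar shapes.

Representative per-subject time courses are extracted per ROI as the
member vertex maximally correlated with the group-level ROI mean course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (AnalysisConfig, MultiTimeSeries, ValidationError,
                      VertexActivationMap)

logger = logging.getLogger("phonoflux")


@dataclass
class Roi:
    roi_id: str
    centroid_vertex: str
    members: set[str]
    mean_course: np.ndarray
    strength: float

    def __post_init__(self):
        if self.centroid_vertex not in self.members:
            raise ValidationError("centroid must be a member of its ROI")
        if not self.members:
            raise ValidationError("ROI must have at least one member")


@dataclass
class RoiSet:
    rois: list[Roi]
    provenance: AnalysisConfig | None = None

    def __post_init__(self):
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValidationError("roi_ids must be unique")
        seen: set[str] = set()
        for r in self.rois:
            if seen & r.members:
                raise ValidationError("ROI member sets must be disjoint")
            seen |= r.members

    def __len__(self) -> int:
        return len(self.rois)

    def labels(self) -> list[str]:
        return [r.roi_id for r in self.rois]

    def to_membership(self) -> dict[str, list[str]]:
        return {r.roi_id: sorted(r.members) for r in self.rois}


def _window_activation(vmap: VertexActivationMap,
                       cfg: AnalysisConfig) -> np.ndarray:
    lo, hi = vmap.window_indices(cfg.window_ms)
    return vmap.activation[:, lo:hi + 1]


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (X - mu) / sd


def select_centroids(vmap: VertexActivationMap,
                     cfg: AnalysisConfig) -> list[str]:
    """Percentile-thresholded, spatially exclusive centroid candidates.

    Mean |activation| over the analysis window is the vertex strength;
    vertices above the ``centroid_percentile`` (linear-interpolation
    percentile) are scanned in descending strength (ties broken by vertex
    id) and any candidate within ``exclusion_radius_mm`` of an accepted
    stronger candidate is discarded.
    """
    if vmap.n_vertices < 2:
        raise ValidationError("centroid selection needs >= 2 vertices")
    W = _window_activation(vmap, cfg)
    strength = np.abs(W).mean(axis=1)
    thresh = np.percentile(strength, cfg.centroid_percentile)
    cand = np.flatnonzero(strength > thresh)
    if cand.size == 0:
        logger.warning("no vertex exceeds the %gth percentile "
                       "(flat activation map?)", cfg.centroid_percentile)
        return []
    order = sorted(cand, key=lambda i: (-strength[i], vmap.vertex_ids[i]))
    accepted: list[int] = []
    coords = vmap.coords_mm
    for i in order:
        if all(np.linalg.norm(coords[i] - coords[j]) > cfg.exclusion_radius_mm
               for j in accepted):
            accepted.append(i)
    return [vmap.vertex_ids[i] for i in accepted]


def _adjacency_tree(vmap: VertexActivationMap) -> cKDTree:
    return cKDTree(vmap.coords_mm)


def grow_roi(centroid: str, vmap: VertexActivationMap, cfg: AnalysisConfig,
             tree: cKDTree | None = None) -> Roi:
    """Grow one ROI from a centroid by time-course similarity + contiguity.

    A vertex is similarity-eligible when the Euclidean distance between
    its z-scored windowed course and the centroid's is below
    ``growth_sd_factor * sqrt(window length)`` (an RMS per-sample
    difference of ``growth_sd_factor`` SD units); membership is then the
    breadth-first closure of eligible vertices from the centroid on the
    spatial adjacency graph.
    """
    idx = {v: i for i, v in enumerate(vmap.vertex_ids)}
    if centroid not in idx:
        raise ValidationError(f"centroid {centroid!r} is not a map vertex")
    ci = idx[centroid]
    W = _window_activation(vmap, cfg)
    Z = _zscore_rows(W)
    d = np.linalg.norm(Z - Z[ci], axis=1)
    eligible = d < cfg.growth_sd_factor * np.sqrt(W.shape[1])
    eligible[ci] = True
    # breadth-first growth over the spatial adjacency graph, restricted to
    # similarity-eligible vertices
    tree = tree or _adjacency_tree(vmap)
    members = {ci}
    frontier = [ci]
    while frontier:
        nxt = []
        for v in frontier:
            for nb in tree.query_ball_point(vmap.coords_mm[v],
                                            cfg.adjacency_radius_mm):
                if nb not in members and eligible[nb]:
                    members.add(nb)
                    nxt.append(nb)
        frontier = nxt
    member_ids = {vmap.vertex_ids[i] for i in members}
    rows = sorted(members)
    mean_course = W[rows].mean(axis=0)
    strength = float(np.abs(W[rows]).mean())
    return Roi(roi_id=f"roi_{centroid}", centroid_vertex=centroid,
               members=member_ids, mean_course=mean_course,
               strength=strength)


def prune_redundant(rois: RoiSet, cfg: AnalysisConfig) -> RoiSet:
    """Drop ROIs whose mean course duplicates a stronger retained ROI's.

    Distances are Euclidean between z-scored mean courses, thresholded at
    ``redundancy_sd_factor * sqrt(window length)`` (RMS per-sample
    difference in SD units).  ROIs are scanned in descending strength so
    the stronger of a redundant pair is always kept.
    """
    if len(rois) <= 1:
        return rois
    courses = _zscore_rows(np.array([r.mean_course for r in rois.rois]))
    n = len(rois)
    thresh = cfg.redundancy_sd_factor * np.sqrt(courses.shape[1])
    order = sorted(range(n), key=lambda i: (-rois.rois[i].strength,
                                            rois.rois[i].roi_id))
    retained: list[int] = []
    for i in order:
        if all(np.linalg.norm(courses[i] - courses[j]) >= thresh
               for j in retained):
            retained.append(i)
    retained_set = set(retained)
    kept = [r for i, r in enumerate(rois.rois) if i in retained_set]
    return RoiSet(rois=kept, provenance=rois.provenance)


def identify_rois(vmap: VertexActivationMap, cfg: AnalysisConfig) -> RoiSet:
    """Full three-step ROI identification.

    Composition of centroid selection, similarity growth, and redundancy
    pruning.  Vertices claimed by several grown ROIs are assigned to the
    strongest claimant so member sets are disjoint.
    """
    centroids = select_centroids(vmap, cfg)
    W = _window_activation(vmap, cfg)
    tree = _adjacency_tree(vmap)
    grown = [grow_roi(c, vmap, cfg, tree=tree) for c in centroids]
    # resolve overlaps: shared vertices go to the stronger ROI
    by_strength = sorted(grown, key=lambda r: (-r.strength, r.roi_id))
    claimed: set[str] = set()
    resolved = []
    for r in by_strength:
        mem = r.members - claimed
        if r.centroid_vertex not in mem:
            continue            # centroid captured by a stronger ROI
        claimed |= mem
        if mem != r.members:
            idx = {v: i for i, v in enumerate(vmap.vertex_ids)}
            rows = sorted(idx[v] for v in mem)
            r = Roi(roi_id=r.roi_id, centroid_vertex=r.centroid_vertex,
                    members=mem, mean_course=W[rows].mean(axis=0),
                    strength=float(np.abs(W[rows]).mean()))
        resolved.append(r)
    roiset = RoiSet(rois=resolved, provenance=cfg)
    return prune_redundant(roiset, cfg)


def extract_roi_timeseries(subject_maps: dict[str, VertexActivationMap],
                           rois: RoiSet, cfg: AnalysisConfig,
                           ) -> dict[str, MultiTimeSeries]:
    """Per-subject representative ROI time courses.

    For each ROI and subject, the representative vertex is the member whose
    windowed course correlates best with the group-level ROI mean course;
    the subject's full-length course at that vertex becomes the ROI channel.
    Channel order follows the RoiSet.
    """
    out = {}
    for subject, vmap in subject_maps.items():
        idx = {v: i for i, v in enumerate(vmap.vertex_ids)}
        lo, hi = vmap.window_indices(cfg.window_ms)
        rows = []
        for roi in rois.rois:
            present = [v for v in sorted(roi.members) if v in idx]
            if not present:
                raise ValidationError(
                    f"subject {subject!r} has no vertex of ROI "
                    f"{roi.roi_id!r}")
            ref = roi.mean_course - roi.mean_course.mean()
            best, best_r = None, -np.inf
            for v in present:
                course = vmap.activation[idx[v], lo:hi + 1]
                c = course - course.mean()
                denom = np.linalg.norm(c) * np.linalg.norm(ref)
                r = float(c @ ref / denom) if denom > 1e-12 else -np.inf
                if r > best_r:
                    best, best_r = v, r
            rows.append(vmap.activation[idx[best]])
        out[subject] = MultiTimeSeries(labels=rois.labels(),
                                       values=np.array(rows),
                                       sampling_rate=vmap.sampling_rate,
                                       t0_ms=vmap.t0_ms)
    return out
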