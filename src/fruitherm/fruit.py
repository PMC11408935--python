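"""Fruit segmentation from labelled-free geometry and return intensity.

Per point, the covariance of the k nearest neighbours is eigen-decomposed
(λ1 ≥ λ2 ≥ λ3 ≥ 0) to yield two geometric features:

* linearity   L = (λ1 − λ2) / λ1            ∈ [0, 1]  (1 on a line)
* curvature   C = 100 · (λ3 / Σλ) / (1/3)   ∈ [0, 100]  (0 on a plane,
  100 for an isotropic neighbourhood; values nearer 100 mean a curved,
  volumetric local shape such as a fruit surface patch at this scale)

Thresholds are the modes of the feature distributions, found as the argmax
of a Gaussian KDE. Wood points satisfy three criteria jointly on (L, C,
R_ToF) and are subtracted; fruit candidates satisfy two criteria on (C,
R_ToF); DBSCAN groups candidates into individual fruit. Temperature plays
no role in segmentation. Detections are scored against ground truth as
precision / recall / F1.

The comparison direction of every criterion is configurable. The defaults
reflect the geometry at typical scan densities and the package's reflectance
ordering: wood is the most linear and darkest class, and — because a
neighbourhood on a thin woody cylinder wraps both sides of the stem — also
the one with the highest surface variation; fruit candidates are curved and
bright.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .cloud import PointCloud


def _provenance(cloud: PointCloud) -> tuple[int, float]:
    """Cheap fingerprint tying features/thresholds to their source cloud."""
    if len(cloud) == 0:
        return (0, 0.0)
    return (len(cloud), float(cloud.xyz.sum()))


class ProvenanceError(ValueError):
    """Features or thresholds applied to a cloud they were not derived from."""


@dataclass
class EigenFeatures:
    """Per-point local-covariance eigenvalues and derived shape features."""

    eigenvalues: np.ndarray   # (n, 3), sorted descending
    linearity: np.ndarray     # L in [0, 1]
    curvature: np.ndarray     # C in [0, 100]
    k: int
    source: tuple = None

    def __len__(self) -> int:
        return len(self.linearity)

    def select(self, index: np.ndarray, cloud: PointCloud = None) -> "EigenFeatures":
        """Subset rows; re-stamp provenance to ``cloud`` when given."""
        return EigenFeatures(self.eigenvalues[index], self.linearity[index],
                             self.curvature[index], self.k,
                             source=_provenance(cloud) if cloud is not None else None)


def compute_eigen_features(cloud: PointCloud, k: int = 30) -> EigenFeatures:
    """Eigen-decompose each point's k-nearest-neighbour covariance.

    The neighbourhood includes the point itself. Degenerate neighbourhoods
    (all points coincident, λ1 = 0) get NaN features.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    n = len(cloud)
    if n < k + 1:
        raise ValueError(f"cloud has {n} points; need at least k+1 = {k + 1}")
    tree = cKDTree(cloud.xyz)
    _, idx = tree.query(cloud.xyz, k=k)
    nbrs = cloud.xyz[idx]                              # (n, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    lam = np.linalg.eigvalsh(cov)[:, ::-1]             # descending
    lam = np.clip(lam, 0.0, None)
    total = lam.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = (lam[:, 0] - lam[:, 1]) / lam[:, 0]
        C = 100.0 * (lam[:, 2] / total) / (1.0 / 3.0)
    degenerate = lam[:, 0] <= 0
    L[degenerate] = np.nan
    C[degenerate] = np.nan
    return EigenFeatures(lam, L, C, k, source=_provenance(cloud))


def threshold_from_mode(values: np.ndarray, min_n: int = 50) -> float:
    """Mode of a feature distribution via Gaussian KDE (Silverman bandwidth).

    The KDE is evaluated on a 512-point grid over the data range and the
    argmax returned. A constant series returns that constant with a
    zero-bandwidth warning.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < min_n:
        raise ValueError(f"need at least {min_n} finite values, got {v.size}")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant series: zero bandwidth, returning the constant")
        return float(lo)
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


#: criterion direction conventions; "ge" keeps values >= threshold
_DEFAULT_DIRECTIONS = {
    "l_wood": "ge",   # wood is the most linear structure
    "c_wood": "ge",   # thin woody cylinders show high surface variation at
                      # typical scan densities (both sides of the stem fall in
                      # one neighbourhood), unlike near-planar leaf/fruit patches
    "r_wood": "le",   # wood is the darkest class at 905 nm
    "c_fruit": "ge",  # fruit neighbourhoods are curved
    "r_fruit": "ge",  # fruit is the brightest class
}

#: directions exactly as the source method prints them (wood linearity
#: inequality physically questionable; see package docs)
PRINTED_DIRECTIONS = {
    "l_wood": "le", "c_wood": "ge", "r_wood": "ge",
    "c_fruit": "ge", "r_fruit": "ge",
}


@dataclass
class ThresholdSet:
    """Mode-derived segmentation thresholds with comparison directions."""

    l_wood: float
    c_wood: float
    r_wood: float
    c_fruit: float
    r_fruit: float
    directions: dict = field(default_factory=lambda: dict(_DEFAULT_DIRECTIONS))
    source: tuple = None

    def __post_init__(self) -> None:
        for name in ("l_wood", "c_wood", "r_wood", "c_fruit", "r_fruit"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")
            if self.directions.get(name) not in ("le", "ge"):
                raise ValueError(f"direction for {name} must be 'le' or 'ge'")

    def compare(self, name: str, values: np.ndarray) -> np.ndarray:
        th = getattr(self, name)
        if self.directions[name] == "ge":
            return values >= th
        return values <= th


def derive_thresholds(cloud: PointCloud, features: EigenFeatures,
                      fruit_reference: np.ndarray | None = None,
                      wood_reference: np.ndarray | None = None,
                      directions: dict | None = None) -> ThresholdSet:
    """Build a :class:`ThresholdSet` from the cloud's own feature distributions.

    Wood thresholds default to the KDE modes of the full-cloud L, C and
    intensity distributions (dominated by foliage, so the modes separate the
    wood tails). Fruit thresholds need a fruit reference subset — a boolean
    mask of known fruit points (ground truth on synthetic scenes, or a
    manually delineated reference on real data) whose C and intensity modes
    become the fruit criteria; without one the full-cloud modes are used and
    a warning raised, since foliage then dominates the fruit thresholds.
    """
    if cloud.intensity is None:
        raise ValueError("cloud needs an intensity channel for thresholds")
    if features.source != _provenance(cloud):
        raise ProvenanceError("features were not computed on this cloud")
    wood_sel = slice(None) if wood_reference is None else wood_reference
    l_w = threshold_from_mode(features.linearity[wood_sel])
    c_w = threshold_from_mode(features.curvature[wood_sel])
    r_w = threshold_from_mode(cloud.intensity[wood_sel])
    if fruit_reference is None:
        warnings.warn("no fruit reference subset: fruit thresholds fall back "
                      "to full-cloud modes and will be foliage-dominated")
        fruit_sel: np.ndarray | slice = slice(None)
    else:
        fruit_sel = np.asarray(fruit_reference, dtype=bool)
    c_f = threshold_from_mode(features.curvature[fruit_sel])
    r_f = threshold_from_mode(cloud.intensity[fruit_sel])
    return ThresholdSet(l_w, c_w, r_w, c_f, r_f,
                        directions=dict(directions or _DEFAULT_DIRECTIONS),
                        source=_provenance(cloud))


def _check_provenance(cloud: PointCloud, features: EigenFeatures,
                      thresholds: ThresholdSet) -> None:
    tag = _provenance(cloud)
    if features.source is not None and features.source != tag:
        raise ProvenanceError("features were computed on a different cloud")
    if thresholds.source is not None and thresholds.source != tag:
        raise ProvenanceError("thresholds were derived from a different cloud")


def segment_wood(cloud: PointCloud, features: EigenFeatures,
                 thresholds: ThresholdSet
                 ) -> tuple[np.ndarray, PointCloud, EigenFeatures]:
    """Remove wood: points meeting all three wood criteria jointly.

    Returns ``(wood_mask, remainder_cloud, remainder_features)``; the
    remainder keeps the working set for fruit-candidate selection.
    """
    if cloud.intensity is None:
        raise ValueError("cloud needs an intensity channel")
    _check_provenance(cloud, features, thresholds)
    with np.errstate(invalid="ignore"):
        wood = (thresholds.compare("l_wood", features.linearity)
                & thresholds.compare("c_wood", features.curvature)
                & thresholds.compare("r_wood", cloud.intensity))
    wood = wood & np.isfinite(features.linearity)
    remainder = cloud.select(~wood)
    if len(remainder) == 0:
        warnings.warn("wood criteria removed every point")
    return wood, remainder, features.select(~wood, cloud=remainder)


def segment_fruit_candidates(cloud: PointCloud, features: EigenFeatures,
                             thresholds: ThresholdSet) -> np.ndarray:
    """Fruit-candidate mask on the wood-subtracted cloud: both criteria jointly."""
    if cloud.intensity is None:
        raise ValueError("cloud needs an intensity channel")
    tag = _provenance(cloud)
    if features.source is not None and features.source != tag:
        raise ProvenanceError("features were computed on a different cloud")
    with np.errstate(invalid="ignore"):
        cand = (thresholds.compare("c_fruit", features.curvature)
                & thresholds.compare("r_fruit", cloud.intensity))
    return cand & np.isfinite(features.curvature)


# ---------------------------------------------------------------------------
# DBSCAN (kept in-package so tests can cross-check it against an
# independent reference implementation)
# ---------------------------------------------------------------------------

def dbscan(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Density-based clustering; returns labels, −1 for noise.

    Core-point semantics match the common convention: a point is core if its
    eps-neighbourhood (itself included) holds at least ``min_samples``
    points. Border points join the first expanding cluster that reaches
    them; cluster ids are assigned in point order, so the labelling is
    deterministic and permutation of identical coordinates cannot change
    the partition.
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    labels = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels
    if eps <= 0:
        raise ValueError("eps must be positive")
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, r=eps)
    core = np.array([len(nb) >= min_samples for nb in neighborhoods])
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cluster
        queue = deque(neighborhoods[i])
        while queue:
            j = queue.popleft()
            if labels[j] == -1:
                labels[j] = cluster
                if core[j]:
                    queue.extend(neighborhoods[j])
        cluster += 1
    return labels


@dataclass
class FruitCluster:
    """One detected fruit: member indices and summary statistics."""

    indices: np.ndarray        # indices into the cloud passed to cluster_fruit
    centroid: np.ndarray       # (3,) metres
    n_points: int
    t_mean: float              # NaN when no member is temperature-annotated
    t_min: float
    t_max: float
    est_diameter: float        # max pairwise member distance, metres


def cluster_fruit(cloud: PointCloud, candidate_mask: np.ndarray, eps: float,
                  min_neighbors: int = 10) -> list[FruitCluster]:
    """Group fruit-candidate points into individual fruit with DBSCAN.

    ``eps`` should be derived from the mean manually measured fruit
    diameter (radius semantics: diameter / 2). Clusters smaller than
    ``min_neighbors`` are noise. Per-cluster temperature statistics are
    taken over annotated (finite) members only.
    """
    if eps <= 0:
        raise ValueError("eps must be positive (derive it from the mean fruit diameter)")
    cand_idx = np.flatnonzero(np.asarray(candidate_mask, dtype=bool))
    if cand_idx.size == 0:
        return []
    labels = dbscan(cloud.xyz[cand_idx], eps=eps, min_samples=min_neighbors)
    clusters: list[FruitCluster] = []
    for lab in range(labels.max() + 1 if labels.size else 0):
        members = cand_idx[labels == lab]
        if members.size < min_neighbors:
            continue
        xyz = cloud.xyz[members]
        if cloud.temperature is not None:
            t = cloud.temperature[members]
            t = t[np.isfinite(t)]
        else:
            t = np.empty(0)
        diam = _max_pairwise_distance(xyz)
        clusters.append(FruitCluster(
            indices=members,
            centroid=xyz.mean(axis=0),
            n_points=int(members.size),
            t_mean=float(t.mean()) if t.size else float("nan"),
            t_min=float(t.min()) if t.size else float("nan"),
            t_max=float(t.max()) if t.size else float("nan"),
            est_diameter=diam,
        ))
    return clusters


def _max_pairwise_distance(xyz: np.ndarray, cap: int = 1500) -> float:
    if len(xyz) > cap:  # subsample: fruit clusters are small, guard anyway
        xyz = xyz[np.linspace(0, len(xyz) - 1, cap).astype(int)]
    diff = xyz[:, None, :] - xyz[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def clusters_to_frame(clusters: list[FruitCluster], tree_id: int = 1) -> pd.DataFrame:
    """Per-fruit summary table (one row per detected fruit)."""
    rows = [{
        "tree_id": tree_id, "fruit_id": i + 1,
        "x": c.centroid[0], "y": c.centroid[1], "z": c.centroid[2],
        "n_points": c.n_points, "t_raw_mean": c.t_mean,
        "t_raw_min": c.t_min, "t_raw_max": c.t_max,
        "est_diameter": c.est_diameter,
    } for i, c in enumerate(clusters)]
    return pd.DataFrame(rows, columns=["tree_id", "fruit_id", "x", "y", "z",
                                       "n_points", "t_raw_mean", "t_raw_min",
                                       "t_raw_max", "est_diameter"])


@dataclass
class DetectionScore:
    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def score_detection(clusters: list[FruitCluster], true_fruit_id: np.ndarray,
                    n_points: int, overlap_threshold: float = 0.5
                    ) -> DetectionScore:
    """Score detected clusters against per-point true fruit ids.

    A cluster is a true positive when more than ``overlap_threshold`` of its
    members share one true fruit id and that fruit is not already matched;
    every other cluster is a false positive, every unmatched true fruit a
    false negative.
    """
    true_fruit_id = np.asarray(true_fruit_id, dtype=np.int64)
    if len(true_fruit_id) != n_points:
        raise ValueError(
            f"ground truth covers {len(true_fruit_id)} points, cloud has {n_points}")
    true_ids = set(np.unique(true_fruit_id[true_fruit_id > 0]).tolist())
    matched: set[int] = set()
    tp = fp = 0
    for c in clusters:
        ids = true_fruit_id[c.indices]
        pos = ids[ids > 0]
        if pos.size:
            vals, counts = np.unique(pos, return_counts=True)
            best = vals[np.argmax(counts)]
            frac = counts.max() / len(ids)
        else:
            best, frac = 0, 0.0
        if frac > overlap_threshold and best not in matched and best in true_ids:
            matched.add(int(best))
            tp += 1
        else:
            fp += 1
    fn = len(true_ids) - len(matched)
    return DetectionScore(tp, fp, fn)
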