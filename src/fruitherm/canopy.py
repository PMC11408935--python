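"""Tree-row processing: two-side ICP alignment, stem detection, cylinder crop.

Rows are scanned from both sides; point-to-point ICP merges the two half
clouds into one. Stems are then located as maxima of the bivariate (x, y)
point-density histogram — valid for slender-spindle training, where the
dominant vertical stem concentrates returns — and each tree is cut out as a
vertical cylinder of the planting distance's diameter around its stem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import PointCloud


@dataclass
class ICPResult:
    rotation: np.ndarray
    translation: np.ndarray
    fused: PointCloud
    mean_distance: float
    converged: bool
    n_iterations: int
    history: list = field(default_factory=list)  # mean distance per iteration


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping src onto dst."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    H = (src - mu_s).T @ (dst - mu_d)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_d - R @ mu_s
    return R, t


def align_sides(side_a: PointCloud, side_b: PointCloud, max_iter: int = 60,
                tol: float = 1e-7, convergence_distance: float = 0.05,
                max_correspondence_distance: float = 1.0) -> ICPResult:
    """Point-to-point ICP aligning ``side_b`` onto ``side_a``.

    Iterates nearest-neighbour correspondence and the closed-form rigid
    update until the mean correspondence distance stops improving by ``tol``.
    Correspondences farther than ``max_correspondence_distance`` are ignored
    (the sides are assumed coarsely positioned already, e.g. by GNSS); if no
    usable correspondences exist, or the final mean inlier distance exceeds
    ``convergence_distance``, ``converged`` is False. The fused cloud is
    ``side_a`` plus the transformed ``side_b``.
    """
    if len(side_a) == 0 or len(side_b) == 0:
        raise ValueError("both sides must be non-empty")
    tree = cKDTree(side_a.xyz)
    R = np.eye(3)
    t = np.zeros(3)
    moved = side_b.xyz.copy()
    history: list[float] = []
    prev = np.inf
    overlap_ok = True
    for it in range(max_iter):
        dist, idx = tree.query(moved)
        inlier = dist <= max_correspondence_distance
        if inlier.sum() < 3:
            overlap_ok = False
            history.append(float(dist.mean()))
            break
        mean_d = float(dist[inlier].mean())
        history.append(mean_d)
        if prev - mean_d < tol:
            break
        prev = mean_d
        R_step, t_step = _kabsch(moved[inlier], side_a.xyz[idx[inlier]])
        moved = moved @ R_step.T + t_step
        R = R_step @ R
        t = R_step @ t + t_step
    dist, _ = tree.query(moved)
    inlier = dist <= max_correspondence_distance
    mean_d = float(dist[inlier].mean()) if inlier.any() else float(dist.mean())
    converged = overlap_ok and inlier.any() and mean_d <= convergence_distance
    if not converged:
        warnings.warn(
            f"ICP did not converge: mean correspondence distance {mean_d:.3f} m")
    moved_cloud = side_b.copy()
    moved_cloud.xyz = moved
    fused = PointCloud(
        np.vstack([side_a.xyz, moved]),
        intensity=_cat(side_a.intensity, moved_cloud.intensity),
        temperature=_cat(side_a.temperature, moved_cloud.temperature),
        label=_cat(side_a.label, moved_cloud.label),
        fruit_id=_cat(side_a.fruit_id, moved_cloud.fruit_id),
    )
    return ICPResult(R, t, fused, mean_d, converged, len(history), history)


def _cat(a, b):
    if a is None or b is None:
        return None
    return np.concatenate([a, b])


@dataclass
class StemMap:
    """Detected stem positions with bookkeeping for points per tree (PPT)."""

    positions: np.ndarray              # (k, 2) stem (x, y) in metres
    planting_distance: float
    peak_counts: np.ndarray = None     # histogram count at each peak
    low_confidence: np.ndarray = None  # per-stem flag
    ppt: np.ndarray = None             # filled after cropping

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        if self.peak_counts is None:
            self.peak_counts = np.zeros(len(self.positions))
        if self.low_confidence is None:
            self.low_confidence = np.zeros(len(self.positions), dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "tree_id": np.arange(1, len(self) + 1),
            "x": self.positions[:, 0],
            "y": self.positions[:, 1],
            "ppt": self.ppt if self.ppt is not None else np.zeros(len(self), int),
        }).to_csv(path, index=False)


def detect_stems(cloud: PointCloud, bin_size: float = 0.10,
                 planting_distance: float = 0.95) -> StemMap:
    """Locate stems as peaks of the bivariate (x, y) point-density histogram.

    Bins whose count exceeds mean + 2·SD of all occupied-bin counts are peak
    candidates; candidates are kept greedily by count with a minimum mutual
    separation of 0.7 × planting distance, and each kept peak is refined to
    the count-weighted centroid of its 3×3 bin neighbourhood. Peaks barely
    above the detection threshold are flagged low-confidence.
    """
    if len(cloud) == 0:
        warnings.warn("empty cloud: no stems")
        return StemMap(np.empty((0, 2)), planting_distance)
    xy = cloud.xyz[:, :2]
    x_edges = np.arange(xy[:, 0].min() - bin_size, xy[:, 0].max() + 2 * bin_size, bin_size)
    y_edges = np.arange(xy[:, 1].min() - bin_size, xy[:, 1].max() + 2 * bin_size, bin_size)
    H, x_edges, y_edges = np.histogram2d(xy[:, 0], xy[:, 1],
                                         bins=[x_edges, y_edges])
    occupied = H[H > 0]
    thresh = occupied.mean() + 2.0 * occupied.std()
    peak_mask = H > thresh
    if not peak_mask.any():
        warnings.warn("no density peak above mean + 2 SD: empty stem map")
        return StemMap(np.empty((0, 2)), planting_distance)

    xc = (x_edges[:-1] + x_edges[1:]) / 2.0
    yc = (y_edges[:-1] + y_edges[1:]) / 2.0
    ii, jj = np.nonzero(peak_mask)
    counts = H[ii, jj]
    order = np.argsort(-counts)
    kept: list[tuple[int, int]] = []
    min_sep = 0.7 * planting_distance
    for k in order:
        i, j = ii[k], jj[k]
        pos = np.array([xc[i], yc[j]])
        if all(np.hypot(xc[i2] - pos[0], yc[j2] - pos[1]) >= min_sep
               for i2, j2 in kept):
            kept.append((i, j))

    positions = []
    peak_counts = []
    for i, j in kept:
        i0, i1 = max(i - 1, 0), min(i + 2, H.shape[0])
        j0, j1 = max(j - 1, 0), min(j + 2, H.shape[1])
        w = H[i0:i1, j0:j1]
        gx, gy = np.meshgrid(xc[i0:i1], yc[j0:j1], indexing="ij")
        positions.append([np.average(gx, weights=w), np.average(gy, weights=w)])
        peak_counts.append(H[i, j])
    positions = np.asarray(positions)
    peak_counts = np.asarray(peak_counts)
    # sort along the row for stable tree ids
    row_order = np.argsort(positions[:, 0])
    positions = positions[row_order]
    peak_counts = peak_counts[row_order]
    low_conf = peak_counts < occupied.mean() + 4.0 * occupied.std()
    if low_conf.any():
        warnings.warn(f"{int(low_conf.sum())} stem peak(s) barely above the "
                      "density threshold; flagged low-confidence")
    return StemMap(positions, planting_distance, peak_counts, low_conf)


def crop_tree(cloud: PointCloud, stem: np.ndarray, diameter: float = 0.95
              ) -> PointCloud:
    """Cut one tree: points within ``diameter/2`` of the stem axis (closed
    boundary), full height."""
    stem = np.asarray(stem, dtype=np.float64).reshape(2)
    d = np.hypot(cloud.xyz[:, 0] - stem[0], cloud.xyz[:, 1] - stem[1])
    keep = d <= diameter / 2.0
    if not keep.any():
        warnings.warn(f"cylinder crop at {stem} is empty")
    return cloud.select(keep)
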