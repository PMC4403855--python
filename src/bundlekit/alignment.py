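"""Cell-orientation and neighborhood-alignment statistics from segmented centerlines.

Input is the centerline (major axis) of each segmented cell, in pixel coordinates
(origin top-left, y down). Each centerline is cut into approximately equally sized
segments; a segment carries its midpoint and its axial orientation (an angle modulo
180 degrees, so anti-parallel cells are perfectly aligned). Alignment is then
quantified from the angular differences between a focal segment and all segments
within a fixed pixel radius, excluding segments of the focal segment's own cell:
tightly bundled chains give mean neighbor differences of a few degrees, while
dispersed fields of independently oriented cells give ~45 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .geometry import axial_difference_deg

__all__ = [
    "CenterlineCell",
    "SegmentField",
    "AngularHistogram",
    "CellLengthSummary",
    "segment_centerline",
    "build_segment_field",
    "axial_difference",
    "neighbor_differences",
    "alignment_map",
    "angle_histogram",
    "cell_length_summary",
    "rotate_field",
]


@dataclass
class CenterlineCell:
    """Ordered 2-D points (pixels) along one cell's major axis."""

    cell_id: str
    points: np.ndarray  # (n, 2), n >= 2

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError(f"cell {self.cell_id!r}: centerline needs >= 2 2-D points")
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"cell {self.cell_id!r}: non-finite coordinate")
        steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
        if np.any(steps == 0.0):
            raise ValueError(f"cell {self.cell_id!r}: consecutive duplicate points")
        self.points = pts

    @property
    def arc_length(self) -> float:
        return float(np.hypot(np.diff(self.points[:, 0]), np.diff(self.points[:, 1])).sum())


def _resample_at(points: np.ndarray, s_targets: np.ndarray) -> np.ndarray:
    """Points at the given arc-length positions along a polyline (linear interp)."""
    seg = np.hypot(np.diff(points[:, 0]), np.diff(points[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    x = np.interp(s_targets, cum, points[:, 0])
    y = np.interp(s_targets, cum, points[:, 1])
    return np.column_stack([x, y])


def segment_centerline(cell: CenterlineCell, target_len: float = 10.0) -> pd.DataFrame:
    """Split one centerline into ceil(arc/target_len) equal-arc-length segments.

    Each segment's orientation is the chord angle (first to last point of the
    sub-arc), axial (mod 180 degrees); its position is the chord midpoint.
    """
    if target_len <= 0:
        raise ValueError("target_len must be > 0")
    total = cell.arc_length
    if total <= 0:
        raise ValueError(f"cell {cell.cell_id!r}: degenerate centerline")
    n_seg = max(1, math.ceil(total / target_len))
    bounds = np.linspace(0.0, total, n_seg + 1)
    pts = _resample_at(cell.points, bounds)
    a = pts[:-1]
    b = pts[1:]
    theta = np.degrees(np.arctan2(b[:, 1] - a[:, 1], b[:, 0] - a[:, 0])) % 180.0
    return pd.DataFrame(
        {
            "cell_id": cell.cell_id,
            "x": (a[:, 0] + b[:, 0]) / 2.0,
            "y": (a[:, 1] + b[:, 1]) / 2.0,
            "theta": theta,
            "seg_len": total / n_seg,
        }
    )


@dataclass
class SegmentField:
    """Oriented cell segments: the substrate of all alignment statistics.

    ``data`` columns: cell_id, x, y, theta (axial degrees in [0, 180)), seg_len.
    """

    data: pd.DataFrame
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        required = {"cell_id", "x", "y", "theta", "seg_len"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"segment field missing columns: {sorted(missing)}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.data[["x", "y"]].to_numpy())
        return self._tree

    @classmethod
    def from_centerlines(cls, cells: Sequence[CenterlineCell], target_len: float = 10.0) -> "SegmentField":
        parts = [segment_centerline(c, target_len) for c in cells]
        return cls(pd.concat(parts, ignore_index=True))


def build_segment_field(cells: Sequence[CenterlineCell], target_len: float = 10.0) -> SegmentField:
    """Segment every centerline and pool the segments into one field."""
    return SegmentField.from_centerlines(cells, target_len)


def axial_difference(theta1, theta2):
    """Smallest angle between two axial orientations, degrees in [0, 90]."""
    return axial_difference_deg(theta1, theta2)


def _neighbor_lists(field: SegmentField, radius: float, exclude_same_cell: bool = True):
    """Per-segment neighbor index lists within the radius (self excluded)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    idx_lists = field.tree.query_ball_tree(field.tree, r=radius)
    cells = field.data["cell_id"].to_numpy()
    out = []
    for i, lst in enumerate(idx_lists):
        if exclude_same_cell:
            out.append(np.array([j for j in lst if cells[j] != cells[i]], dtype=int))
        else:
            out.append(np.array([j for j in lst if j != i], dtype=int))
    return out


def neighbor_differences(field: SegmentField, focal_idx: int, radius: float = 20.0,
                         exclude_same_cell: bool = True) -> np.ndarray:
    """Axial differences between a focal segment and all neighbors within radius.

    Neighbors are segments whose midpoint lies within ``radius`` pixels of the
    focal segment's midpoint; segments of the focal cell itself (including the
    focal segment) are skipped when ``exclude_same_cell``. An isolated segment
    yields an empty array.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    data = field.data
    if not 0 <= focal_idx < len(data):
        raise IndexError(f"focal index {focal_idx} out of range")
    pt = data[["x", "y"]].to_numpy()[focal_idx]
    neigh = field.tree.query_ball_point(pt, r=radius)
    cells = data["cell_id"].to_numpy()
    theta = data["theta"].to_numpy()
    if exclude_same_cell:
        keep = [j for j in neigh if cells[j] != cells[focal_idx]]
    else:
        keep = [j for j in neigh if j != focal_idx]
    if not keep:
        return np.empty(0)
    return axial_difference_deg(theta[focal_idx], theta[keep])


def alignment_map(field: SegmentField, radius: float = 20.0,
                  exclude_same_cell: bool = True) -> pd.DataFrame:
    """Per-segment alignment score: 1 - (mean neighbor difference / 90 degrees).

    1 means all neighbors parallel, 0 means a mean difference of 90 degrees;
    segments with no neighbors get NaN. The score is invariant under global
    rotation, translation, and 180-degree orientation flips of the field.
    """
    lists = _neighbor_lists(field, radius, exclude_same_cell)
    theta = field.data["theta"].to_numpy()
    mean_diff = np.full(len(field), np.nan)
    for i, neigh in enumerate(lists):
        if neigh.size:
            mean_diff[i] = axial_difference_deg(theta[i], theta[neigh]).mean()
    out = field.data[["cell_id", "x", "y", "theta"]].copy()
    out["mean_neighbor_diff"] = mean_diff
    out["score"] = 1.0 - mean_diff / 90.0
    return out


@dataclass
class AngularHistogram:
    """Distribution of neighbor angular differences, binned on [0, 90] degrees."""

    bin_edges: np.ndarray        # 0, bin_width, ..., 90
    frequency: np.ndarray        # relative frequency per bin (sums to 1)
    n_pairs: int                 # pooled focal-neighbor pairs
    n_focal: int                 # focal segments sampled
    mean_deg: float              # mean of the pooled differences (not bin midpoints)
    empty: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "frequency": self.frequency,
            }
        )


def angle_histogram(field: SegmentField, radius: float = 20.0, bin_width: float = 9.0,
                    sample_frac: float = 0.10, seed: Optional[int] = None,
                    exclude_same_cell: bool = True) -> AngularHistogram:
    """Pooled neighbor-difference histogram from a subsample of focal segments.

    Focal segments are subsampled without replacement at ``sample_frac`` (at
    least one); all their neighbor differences within ``radius`` are pooled and
    binned in ``bin_width``-degree bins on [0, 90]. Neighbors always come from
    the full field. The mean is the mean of the pooled differences.
    """
    if not 0.0 < sample_frac <= 1.0:
        raise ValueError("sample_frac must be in (0, 1]")
    if not 0.0 < bin_width <= 90.0:
        raise ValueError("bin_width must be in (0, 90]")
    rng = np.random.default_rng(seed)
    n = len(field)
    edges = np.arange(0.0, 90.0, bin_width)
    edges = np.append(edges, 90.0)
    if n == 0:
        return AngularHistogram(edges, np.zeros(len(edges) - 1), 0, 0, math.nan, empty=True)

    n_focal = max(1, round(sample_frac * n))
    focal = rng.choice(n, size=n_focal, replace=False)

    diffs = []
    for i in focal:
        d = neighbor_differences(field, int(i), radius, exclude_same_cell)
        if d.size:
            diffs.append(d)
    if not diffs:
        return AngularHistogram(edges, np.zeros(len(edges) - 1), 0, n_focal, math.nan, empty=True)
    pooled = np.concatenate(diffs)
    counts, _ = np.histogram(pooled, bins=edges)
    return AngularHistogram(
        bin_edges=edges,
        frequency=counts / pooled.size,
        n_pairs=int(pooled.size),
        n_focal=int(n_focal),
        mean_deg=float(pooled.mean()),
    )


@dataclass
class CellLengthSummary:
    """Per-group centerline-length statistics plus a Welch two-sample t-test."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    p_value: float
    df: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": ["a", "b"],
                "n": [self.n_a, self.n_b],
                "mean": [self.mean_a, self.mean_b],
                "sd": [self.sd_a, self.sd_b],
                "t_stat": self.t_stat,
                "p_value": self.p_value,
                "df": self.df,
            }
        )


def cell_length_summary(cells_a: Sequence[CenterlineCell],
                        cells_b: Sequence[CenterlineCell]) -> CellLengthSummary:
    """Compare cell lengths (centerline arc lengths) between two groups.

    Group a is conventionally the bundled population, group b the single-cell
    one; a positive t favors longer cells in group a (Welch test, two-sided p).
    """
    la = np.array([c.arc_length for c in cells_a])
    lb = np.array([c.arc_length for c in cells_b])
    if la.size < 2 or lb.size < 2:
        raise ValueError("need at least 2 cells per group")
    res = stats.ttest_ind(la, lb, equal_var=False)
    return CellLengthSummary(
        mean_a=float(la.mean()), sd_a=float(la.std(ddof=1)), n_a=int(la.size),
        mean_b=float(lb.mean()), sd_b=float(lb.std(ddof=1)), n_b=int(lb.size),
        t_stat=float(res.statistic), p_value=float(res.pvalue), df=float(res.df),
    )


def rotate_field(field: SegmentField, angle_deg: float, translation=(0.0, 0.0)) -> SegmentField:
    """Rigidly transform a field (used to verify invariance of the statistics)."""
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    d = field.data.copy()
    x = d["x"].to_numpy()
    y = d["y"].to_numpy()
    d["x"] = c * x - s * y + translation[0]
    d["y"] = s * x + c * y + translation[1]
    d["theta"] = (d["theta"].to_numpy() + angle_deg) % 180.0
    return SegmentField(d)
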