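"""Pixel-level fluorescence quantification.

Three analyses that operate on grayscale intensity images (arbitrary units):

* **observed/expected co-expression ratio** — pixels of two channels are jointly
  binned; the observed 2-D count histogram is divided by the product-of-marginals
  expectation. Ratios below 1 mean the two reporters co-occur less often than
  chance (mutual exclusivity of the two cell types); empty cells are masked.
* **transect profiles** — intensities sampled by bilinear interpolation along
  line segments (transects) drawn across cell-cell interaction zones, centered
  on each profile's maximum and summarized as mean +/- sd per offset. Protein
  that accumulates at cell poles produces a symmetric central peak on
  pole-to-pole transects and none on side-to-side ones.
* **labeled-minus-control expression** — mean reporter intensity over cell
  pixels of a labeled strain minus that of an unlabeled control, the background
  -corrected population expression level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "IntensityImage",
    "Transect",
    "JointIntensityHistogram",
    "ProfileStack",
    "joint_obs_exp",
    "extract_profile",
    "center_and_summarize",
    "background_normalize",
    "expression_difference",
]


@dataclass
class IntensityImage:
    """A 2-D grid of non-negative intensities plus minimal acquisition metadata."""

    data: np.ndarray
    bit_depth: Optional[int] = None
    source: Optional[str] = None

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise ValueError("intensity image must be 2-D")
        if not np.all(np.isfinite(arr.astype(float))):
            raise ValueError("intensity image contains non-finite values")
        self.data = arr


def _as_array(image) -> np.ndarray:
    if isinstance(image, IntensityImage):
        return np.asarray(image.data, dtype=float)
    return np.asarray(image, dtype=float)


@dataclass
class Transect:
    """A sampling line segment across an image, pixel coordinates (x right, y down)."""

    x0: float
    y0: float
    x1: float
    y1: float
    kind: str = "major"     # "major": pole-to-pole axis; "minor": side-to-side
    step: float = 1.0       # sampling step in pixels

    def __post_init__(self):
        if self.length == 0.0:
            raise ValueError("transect has zero length")
        if self.step <= 0:
            raise ValueError("sampling step must be > 0")

    @property
    def length(self) -> float:
        return math.hypot(self.x1 - self.x0, self.y1 - self.y0)


@dataclass
class JointIntensityHistogram:
    """Observed and independence-expected counts over binned two-channel intensities."""

    edges_a: np.ndarray
    edges_b: np.ndarray
    observed: np.ndarray      # (n_bins, n_bins) counts, channel A on axis 0
    expected: np.ndarray      # rowTotal * colTotal / total
    ratio: np.ndarray         # observed / expected where observed > 0, NaN elsewhere
    mask: np.ndarray          # True where observed == 0 (the grey cells)

    @property
    def n_pixels(self) -> int:
        return int(self.observed.sum())

    def to_dataframe(self) -> pd.DataFrame:
        ia, ib = np.meshgrid(np.arange(self.observed.shape[0]),
                             np.arange(self.observed.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "bin_a": ia.ravel(),
                "bin_b": ib.ravel(),
                "a_lo": self.edges_a[:-1][ia.ravel()],
                "b_lo": self.edges_b[:-1][ib.ravel()],
                "observed": self.observed.ravel(),
                "expected": self.expected.ravel(),
                "ratio": self.ratio.ravel(),
                "masked": self.mask.ravel(),
            }
        )

    def in_band_fraction(self, lo: float = 0.8, hi: float = 1.25) -> float:
        """Pixel-weighted fraction of the sample whose histogram cell has a
        ratio inside [lo, hi] (cells weighted by their observed count)."""
        ok = (~self.mask) & (self.ratio >= lo) & (self.ratio <= hi)
        return float(self.observed[ok].sum() / self.observed.sum())


def _bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo = float(values.min())
    hi = float(values.max())
    if hi <= lo:  # constant channel: one degenerate-but-valid bin span
        lo -= 0.5
        hi += 0.5
    return np.linspace(lo, hi, n_bins + 1)


def joint_obs_exp(image_a, image_b, n_bins: int = 32) -> JointIntensityHistogram:
    """Joint two-channel pixel histogram with its independence expectation.

    Equal-width bins span each channel's observed range. The expected count in
    cell (i, j) is rowTotal(i) * colTotal(j) / total, so the marginals of the
    expected grid equal the observed marginals and the totals agree exactly.
    The ratio observed/expected is reported where observed > 0; cells with no
    pixels are masked (the analysis cannot tell depletion from no data there).
    """
    a = _as_array(image_a).ravel()
    b = _as_array(image_b).ravel()
    if _as_array(image_a).shape != _as_array(image_b).shape:
        raise ValueError("channel images must have the same shape")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    edges_a = _bin_edges(a, n_bins)
    edges_b = _bin_edges(b, n_bins)
    observed, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
    total = observed.sum()
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    expected = np.outer(row, col) / total
    mask = observed == 0
    ratio = np.full_like(observed, np.nan)
    np.divide(observed, expected, out=ratio, where=~mask)
    return JointIntensityHistogram(edges_a, edges_b, observed, expected, ratio, mask)


def extract_profile(image, transect: Transect) -> np.ndarray:
    """Intensities sampled along a transect by bilinear interpolation.

    Samples sit at multiples of ``transect.step`` from the start point (the end
    point is included only when the length is a multiple of the step). Pixel
    centers are at integer coordinates; both endpoints must lie inside the
    image.
    """
    img = _as_array(image)
    h, w = img.shape
    for (x, y) in ((transect.x0, transect.y0), (transect.x1, transect.y1)):
        if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
            raise ValueError(f"transect endpoint ({x}, {y}) outside image bounds {w}x{h}")
    length = transect.length
    n = int(math.floor(length / transect.step + 1e-9))
    t = np.arange(n + 1) * (transect.step / length)
    xs = transect.x0 + t * (transect.x1 - transect.x0)
    ys = transect.y0 + t * (transect.y1 - transect.y0)
    return ndimage.map_coordinates(img, np.vstack([ys, xs]), order=1, mode="nearest")


@dataclass
class ProfileStack:
    """Transect profiles aligned on their maxima, with per-offset mean and sd."""

    offsets: np.ndarray       # integer sample offsets; 0 is each profile's argmax
    matrix: np.ndarray        # (n_profiles, n_offsets), NaN where a profile has no sample
    mean: np.ndarray          # per-offset mean (NaN where no profile has a sample)
    sd: np.ndarray            # per-offset sd, ddof=1 (NaN where < 2 profiles overlap)
    n: np.ndarray             # profiles contributing per offset

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean, "sd": self.sd, "n": self.n})


def center_and_summarize(profiles: Sequence[np.ndarray]) -> ProfileStack:
    """Align each profile so its maximum sits at offset 0 and summarize.

    Ties in the maximum go to the leftmost occurrence. The mean is reported
    wherever at least one profile has a sample; the sd needs at least two.
    Because transects differ in length, the aligned matrix is NaN-padded.
    """
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    peaks = [int(np.argmax(p)) for p in profiles]
    lo = -max(peaks)
    hi = max(len(p) - 1 - k for p, k in zip(profiles, peaks))
    offsets = np.arange(lo, hi + 1)
    mat = np.full((len(profiles), offsets.size), np.nan)
    for r, (p, k) in enumerate(zip(profiles, peaks)):
        start = -k - lo
        mat[r, start: start + len(p)] = p
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd = np.full(offsets.size, np.nan)
        enough = n >= 2
        if enough.any():
            sd[enough] = np.nanstd(mat[:, enough], axis=0, ddof=1)
    return ProfileStack(offsets=offsets, matrix=mat, mean=mean, sd=sd, n=n)


def background_normalize(values, background_sample) -> np.ndarray:
    """Subtract the mean of a background pixel sample; negative results stay.

    No clipping is applied: values below the background mean are noise and are
    informative as such.
    """
    bg = np.asarray(background_sample, dtype=float).ravel()
    if bg.size == 0:
        raise ValueError("background sample is empty")
    return np.asarray(values, dtype=float) - bg.mean()


def expression_difference(labeled_images: Sequence, control_images: Sequence,
                          labeled_masks: Optional[Sequence] = None,
                          control_masks: Optional[Sequence] = None) -> float:
    """Mean intensity over labeled cell pixels minus that over control cell pixels.

    Masks select the cell pixels of each image; without masks, whole images are
    pooled. Pixels are pooled across all images of a group before averaging.
    """
    def pooled(images, masks):
        chunks = []
        for i, img in enumerate(images):
            arr = _as_array(img)
            if masks is not None:
                m = np.asarray(masks[i], dtype=bool)
                if m.shape != arr.shape:
                    raise ValueError(f"mask {i} shape {m.shape} != image shape {arr.shape}")
                if not m.any():
                    raise ValueError(f"mask {i} selects no pixels")
                chunks.append(arr[m])
            else:
                chunks.append(arr.ravel())
        if not chunks:
            raise ValueError("need at least one image per group")
        return np.concatenate(chunks)

    return float(pooled(labeled_images, labeled_masks).mean()
                 - pooled(control_images, control_masks).mean())
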