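"""Seeded generators for every input the analyses consume, with ground truth.

Each generator emulates the statistical structure one analysis assumes, not the
visual texture of a real micrograph:

* ``gen_cell_field`` — fields of elongated cells, either bundle-like (chained,
  near-collinear rows with wrapped-normal orientation noise) or dispersed
  (uniform random axial orientations), for the alignment statistics;
* ``gen_dual_channel`` — two reporter intensity vectors driven by a latent cell
  state with tunable dependence from fully mutually exclusive (-1) through
  independent (0) to fully co-expressed (+1);
* ``gen_pole_image`` — rod-shaped cells in rows with Gaussian intensity peaks at
  the pole-to-pole junctions, plus matching pole-to-pole and side-to-side
  transects and a pure-background region;
* ``gen_loops`` — random-walk loop traces with near-straight baseline steps and
  inserted folds of controlled frequency and sharpness.

All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import CenterlineCell
from .fluorescence import Transect
from .folding import LoopTrace

__all__ = [
    "gen_cell_field",
    "gen_dual_channel",
    "gen_pole_image",
    "gen_loops",
    "expected_folded_mean_deg",
]


def expected_folded_mean_deg(angle_sd_deg: float, n_grid: int = 200_001) -> float:
    """Analytic mean axial difference between two cells with independent
    wrapped-normal orientation noise of the given sd (degrees).

    The difference of the two angles is normal with sd sqrt(2)*sigma; the axial
    difference folds it into [0, 90]. Computed by numerical integration over
    the wrapped difference (for sigma << 90 this approaches 2*sigma/sqrt(pi)).
    """
    if angle_sd_deg == 0:
        return 0.0
    sd = math.sqrt(2.0) * angle_sd_deg
    # integrate folded |delta| over the normal density, wrapping mod 180
    x = np.linspace(-8.0 * sd, 8.0 * sd, n_grid)
    dens = np.exp(-0.5 * (x / sd) ** 2) / (sd * math.sqrt(2.0 * math.pi))
    d = np.abs(x) % 180.0
    folded = np.minimum(d, 180.0 - d)
    return float(np.trapezoid(folded * dens, x))


def gen_cell_field(mode: str, n_cells: int = 200, mean_len: float = 30.0,
                   len_sd: float = 4.0, angle_sd: float = 5.0,
                   seed: Optional[int] = None):
    """Synthetic field of elongated cells for the alignment statistics.

    ``mode='bundle'`` chains cells pole-to-pole in parallel rows; each cell's
    axial orientation is the row direction plus wrapped-normal noise with sd
    ``angle_sd`` degrees. ``mode='dispersed'`` scatters cells uniformly with
    independent uniform axial orientations. Returns ``(cells, truth)`` where
    ``cells`` is a list of CenterlineCell (4-point straight centerlines) and
    ``truth`` records the drawn orientation and length per cell.

    Geometry is sized so that a 20-px neighborhood holds a handful of foreign
    -cell segments at the default density.
    """
    if mode not in ("bundle", "dispersed"):
        raise ValueError("mode must be 'bundle' or 'dispersed'")
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(seed)
    row_spacing = 6.0
    gap = 2.0

    lengths = np.clip(rng.normal(mean_len, len_sd, size=n_cells), mean_len * 0.3, None)

    cells = []
    thetas = np.empty(n_cells)

    if mode == "bundle":
        per_row = max(2, round(math.sqrt(row_spacing * n_cells / mean_len) * 2))
        theta_noise = rng.normal(0.0, angle_sd, size=n_cells)
        for i in range(n_cells):
            row, col = divmod(i, per_row)
            th = theta_noise[i] % 180.0
            thetas[i] = th
            if col == 0:
                cursor = np.array([5.0, 5.0 + row * row_spacing])
            ang = math.radians(theta_noise[i])
            u = np.array([math.cos(ang), math.sin(ang)])
            start = cursor
            end = start + lengths[i] * u
            pts = start + np.linspace(0.0, 1.0, 4)[:, None] * (end - start)
            cells.append(CenterlineCell(f"cell_{i:04d}", pts))
            cursor = end + gap * np.array([1.0, 0.0])
    else:
        side = math.sqrt(n_cells * mean_len * row_spacing)
        centers = rng.uniform(0.0, side, size=(n_cells, 2))
        th = rng.uniform(0.0, 180.0, size=n_cells)
        thetas[:] = th
        for i in range(n_cells):
            ang = math.radians(th[i])
            u = np.array([math.cos(ang), math.sin(ang)])
            start = centers[i] - 0.5 * lengths[i] * u
            end = centers[i] + 0.5 * lengths[i] * u
            pts = start + np.linspace(0.0, 1.0, 4)[:, None] * (end - start)
            cells.append(CenterlineCell(f"cell_{i:04d}", pts))

    truth = {
        "mode": mode,
        "angle_sd": float(angle_sd),
        "theta_deg": thetas.tolist(),
        "length_px": lengths.tolist(),
    }
    return cells, truth


def gen_dual_channel(n_pixels: int = 100_000, exclusivity: float = 0.0,
                     noise_sd: float = 8.0, seed: Optional[int] = None,
                     low: float = 20.0, high: float = 100.0):
    """Two reporter intensity vectors with tunable dependence.

    Each pixel carries two latent binary states (one per channel). With
    probability ``|exclusivity|`` the states are coupled — opposite for
    negative values (mutually exclusive cell types), equal for positive ones —
    and independent otherwise. Intensities are ``low`` or ``high`` plus
    Gaussian noise, clipped at zero. Returns ``(a, b, truth)``.
    """
    if n_pixels < 100:
        raise ValueError("n_pixels must be >= 100")
    if not -1.0 <= exclusivity <= 1.0:
        raise ValueError("exclusivity must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    za = rng.random(n_pixels) < 0.5
    coupled = rng.random(n_pixels) < abs(exclusivity)
    zb_free = rng.random(n_pixels) < 0.5
    zb_coupled = za if exclusivity >= 0 else ~za
    zb = np.where(coupled, zb_coupled, zb_free)
    a = np.clip(low + (high - low) * za + rng.normal(0.0, noise_sd, n_pixels), 0.0, None)
    b = np.clip(low + (high - low) * zb + rng.normal(0.0, noise_sd, n_pixels), 0.0, None)
    truth = {
        "exclusivity": float(exclusivity),
        "low": float(low),
        "high": float(high),
        "noise_sd": float(noise_sd),
        "frac_high_high": float(np.mean(za & zb)),
    }
    return a, b, truth


def gen_pole_image(n_cells: int = 24, peak_height: float = 100.0,
                   background: float = 50.0, noise_sd: float = 0.0,
                   seed: Optional[int] = None, cell_len: int = 20,
                   cell_width: int = 7, peak_sigma: float = 1.5,
                   body_contrast: float = 0.0):
    """Image of rod cells in rows with intensity peaks at pole-to-pole junctions.

    Cells are horizontal rods chained in rows; at every junction between two
    consecutive cells a Gaussian peak of amplitude ``peak_height`` (above the
    local level) is added at an integer pixel position. The cell body adds
    ``body_contrast`` over the background (0 by default so that a centered
    pole-to-pole profile recovers exactly ``peak_height`` after background
    normalization). Additive Gaussian noise with sd ``noise_sd`` is applied
    last, clipped at zero.

    Returns ``(image, transects, background_mask, truth)``: pole-to-pole
    ("major") transects centered on each junction, side-to-side ("minor")
    transects crossing mid-cell, and a boolean mask of pure-background pixels.
    """
    if n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    rng = np.random.default_rng(seed)
    per_row = max(2, math.ceil(math.sqrt(n_cells)))
    n_rows = math.ceil(n_cells / per_row)
    margin = 20
    row_spacing = 3 * cell_width
    width = margin * 2 + per_row * cell_len
    height = margin * 2 + (n_rows - 1) * row_spacing + cell_width

    img = np.full((height, width), float(background))
    body = np.zeros_like(img, dtype=bool)

    junctions = []
    transects = []
    half_w = cell_width // 2
    placed = 0
    for r in range(n_rows):
        yc = margin + r * row_spacing
        n_in_row = min(per_row, n_cells - placed)
        if n_in_row <= 0:
            break
        x0 = margin
        for c in range(n_in_row):
            xa = x0 + c * cell_len
            body[yc - half_w: yc + half_w + 1, xa: xa + cell_len] = True
            # side-to-side transect across the cell middle
            xm = xa + cell_len // 2
            transects.append(Transect(xm, yc - (cell_width + 4), xm, yc + cell_width + 4, kind="minor"))
            if c >= 1:  # junction with the previous cell in the row
                junctions.append((xa, yc))
                transects.append(Transect(xa - cell_len // 2, yc, xa + cell_len // 2, yc, kind="major"))
        placed += n_in_row

    img += body_contrast * body
    yy, xx = np.mgrid[0:height, 0:width]
    for (jx, jy) in junctions:
        img += peak_height * np.exp(-((xx - jx) ** 2 + (yy - jy) ** 2) / (2.0 * peak_sigma ** 2))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, None)

    bg_mask = np.zeros_like(body)
    bg_mask[: margin // 2, :] = True  # strip far above the first row of cells

    truth = {
        "peak_height": float(peak_height),
        "background": float(background),
        "noise_sd": float(noise_sd),
        "peak_sigma": float(peak_sigma),
        "body_contrast": float(body_contrast),
        "junctions_xy": [[int(x), int(y)] for (x, y) in junctions],
    }
    return img, transects, bg_mask, truth


def gen_loops(n_loops: int = 5, fold_rate: float = 40.0,
              fold_angle_mean: float = 150.0, fold_angle_sd: float = 8.0,
              seed: Optional[int] = None, n_segments: int = 100,
              step_len: float = 10.0, jitter_sd: float = 2.0):
    """Random-walk loop traces with inserted folds.

    Each trace takes ``n_segments`` steps of length ``step_len``. Folds are
    inserted at exactly ``round(fold_rate/100 * n_vertices)`` randomly chosen
    interior vertices per loop (stratified placement, so the fold frequency is
    the stated one rather than a binomial draw around it): a folded vertex gets
    an angle drawn from Normal(fold_angle_mean, fold_angle_sd) (clipped to
    (5, 180]) with random turn direction; elsewhere the heading jitters by
    Normal(0, jitter_sd) degrees. Returns ``(traces, true_angles)`` with the
    drawn vertex angles pooled over all loops.
    """
    if fold_rate < 0:
        raise ValueError("fold_rate must be >= 0")
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    rng = np.random.default_rng(seed)
    traces = []
    true_angles = []
    n_vertices = n_segments - 1
    n_folds = min(n_vertices, round(fold_rate / 100.0 * n_vertices))
    for ln in range(n_loops):
        fold_at = set(rng.choice(n_vertices, size=n_folds, replace=False).tolist())
        heading = rng.uniform(0.0, 360.0)
        pos = np.zeros(2)
        pts = [pos.copy()]
        for s in range(n_segments):
            if s > 0:
                if (s - 1) in fold_at:
                    ang = float(np.clip(rng.normal(fold_angle_mean, fold_angle_sd), 5.0, 180.0))
                    turn = (180.0 - ang) * (1.0 if rng.random() < 0.5 else -1.0)
                else:
                    turn = float(rng.normal(0.0, jitter_sd))
                    ang = 180.0 - abs(turn)
                heading += turn
                true_angles.append(ang)
            rad = math.radians(heading)
            pos = pos + step_len * np.array([math.cos(rad), math.sin(rad)])
            pts.append(pos.copy())
        traces.append(LoopTrace(f"loop_{ln:03d}", np.array(pts), closed=False))
    return traces, np.array(true_angles)
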