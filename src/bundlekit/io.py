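"""Readers and writers for the plain-text interchange formats, plus run manifests.

Conventions used everywhere: pixel centers sit at integer coordinates, origin
top-left, y increasing downward (image convention); CSV is the primary format;
every CLI run writes a JSON manifest echoing its configuration, seed, package
version, and a SHA-256 checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .alignment import CenterlineCell
from .fluorescence import IntensityImage, Transect
from .folding import LoopTrace

__all__ = [
    "read_centerlines",
    "write_centerlines",
    "read_image",
    "write_image",
    "read_transects",
    "write_transects",
    "read_loops",
    "write_loops",
    "read_sim_config",
    "write_sim_config",
    "write_run_manifest",
    "read_run_manifest",
]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _check_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise ParseError(f"{path}: non-numeric value {df[c].iloc[row]!r} in column {c!r} at row {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise ParseError(f"{path}: missing value in column {c!r} at row {row}")
        df[c] = coerced
    return df


# ---------------------------------------------------------------------------
# centerlines (cell_id, point_index, x, y)
# ---------------------------------------------------------------------------

def read_centerlines(path) -> list:
    """Read segmented-cell centerlines from CSV or JSON.

    CSV columns: cell_id, point_index, x, y (row order irrelevant). JSON: a
    list of objects with ``cell_id`` and ``points`` ([[x, y], ...]).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        return [CenterlineCell(str(rec["cell_id"]), np.asarray(rec["points"], dtype=float))
                for rec in raw]
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["cell_id", "point_index", "x", "y"], path)
    df = _check_numeric(df, ["point_index", "x", "y"], path)
    dup = df.duplicated(subset=["cell_id", "point_index"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ParseError(f"{path}: duplicate (cell_id, point_index) at row {row}")
    cells = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("point_index")
        cells.append(CenterlineCell(str(cid), grp[["x", "y"]].to_numpy()))
    return cells


def write_centerlines(cells: Sequence[CenterlineCell], path) -> None:
    rows = []
    for c in cells:
        for i, (x, y) in enumerate(c.points):
            rows.append({"cell_id": c.cell_id, "point_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# images (grayscale TIFF)
# ---------------------------------------------------------------------------

def read_image(path, plane: Optional[int] = None) -> IntensityImage:
    """Read a grayscale (8/16-bit or float) TIFF; multi-plane files need ``plane``."""
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        if plane is None:
            raise ValueError(f"{path}: multi-plane image; select a plane")
        arr = arr[plane]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else None
    return IntensityImage(data=arr, bit_depth=bit_depth, source=str(path))


def write_image(path, data: np.ndarray, dtype=np.uint16) -> None:
    arr = np.asarray(data)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        arr = np.clip(np.rint(arr), info.min, info.max)
    tifffile.imwrite(path, arr.astype(dtype))


# ---------------------------------------------------------------------------
# transects (x0, y0, x1, y1, class)
# ---------------------------------------------------------------------------

def read_transects(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["x0", "y0", "x1", "y1", "class"], path)
    df = _check_numeric(df, ["x0", "y0", "x1", "y1"], path)
    return [Transect(row["x0"], row["y0"], row["x1"], row["y1"], kind=str(row["class"]))
            for _, row in df.iterrows()]


def write_transects(transects: Sequence[Transect], path) -> None:
    pd.DataFrame(
        [{"x0": t.x0, "y0": t.y0, "x1": t.x1, "y1": t.y1, "class": t.kind} for t in transects]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loop traces (loop_id, point_index, x, y, closed)
# ---------------------------------------------------------------------------

def read_loops(path) -> list:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["loop_id", "point_index", "x", "y", "closed"], path)
    df = _check_numeric(df, ["point_index", "x", "y"], path)
    dup = df.duplicated(subset=["loop_id", "point_index"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ParseError(f"{path}: duplicate (loop_id, point_index) at row {row}")
    loops = []
    for lid, grp in df.groupby("loop_id", sort=True):
        grp = grp.sort_values("point_index")
        closed = bool(grp["closed"].iloc[0])
        loops.append(LoopTrace(str(lid), grp[["x", "y"]].to_numpy(), closed=closed))
    return loops


def write_loops(loops: Sequence[LoopTrace], path) -> None:
    rows = []
    for lp in loops:
        for i, (x, y) in enumerate(lp.points):
            rows.append({"loop_id": lp.loop_id, "point_index": i, "x": x, "y": y,
                         "closed": lp.closed})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulator config (key = value)
# ---------------------------------------------------------------------------

_INT_KEYS = {"N", "T", "seed"}
_FLOAT_KEYS = {"G", "S", "B", "k", "w", "p_turn", "L0"}


def read_sim_config(path) -> dict:
    """Parse a ``key = value`` simulator config (# starts a comment)."""
    out = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}: line {ln}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key in _INT_KEYS:
                out[key] = int(val)
            elif key in _FLOAT_KEYS:
                out[key] = float(val)
            else:
                raise ParseError(f"{path}: line {ln}: unknown parameter {key!r}")
    return out


def write_sim_config(params, path) -> None:
    with open(path, "w") as fh:
        for key in ("N", "T", "G", "S", "B", "k", "w", "p_turn", "L0", "seed"):
            fh.write(f"{key} = {getattr(params, key)!r}\n")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(config: dict, outputs: Sequence, out_dir, name: str = "manifest.json") -> Path:
    """Write a JSON manifest with the config echo, seed, version and checksums.

    Every path in ``outputs`` must exist. Deliberately contains no timestamp so
    identically seeded runs produce byte-identical manifests.
    """
    from . import __version__

    out_dir = Path(out_dir)
    checksums = {}
    for p in outputs:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"manifest: output file missing: {p}")
        checksums[p.name] = _sha256(p)
    manifest = {
        "version": __version__,
        "config": config,
        "seed": config.get("seed"),
        "outputs": checksums,
    }
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def read_run_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
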