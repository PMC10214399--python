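"""File I/O in fixed dialects: polyline CSV, trajectory/series CSV, TIFF
stacks, YAML configs and reproducibility manifests.

Coordinate convention: 0-based, micrometres, y increasing downward (image
convention). CSV files are comma-separated UTF-8 with a header row and '.'
decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .boundary_quant import Polyline
from .dh_estimation import ProfileSeries
from .errors import ConfigurationError, FormatError, ParameterError
from .simulators import Trajectory

__all__ = [
    "read_polylines",
    "write_polylines",
    "write_trajectory",
    "read_profile_series",
    "write_profile_series",
    "read_tiff",
    "write_tiff",
    "max_project",
    "load_config",
    "validate_config_keys",
    "write_manifest",
]

NATIVE_COLUMNS = ["segment_id", "point_index", "x_um", "y_um"]
# ridge-detection export dialect (extra columns like Length/Contrast ignored)
RIDGE_COLUMNS = {"contour id": "segment_id", "pos.": "point_index",
                 "x": "x_um", "y": "y_um"}


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df


def read_polylines(path, dialect: str = "auto") -> list[Polyline]:
    """Read boundary polylines from CSV.

    ``native`` dialect: columns segment_id, point_index, x_um, y_um with
    point_index contiguous from 0 within each segment. ``ridge`` dialect: the
    ridge-detection export (Contour ID, Pos., X, Y; other columns ignored).
    ``auto`` picks whichever header matches. Segments are returned ordered by
    id.
    """
    df = _read_csv(path)
    lower = {c.strip().lower(): c for c in df.columns}

    def has_native() -> bool:
        return all(c in df.columns for c in NATIVE_COLUMNS)

    def has_ridge() -> bool:
        return all(c in lower for c in RIDGE_COLUMNS)

    if dialect == "auto":
        dialect = "native" if has_native() else "ridge" if has_ridge() else "native"
    if dialect == "native":
        missing = [c for c in NATIVE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        table = df[NATIVE_COLUMNS].copy()
    elif dialect == "ridge":
        missing = [c for c in RIDGE_COLUMNS if c not in lower]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        table = df[[lower[c] for c in RIDGE_COLUMNS]].copy()
        table.columns = list(RIDGE_COLUMNS.values())
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    if not np.all(np.isfinite(table[["x_um", "y_um"]].to_numpy(dtype=float))):
        raise FormatError(f"{path}: non-finite coordinates")
    polylines = []
    for seg_id, g in table.groupby("segment_id", sort=True):
        idx = g["point_index"].to_numpy()
        order = np.argsort(idx)
        idx = idx[order]
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(
                f"{path}: segment {seg_id!r}: point_index not contiguous from 0"
            )
        pts = g[["x_um", "y_um"]].to_numpy(dtype=float)[order]
        polylines.append(Polyline(segment_id=seg_id, points=pts))
    return polylines


def write_polylines(path, polylines: Sequence[Polyline]) -> None:
    """Write polylines in the native dialect (round-trips with
    :func:`read_polylines` up to float formatting)."""
    rows = []
    for p in polylines:
        for j, (x, y) in enumerate(p.points):
            rows.append((p.segment_id, j, x, y))
    pd.DataFrame(rows, columns=NATIVE_COLUMNS).to_csv(path, index=False)


def write_trajectory(path, traj: Trajectory) -> None:
    """Serialize a trajectory as long-form CSV with columns time, x, h."""
    t = np.repeat(traj.times, traj.grid.n_points)
    x = np.tile(traj.grid.x, traj.times.size)
    pd.DataFrame({"time": t, "x": x, "h": traj.profiles.ravel()}).to_csv(
        path, index=False
    )


def write_profile_series(path, series: Sequence[ProfileSeries]) -> None:
    """Serialize boundary time series as CSV (time, segment_id, x, h)."""
    frames = []
    for s in series:
        n = s.profiles.shape[1]
        frames.append(pd.DataFrame({
            "time": np.repeat(s.times, n),
            "segment_id": s.segment_id,
            "x": np.tile(np.arange(n) * s.dx, s.times.size),
            "h": s.profiles.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profile_series(path) -> list[ProfileSeries]:
    """Read boundary time series (columns time, segment_id, x, h); the site
    spacing dx is inferred from the x grid, which must be uniform."""
    df = _read_csv(path)
    missing = [c for c in ("time", "segment_id", "x", "h") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    out = []
    for seg_id, g in df.groupby("segment_id", sort=True):
        times = np.sort(g["time"].unique())
        xs = np.sort(g["x"].unique())
        dxs = np.diff(xs)
        if xs.size < 3 or not np.allclose(dxs, dxs[0], rtol=1e-6):
            raise FormatError(f"{path}: segment {seg_id!r}: non-uniform x grid")
        piv = g.pivot_table(index="time", columns="x", values="h", sort=True)
        if piv.isna().any().any():
            raise FormatError(f"{path}: segment {seg_id!r}: missing (time, x) samples")
        out.append(ProfileSeries(times=times, profiles=piv.to_numpy(),
                                 dx=float(dxs[0]), segment_id=seg_id))
    return out


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_tiff(path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the leading (z) axis of a volume."""
    arr = np.asarray(stack)
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ParameterError("stack must be 3-D with >= 1 plane")
    return arr.max(axis=0)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def validate_config_keys(cfg: dict, allowed: Sequence[str]) -> dict:
    unknown = sorted(set(cfg) - set(allowed))
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    return cfg


def write_manifest(path, command: str, config: dict, seed: int | None) -> None:
    """Reproducibility manifest: the command, its full parameterization, the
    seed and library versions — enough to regenerate the output."""
    import scipy

    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "versions": {
            "interdigit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n",
                          encoding="utf-8")
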