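"""Readers and writers for centerline tables, kymograms, masks and manifests.

Everything is plain text: centerlines and kymograms as CSV (comma separator,
'.' decimal, UTF-8, header row), configs and sidecars as JSON.  Units are
fixed -- seconds, millimetres, dimensionless curvature (kappa*L) -- and are
recorded in every kymogram sidecar to prevent unit drift.  Round trips are
lossless to well below 1e-9.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig, StimulusMask
from .errors import SchemaError, ValidationError
from .kinematics import CenterlineSeries, CurvatureMap

SCHEMA_VERSION = 1
CENTERLINE_COLUMNS = ["frame_index", "time_s", "point_index", "x_mm", "y_mm"]
#: Allowed relative jitter of frame timestamps around the median interval.
TIME_JITTER_TOLERANCE = 0.01


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


# ---------------------------------------------------------------------------
# centerlines


def read_centerlines(path) -> CenterlineSeries:
    """Read a long-format centerline CSV into a :class:`CenterlineSeries`.

    Required columns: frame_index, time_s, point_index, x_mm, y_mm.  Frames
    must be uniformly sampled (<= 1% timestamp jitter); point counts may
    vary between frames (profiles are resampled downstream).
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"centerline file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in CENTERLINE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("x_mm", "y_mm", "time_s"):
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: one for the header line, one for 0-based indexing
            raise SchemaError(f"{path}: NaN in column '{col}' at CSV row {bad[0] + 2}")
    frames, times = [], []
    for fidx, g in df.groupby("frame_index", sort=True):
        pi = g["point_index"].to_numpy()
        if np.any(np.diff(pi) <= 0):
            row = g.index[np.flatnonzero(np.diff(pi) <= 0)[0] + 1] + 2
            raise SchemaError(
                f"{path}: non-monotone point_index in frame {fidx} at CSV row {row}"
            )
        t = g["time_s"].unique()
        if t.size != 1:
            raise SchemaError(f"{path}: frame {fidx} has inconsistent time_s values")
        frames.append(g[["x_mm", "y_mm"]].to_numpy(dtype=float))
        times.append(float(t[0]))
    times = np.asarray(times)
    if len(frames) >= 2:
        dt = np.diff(times)
        med = float(np.median(dt))
        if med <= 0:
            raise SchemaError(f"{path}: frame times are not increasing")
        if np.any(np.abs(dt / med - 1.0) > TIME_JITTER_TOLERANCE):
            raise SchemaError(
                f"{path}: frame timestamps deviate more than "
                f"{TIME_JITTER_TOLERANCE:.0%} from uniform sampling"
            )
        rate = 1.0 / med
    else:
        rate = 1.0
    return CenterlineSeries(frames=frames, sampling_rate=rate, times=times)


def write_centerlines(series: CenterlineSeries, path) -> Path:
    """Write a :class:`CenterlineSeries` as a long-format CSV."""
    path = Path(path)
    rows = []
    for i, (frame, t) in enumerate(zip(series.frames, series.times)):
        for p, (x, y) in enumerate(frame):
            rows.append((i, t, p, x, y))
    df = pd.DataFrame(rows, columns=CENTERLINE_COLUMNS)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


# ---------------------------------------------------------------------------
# kymograms


def write_kymogram(cmap: CurvatureMap, path) -> Path:
    """Write a kymogram as CSV (first column time, columns body coords) plus
    a JSON sidecar (``<path>.meta.json``) with sampling rate, worm length,
    units and provenance metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cmap.values, columns=[f"{c:.6f}" for c in cmap.body_coords])
    df.insert(0, "time_s", cmap.times)
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "sampling_rate_hz": cmap.sampling_rate,
        "worm_length_mm": cmap.worm_length,
        "units": {"time": "s", "body_coord": "percent body length",
                  "curvature": "dimensionless (kappa * L)"},
        "meta": cmap.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_kymogram(path) -> CurvatureMap:
    """Read a kymogram CSV written by :func:`write_kymogram`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"kymogram file not found: {path}")
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise SchemaError(f"missing kymogram sidecar: {side_path}")
    try:
        side = json.loads(side_path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"corrupted kymogram sidecar {side_path}: {exc}") from exc
    for key in ("sampling_rate_hz", "worm_length_mm"):
        if key not in side:
            raise SchemaError(f"kymogram sidecar {side_path} lacks field '{key}'")
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise SchemaError(f"{path}: first column must be 'time_s'")
    try:
        coords = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SchemaError(f"{path}: body-coordinate header is not numeric: {exc}") from exc
    return CurvatureMap(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        times=df["time_s"].to_numpy(dtype=float),
        body_coords=coords,
        sampling_rate=float(side["sampling_rate_hz"]),
        worm_length=float(side["worm_length_mm"]),
        meta=side.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# stimulus masks


def read_mask_config(path) -> list[StimulusMask]:
    """Read stimulus masks from JSON: either a list of mask objects or an
    object with a ``"masks"`` list."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"mask config not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if isinstance(data, dict):
        data = data.get("masks")
        if data is None:
            raise SchemaError(f"{path}: expected a 'masks' list")
    if not isinstance(data, list):
        raise SchemaError(f"{path}: mask config must be a list of mask objects")
    masks = []
    for i, entry in enumerate(data):
        try:
            masks.append(StimulusMask.from_dict(dict(entry)))
        except (ValidationError, TypeError) as exc:
            raise SchemaError(f"{path}: invalid mask #{i}: {exc}") from exc
    return masks


# ---------------------------------------------------------------------------
# run manifests


def _hash_config(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written alongside every command-line analysis."""

    config_hash: str
    seed: int | None
    software_version: str
    created_utc: str
    inputs: list
    outputs: list
    thresholds: dict
    config: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def create(cls, config: dict, seed=None, inputs=(), outputs=(), thresholds=None):
        from . import __version__

        return cls(
            config_hash=_hash_config(config),
            seed=seed,
            software_version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(),
            inputs=[str(p) for p in inputs],
            outputs=[str(p) for p in outputs],
            thresholds=dict(thresholds or {}),
            config=config,
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def simconfig_from_json(path) -> SimConfig:
    """Read a :class:`SimConfig` (with inline masks) from a JSON file."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"simulator config not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: simulator config must be a JSON object")
    return SimConfig.from_dict(data)
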