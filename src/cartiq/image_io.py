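"""Stack, decay-cube and metric-table I/O plus acquisition-intensity normalization.

Images travel as multi-page TIFF files with a JSON sidecar (``<path>.json``)
carrying voxel size, channel and optional laser power; tables travel as CSV.
Axis order is (z, y, x) with y increasing downward from the articular surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("NADH", "FAD", "XLINK", "SHG", "OTHER")

#: Default laser repetition period (ns) used when metadata does not state one.
DEFAULT_REP_PERIOD_NS = 12.5


class MetadataError(ValueError):
    """Raised when required image metadata is missing or inconsistent."""


@dataclass
class VolumetricImage:
    """One channel's 3D intensity stack.

    Parameters
    ----------
    intensities : ndarray, shape (z, y, x)
        Non-negative intensities. 2D input is promoted to a single z plane.
    voxel_size : tuple of float
        Voxel edge length in µm per axis, ordered (z, y, x).
    channel : str
        One of ``NADH, FAD, XLINK, SHG, OTHER``.
    power : float, optional
        Incident laser power (arbitrary units) if recorded and not yet
        consumed by :func:`normalize_power`.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = "OTHER"
    power: Optional[float] = None
    power_normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise ValueError(f"expected 2D or 3D intensities, got ndim={arr.ndim}")
        if arr.size and float(arr.min()) < 0:
            raise ValueError("intensities must be non-negative")
        self.intensities = arr
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values, got {self.voxel_size}")
        self.voxel_size = vs
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class DecayCube:
    """Per-pixel time-binned photon counts from a TCSPC acquisition.

    ``counts`` has shape (time-bin, y, x); ``bin_width`` and ``rep_period``
    are in ns and must satisfy ``n_bins * bin_width <= rep_period`` (within
    float tolerance).
    """

    counts: np.ndarray
    bin_width: float
    rep_period: float = DEFAULT_REP_PERIOD_NS
    channel: str = "OTHER"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 3:
            raise ValueError(f"counts must be 3D (bin, y, x), got ndim={arr.ndim}")
        if arr.size and float(arr.min()) < 0:
            raise ValueError("photon counts must be non-negative")
        self.counts = arr
        if self.bin_width <= 0 or self.rep_period <= 0:
            raise ValueError("bin_width and rep_period must be positive")
        if arr.shape[0] * self.bin_width > self.rep_period * (1 + 1e-9):
            raise ValueError(
                f"{arr.shape[0]} bins x {self.bin_width} ns exceed the "
                f"{self.rep_period} ns repetition period"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if arr.size and arr.sum() == 0 and "empty" not in self.flags:
            self.flags.append("empty")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        """Time-bin center positions in ns."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_stack(img: VolumetricImage, path) -> None:
    """Write a stack as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, img.intensities, photometric="minisblack")
    meta = {
        "voxel_size_um": list(img.voxel_size),
        "channel": img.channel,
        "power": img.power,
        "power_normalized": img.power_normalized,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> VolumetricImage:
    """Read a multi-page TIFF stack; single-page files become a z=1 stack."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise MetadataError(f"sidecar {sidecar} lacks 'voxel_size_um'")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise MetadataError(f"pages of {path} do not form a uniform 3D stack")
    return VolumetricImage(
        intensities=arr,
        voxel_size=tuple(meta["voxel_size_um"]),
        channel=meta.get("channel", "OTHER"),
        power=meta.get("power"),
        power_normalized=bool(meta.get("power_normalized", False)),
    )


def write_decay_cube(cube: DecayCube, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, cube.counts, photometric="minisblack")
    meta = {
        "bin_width_ns": cube.bin_width,
        "rep_period_ns": cube.rep_period,
        "n_bins": cube.n_bins,
        "channel": cube.channel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_decay_cube(path) -> DecayCube:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("bin_width_ns", "rep_period_ns"):
        if key not in meta:
            raise MetadataError(f"sidecar {sidecar} lacks {key!r}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if "n_bins" in meta and arr.shape[0] != meta["n_bins"]:
        raise MetadataError(
            f"{path} holds {arr.shape[0]} time bins but the sidecar declares {meta['n_bins']}"
        )
    return DecayCube(
        counts=arr,
        bin_width=float(meta["bin_width_ns"]),
        rep_period=float(meta["rep_period_ns"]),
        channel=meta.get("channel", "OTHER"),
    )


def normalize_power(img: VolumetricImage) -> VolumetricImage:
    """Divide intensities by the square of the incident laser power.

    The power field is consumed so the normalization cannot be applied twice.
    """
    if img.power_normalized:
        raise ValueError("stack already power-normalized")
    if img.power is None:
        raise MetadataError("no laser power recorded; cannot normalize")
    if img.power <= 0:
        raise ValueError(f"laser power must be positive, got {img.power}")
    return replace(
        img,
        intensities=img.intensities.astype(float) / img.power**2,
        power=None,
        power_normalized=True,
    )


# ---------------------------------------------------------------------------
# Metric tables

KEY_COLUMNS = ["specimen", "group", "time_point", "zone", "field_id"]
METRIC_COLUMNS = [
    "variance",
    "xlink_density",
    "xlink_llif",
    "redox_ratio",
    "nadh_llif",
    "beta",
]
#: Metric columns constrained to the unit interval by definition.
UNIT_INTERVAL_METRICS = ("variance", "xlink_llif", "redox_ratio", "nadh_llif")


def _validate_metrics(df: pd.DataFrame) -> None:
    missing = [c for c in KEY_COLUMNS + METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    for col in METRIC_COLUMNS:
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))].tolist()
        if bad:
            raise ValueError(f"non-finite values in metric column {col!r} at rows {bad}")
    for col in UNIT_INTERVAL_METRICS:
        vals = df[col].to_numpy(dtype=float)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError(f"metric column {col!r} must lie in [0, 1]")
    dup = df.duplicated(subset=["field_id", "zone"])
    if dup.any():
        raise ValueError(
            f"duplicate (field_id, zone) keys at rows {df.index[dup].tolist()}"
        )


def write_metrics(df: pd.DataFrame, path) -> None:
    """Write a per-field metric table as CSV with a fixed column order."""
    if len(df):
        _validate_metrics(df)
    else:
        df = pd.DataFrame(columns=KEY_COLUMNS + METRIC_COLUMNS)
    extra = [c for c in df.columns if c not in KEY_COLUMNS + METRIC_COLUMNS]
    df[KEY_COLUMNS + METRIC_COLUMNS + extra].to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        _validate_metrics(df)
    return df


def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
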