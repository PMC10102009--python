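"""Surface alignment, zonal segmentation and matrix/cell/cytoplasm masks.

Zones are assigned per depth row (y), matching the banded anatomy of
articular cartilage: superficial fibers run parallel to the surface,
radial fibers perpendicular, transitional fibers are dispersed, and the
calcified zone sits below the dark endplate line in the SHG channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .fiber3d import OrientationField
from .image_io import VolumetricImage

ZONE_CODES = {
    "background": 0,
    "superficial": 1,
    "transitional": 2,
    "radial": 3,
    "calcified": 4,
}
ZONE_NAMES = {v: k for k, v in ZONE_CODES.items()}

#: Angular tolerance (deg) for the superficial/radial per-row rules.
DEFAULT_ANGLE_TOL = 25.0
#: Endplate darkness factor: rows darker than this fraction of the cartilage
#: median row intensity count as endplate candidates.
DEFAULT_ENDPLATE_FACTOR = 0.2
#: Percentiles of cell-region NAD(P)H used to strip dark nuclei (low) and
#: bright lipofuscin (high) from the cytoplasm mask.
DEFAULT_NUCLEUS_PCT = 20.0
DEFAULT_LIPOFUSCIN_PCT = 98.0
#: Flat per-row evidence penalty: an aligned-zone call must beat this after
#: the angular margin, or the row defaults to transitional.
DEFAULT_MIN_ROW_EVIDENCE = 0.1


@dataclass
class ZoneLabelMap:
    """Per-voxel zone labels (see :data:`ZONE_CODES`)."""

    labels: np.ndarray
    flags: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def mask(self, zone: str) -> np.ndarray:
        return self.labels == ZONE_CODES[zone]

    @property
    def cartilage(self) -> np.ndarray:
        return self.labels != ZONE_CODES["background"]


@dataclass
class CompartmentMasks:
    """Matrix / cell / cytoplasm-only compartments; matrix and cell are
    disjoint and cytoplasm is a subset of cell."""

    matrix_mask: np.ndarray
    cell_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    flags: list[str] = field(default_factory=list)


def _surface_points(mip: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Topmost foreground row per column of a (y, x) projection."""
    if mip.max() <= 0:
        raise ValueError("no SHG-positive region found")
    thr = threshold_otsu(mip)
    fg = mip > thr
    if not fg.any():
        raise ValueError("no SHG-positive region found")
    cols = np.flatnonzero(fg.any(axis=0))
    tops = np.array([np.argmax(fg[:, c]) for c in cols])
    return cols, tops, fg


def align_surface(shg: VolumetricImage) -> tuple[VolumetricImage, float]:
    """Rotate a stack in-plane so the articular surface is horizontal.

    The surface is the topmost SHG-positive row per column of the z maximum
    projection; a line is fitted to those points and the stack rotated by its
    inclination.  Returns the rotated stack and the applied angle in degrees.
    """
    if shg.channel != "SHG":
        raise ValueError(f"surface alignment expects the SHG channel, got {shg.channel}")
    mip = shg.intensities.max(axis=0)
    cols, tops, fg = _surface_points(mip)
    if len(cols) < max(8, mip.shape[1] // 4):
        raise ValueError("no SHG-positive region found")
    if np.median(tops) < 2:
        raise ValueError(
            "no background band above the SHG-positive region; surface not visible"
        )

    # trimmed least squares: corner clipping and speckle produce top-row
    # outliers that bias a single pass badly
    slope, intercept = np.polyfit(cols, tops, 1)
    for _ in range(3):
        res = tops - (slope * cols + intercept)
        mad = np.median(np.abs(res - np.median(res))) + 1e-9
        keep = np.abs(res - np.median(res)) < 4 * mad
        if keep.sum() < 8:
            break
        slope, intercept = np.polyfit(cols[keep], tops[keep], 1)

    # a coherent surface has almost no foreground above the fitted line
    above = fg & (
        np.arange(mip.shape[0])[:, None]
        < intercept + slope * np.arange(mip.shape[1])[None, :] - 2
    )
    if above.sum() > 0.2 * fg.sum():
        raise ValueError("SHG-positive region is not bounded by a surface line")

    angle = float(np.degrees(np.arctan(slope)))
    if abs(angle) < 1e-6:
        return shg, 0.0
    rotated = ndimage.rotate(
        shg.intensities, angle, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
    )
    rotated = np.clip(rotated, 0.0, None)
    out = VolumetricImage(
        intensities=rotated,
        voxel_size=shg.voxel_size,
        channel=shg.channel,
        power=shg.power,
        power_normalized=shg.power_normalized,
    )
    return out, angle


def segment_zones(
    shg: VolumetricImage,
    orient: OrientationField,
    overrides: Optional[ZoneLabelMap] = None,
    angle_tol: float = DEFAULT_ANGLE_TOL,
    endplate_factor: float = DEFAULT_ENDPLATE_FACTOR,
    min_endplate_rows: int = 2,
    min_row_evidence: float = DEFAULT_MIN_ROW_EVIDENCE,
) -> ZoneLabelMap:
    """Partition a surface-aligned stack into depth-ordered cartilage zones.

    Each cartilage row is classified from the circular mean of its in-plane
    fiber angles: near 0/180 deg is superficial, near 90 deg radial, anything
    else transitional; the calcified zone is every row at and below the
    deepest contiguous dark (endplate) row band.  An ``overrides`` label map
    replaces the automatic result verbatim.
    """
    if overrides is not None:
        return overrides

    intens = shg.intensities
    flags: list[str] = []
    row_mean = intens.mean(axis=(0, 2))
    if row_mean.max() <= 0:
        raise ValueError("no SHG-positive region found")

    bright = row_mean > 0.05 * row_mean.max()
    surface_row = int(np.argmax(bright))
    cart_rows = np.arange(surface_row, intens.shape[1])
    cart_median = float(np.median(row_mean[cart_rows][row_mean[cart_rows] > 0]))

    dark = row_mean[cart_rows] < endplate_factor * cart_median
    calc_start = None
    # deepest contiguous dark band of at least min_endplate_rows marks the
    # endplate; single dim rows are noise, not anatomy
    runs = [r for r in _contiguous_runs(dark) if r[1] - r[0] >= min_endplate_rows]
    if runs:
        start, _stop = runs[-1]
        calc_start = cart_rows[start]

    n_rows = intens.shape[1]
    row_labels = np.zeros(n_rows, dtype=np.uint8)
    soft_end = calc_start if calc_start is not None else n_rows

    # Per-row axial resultant of doubled in-plane angles, smoothed across a
    # few rows so single noisy rows cannot move the band boundaries.  The
    # normalized resultant encodes both the circular-mean angle and its
    # concentration: Re(z)/n = R cos(2*theta_mean), positive toward 0/180
    # deg, negative toward 90 deg, shrunk toward 0 for dispersed rows.
    # votes weighted by orientation coherence (voxels with an ambiguous
    # moment tensor barely count) and by sin^2(phi): the in-plane angle of a
    # near-optical-axis fiber is meaningless
    weight = orient.valid * np.sin(np.radians(orient.phi)) ** 2
    if orient.coherence is not None:
        weight = weight * orient.coherence
    z2 = weight * np.exp(2j * np.radians(orient.theta))
    row_resultant = z2.sum(axis=(0, 2))
    row_count = weight.sum(axis=(0, 2))
    smooth_rows = max(3, int(round(5.3 / shg.voxel_size[1])) | 1)
    kernel = np.ones(smooth_rows)
    smoothed = np.convolve(row_resultant, kernel, mode="same")
    counts = np.maximum(np.convolve(row_count, kernel, mode="same"), 1e-9)
    cos2 = np.real(smoothed) / counts  # R cos(2 theta_mean) per row
    conc = np.abs(smoothed) / counts

    # Row evidence: a row supports an aligned zone when its mean angle is
    # within angle_tol of that zone's direction (cos(2*angle_tol) is the
    # zero contour) AND its resultant clears a flat penalty, so dispersed
    # rows (small resultant) default to transitional.
    margin = np.cos(np.radians(2.0 * angle_tol))
    ev_sup = cos2 - margin * conc - min_row_evidence
    ev_rad = -cos2 - margin * conc - min_row_evidence

    # Depth-ordered bands by change-point search: superficial is
    # [surface, b1), transitional [b1, b2), radial [b2, endplate); pick
    # (b1, b2) maximizing total aligned-zone evidence.
    span = np.arange(surface_row, soft_end)
    if len(span):
        pre_sup = np.concatenate([[0.0], np.cumsum(ev_sup[span])])
        pre_rad = np.concatenate([[0.0], np.cumsum(ev_rad[span])])
        best = (-np.inf, 0, 0)
        best_b1_val, best_b1 = -np.inf, 0
        for b2 in range(len(span) + 1):
            if pre_sup[b2] > best_b1_val:
                best_b1_val, best_b1 = pre_sup[b2], b2
            score = best_b1_val + (pre_rad[-1] - pre_rad[b2])
            if score > best[0]:
                best = (score, best_b1, b2)
        _, b1, b2 = best
        row_labels[span[:b1]] = ZONE_CODES["superficial"]
        row_labels[span[b1:b2]] = ZONE_CODES["transitional"]
        row_labels[span[b2:]] = ZONE_CODES["radial"]
        if b1 == 0:
            flags.append("superficial zone absent")
        if b2 == b1:
            flags.append("transitional zone absent")
        if b2 == len(span):
            flags.append("radial zone absent")
    if calc_start is not None:
        row_labels[calc_start:] = ZONE_CODES["calcified"]
    else:
        flags.append("calcified zone absent")

    labels = np.zeros(intens.shape, dtype=np.uint8)
    labels[:, :, :] = row_labels[np.newaxis, :, np.newaxis]
    return ZoneLabelMap(labels=labels, flags=flags)


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs in a 1D boolean array."""
    runs = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def compartment_masks(
    shg: Optional[VolumetricImage],
    nadh: VolumetricImage,
    zones: Optional[ZoneLabelMap] = None,
    nucleus_pct: float = DEFAULT_NUCLEUS_PCT,
    lipofuscin_pct: float = DEFAULT_LIPOFUSCIN_PCT,
) -> CompartmentMasks:
    """Split the cartilage region into matrix, cell and cytoplasm-only masks.

    Matrix is the SHG-bright compartment (Otsu threshold within cartilage);
    cells are the rest.  Cytoplasm keeps cell voxels whose NAD(P)H lies
    strictly between the ``nucleus_pct`` percentile (dark nuclei) and at or
    below the ``lipofuscin_pct`` percentile (bright lipofuscin) of cell
    NAD(P)H.  Sections imaged parallel to the surface may pass ``shg=None``
    and ``zones=None`` to treat the whole field as one cell region.
    """
    flags: list[str] = []
    shape = nadh.shape
    cartilage = zones.cartilage if zones is not None else np.ones(shape, dtype=bool)

    if shg is not None and shg.intensities.max() > 0:
        vals = shg.intensities[cartilage]
        thr = threshold_otsu(vals) if vals.max() > vals.min() else vals.max()
        matrix = cartilage & (shg.intensities >= thr)
    else:
        matrix = np.zeros(shape, dtype=bool)
        flags.append("no SHG channel: matrix mask empty")
    cell = cartilage & ~matrix
    if not cell.any():
        raise ValueError("empty cell region: SHG-bright matrix covers all of cartilage")

    cell_nadh = nadh.intensities[cell]
    t_lo = np.percentile(cell_nadh, nucleus_pct)
    t_hi = np.percentile(cell_nadh, lipofuscin_pct)
    cytoplasm = cell & (nadh.intensities > t_lo) & (nadh.intensities <= t_hi)
    if not cytoplasm.any():
        flags.append("cytoplasm mask empty")
    return CompartmentMasks(
        matrix_mask=matrix, cell_mask=cell, cytoplasm_mask=cytoplasm, flags=flags
    )
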