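"""Phasor transform of TCSPC decay cubes and long-lifetime intensity fraction.

A pixel's decay maps to phasor coordinates (G, S) via the real and imaginary
parts of its Fourier transform at the laser repetition frequency.  Pixels of
a bi-exponential field fall on a line inside the universal semicircle
``(G - 1/2)^2 + S^2 = 1/4``; the line's semicircle intersections give the
short (right) and long (left) lifetime components, and the position of a
phasor along the line is its long-lifetime intensity fraction (LLIF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import DecayCube


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates at harmonic ``harmonic`` of ``omega``."""

    G: np.ndarray
    S: np.ndarray
    valid: np.ndarray
    omega: float  # rad/ns at the first harmonic
    harmonic: int = 1

    @property
    def effective_omega(self) -> float:
        return self.omega * self.harmonic


@dataclass
class LifetimeLine:
    """Total-least-squares line through a phasor cloud and its semicircle
    intersections; lifetimes follow from tau = S / (omega G)."""

    centroid: np.ndarray
    direction: np.ndarray
    p_short: np.ndarray
    p_long: np.ndarray
    tau_short: float
    tau_long: float
    axis_ratio: float


@dataclass
class LlifMap:
    llif: np.ndarray
    valid: np.ndarray
    centroid_llif: float
    mean_llif: float
    clipped_fraction: float
    flags: list[str] = field(default_factory=list)


def phasor_transform(cube: DecayCube, harmonic: int = 1, min_photons: int = 1) -> PhasorField:
    """Map every pixel's decay onto phasor coordinates.

    ``G = sum I(t) cos(n w t) / sum I(t)`` and ``S = sum I(t) sin(n w t) / sum I(t)``
    over bin centers t.  Pixels with fewer than ``min_photons`` total counts
    are invalid; an all-invalid cube is an error.
    """
    if min_photons < 1:
        raise ValueError("min_photons must be >= 1")
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = 2.0 * np.pi / cube.rep_period
    t = cube.bin_centers
    counts = cube.counts.astype(float)
    total = counts.sum(axis=0)
    valid = total >= min_photons
    if not valid.any():
        raise ValueError("no pixel reaches min_photons; cannot compute phasors")

    cos_t = np.cos(harmonic * omega * t)[:, None, None]
    sin_t = np.sin(harmonic * omega * t)[:, None, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (counts * cos_t).sum(axis=0) / total
        S = (counts * sin_t).sum(axis=0) / total
    G[~valid] = np.nan
    S[~valid] = np.nan
    return PhasorField(G=G, S=S, valid=valid, omega=omega, harmonic=harmonic)


def semicircle_point(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of a mono-exponential decay with lifetime ``tau`` (closed form)."""
    wt = omega * tau
    return 1.0 / (1.0 + wt**2), wt / (1.0 + wt**2)


def _line_circle_intersections(centroid: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Intersections of the infinite line with (G-1/2)^2 + S^2 = 1/4."""
    d = direction / np.linalg.norm(direction)
    rel = centroid - np.array([0.5, 0.0])
    b = 2.0 * rel @ d
    c = rel @ rel - 0.25
    disc = b * b - 4.0 * c
    if disc <= 0:
        raise ValueError("phasor line does not intersect the universal semicircle")
    roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / 2.0
    return centroid + roots[:, None] * d[None, :]


def fit_lifetime_line(
    ph: PhasorField, mask=None, min_pixels: int = 50, min_axis_ratio: float = 1.2
) -> LifetimeLine:
    """Fit the principal axis of a masked phasor cloud and intersect it with
    the universal semicircle.

    The fit is total least squares (principal component through the
    centroid), not a regression of S on G, because both coordinates carry
    noise.  An isotropic cloud (axis ratio below ``min_axis_ratio``) has no
    dominant axis and is rejected.
    """
    sel = ph.valid.copy()
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    pts = np.stack([ph.G[sel], ph.S[sel]], axis=1)
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < min_pixels:
        raise ValueError(f"need >= {min_pixels} valid phasor pixels, got {len(pts)}")

    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0:
        axis_ratio = float(np.sqrt(evals[1] / evals[0]))
    else:
        axis_ratio = np.inf
    if axis_ratio < min_axis_ratio:
        raise ValueError(
            f"no dominant axis in phasor cloud (axis ratio {axis_ratio:.2f} < {min_axis_ratio})"
        )
    direction = evecs[:, 1]

    inter = _line_circle_intersections(centroid, direction)
    if np.any(inter[:, 1] < -1e-9):
        raise ValueError("phasor line intersects the circle below S = 0")
    # short lifetime = larger G (right intersection)
    order = np.argsort(inter[:, 0])[::-1]
    p_short, p_long = inter[order[0]], inter[order[1]]
    w = ph.effective_omega
    tau_short = float(p_short[1] / (w * p_short[0]))
    tau_long = float(p_long[1] / (w * p_long[0]))
    return LifetimeLine(
        centroid=centroid,
        direction=direction,
        p_short=p_short,
        p_long=p_long,
        tau_short=tau_short,
        tau_long=tau_long,
        axis_ratio=axis_ratio,
    )


def llif_map(ph: PhasorField, line: LifetimeLine, mask=None, tol: float = 1e-9) -> LlifMap:
    """Project masked phasors onto the lifetime line and express each as a
    fraction of the short-to-long segment, clipped to [0, 1].

    The centroid LLIF (headline value) and the mean of per-pixel values are
    both reported, along with the fraction of pixels that needed clipping.
    """
    seg = line.p_long - line.p_short
    seg_len = np.linalg.norm(seg)
    if seg_len < tol:
        raise ValueError("degenerate lifetime line: endpoints coincide")
    d = seg / seg_len

    sel = ph.valid.copy()
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("no valid pixels under the mask")

    rel_g = ph.G - line.p_short[0]
    rel_s = ph.S - line.p_short[1]
    raw = (rel_g * d[0] + rel_s * d[1]) / seg_len
    llif = np.where(sel, np.clip(raw, 0.0, 1.0), np.nan)
    clipped = np.abs(llif[sel] - raw[sel]) > 1e-12
    clipped_fraction = float(clipped.mean())

    cen_raw = float((line.centroid - line.p_short) @ d / seg_len)
    centroid_llif = float(np.clip(cen_raw, 0.0, 1.0))
    flags = []
    if clipped_fraction >= 0.01:
        flags.append(f"{clipped_fraction:.1%} of pixels clipped to [0, 1]")
    return LlifMap(
        llif=llif,
        valid=sel,
        centroid_llif=centroid_llif,
        mean_llif=float(np.nanmean(llif[sel])),
        clipped_fraction=clipped_fraction,
        flags=flags,
    )
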