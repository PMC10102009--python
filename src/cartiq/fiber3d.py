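"""Per-voxel 3D fiber orientation and windowed 3D directional variance.

The orientation estimator accumulates, for every voxel, an intensity-weighted
second-moment tensor of unit displacement vectors within a physical window
and takes its principal eigenvector as the local fiber axis.  The variance
metric summarizes the dispersion of those axes: 0 for perfectly parallel
fibers, 1 for completely random organization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import VolumetricImage

#: Default physical analysis window, (z, y, x) in µm — chosen at 2–3x the
#: typical 1–2 µm collagen fiber diameter for both orientation and variance.
DEFAULT_WINDOW_UM = (5.0, 5.3, 5.3)


@dataclass
class OrientationField:
    """Per-voxel axial fiber orientation.

    ``theta`` is the azimuth in the imaging plane measured from +x in degrees
    [0, 180); ``phi`` the polar angle from the optical (+z) axis in degrees
    [0, 180].  ``(theta, phi)`` are canonical axial coordinates: a fiber axis
    and its negation map to the same pair (fold: in-plane component toward
    +y).  phi beyond 90 deg encodes an axis whose z component points against
    the folded in-plane direction; the sign-free tilt magnitude in [0, 90]
    is available as :meth:`phi_axial`.  ``valid`` marks voxels carrying a
    defined orientation.
    """

    theta: np.ndarray
    phi: np.ndarray
    valid: np.ndarray
    voxel_size: tuple[float, float, float]
    #: optional per-voxel confidence in [0, 1]: normalized gap between the
    #: two largest moment-tensor eigenvalues (1 = unambiguous axis)
    coherence: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def phi_axial(self) -> np.ndarray:
        """Tilt from the optical axis folded to [0, 90] degrees."""
        return np.minimum(self.phi, 180.0 - self.phi)

    def __post_init__(self) -> None:
        if not (self.theta.shape == self.phi.shape == self.valid.shape):
            raise ValueError("theta, phi and valid must share one shape")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.theta.shape

    def axes(self) -> np.ndarray:
        """Unit axis vectors, shape (*grid, 3) ordered (x, y, z); NaN where invalid."""
        vec = axes_from_angles(self.theta, self.phi)
        vec[~self.valid] = np.nan
        return vec


@dataclass
class VarianceMap:
    """Windowed 3D directional variance in [0, 1] plus provenance."""

    V: np.ndarray
    valid: np.ndarray
    window_um: tuple[float, float, float]
    flags: list[str] = field(default_factory=list)


def angles_from_axes(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (theta, phi) in degrees from axis vectors ordered (x, y, z).

    Axes are folded so their in-plane component points toward +y (ties:
    toward +x, then +z), making the representation bijective on axes:
    theta lands in [0, 180) and phi in [0, 180], and
    ``axes_from_angles(*angles_from_axes(u))`` returns u up to sign.
    """
    v = np.asarray(vec, dtype=float).copy()
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = v / norm
    y, x, z = v[..., 1], v[..., 0], v[..., 2]
    tol = 1e-12  # components this small are treated as zero in the fold
    y_zero = np.abs(y) < tol
    x_zero = np.abs(x) < tol
    flip = (y < -tol) | (y_zero & (x < -tol)) | (y_zero & x_zero & (z < 0))
    v[flip] *= -1
    # snap folded-away y to +0 so atan2 cannot wrap to 180 - epsilon
    v[..., 1] = np.where(np.abs(v[..., 1]) < tol, 0.0, v[..., 1])
    phi = np.degrees(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))
    theta = np.degrees(np.arctan2(v[..., 1], v[..., 0])) % 180.0
    # a pure +/-z axis has no in-plane direction
    theta = np.where(np.abs(v[..., 2]) > 1.0 - 1e-12, 0.0, theta)
    return theta, phi


def axes_from_angles(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit vectors (x, y, z) from azimuth/polar angles in degrees."""
    t = np.radians(np.asarray(theta, dtype=float))
    p = np.radians(np.asarray(phi, dtype=float))
    return np.stack(
        [np.sin(p) * np.cos(t), np.sin(p) * np.sin(t), np.cos(p)], axis=-1
    )


def window_voxels(
    window_um, voxel_size: tuple[float, float, float]
) -> tuple[int, int, int]:
    """Convert a physical window to odd per-axis voxel counts (z, y, x).

    Anisotropic sampling is honored so the window stays approximately cubic
    in physical space; each axis is rounded to the nearest odd count >= 3.
    """
    window_um = np.broadcast_to(np.asarray(window_um, dtype=float), (3,))
    if np.any(window_um <= 0):
        raise ValueError("window must be positive on every axis")
    out = []
    for w, v in zip(window_um, voxel_size):
        if w < 2 * v:
            raise ValueError(
                f"window of {w} µm spans fewer than 3 voxels at {v} µm sampling"
            )
        n = int(round(w / v))
        n = max(n + (1 - n % 2), 3)  # force odd, at least 3
        out.append(n)
    return tuple(out)


def _offset_grid(shape_zyx, voxel_size):
    """Physical (x, y, z) offsets of window voxels relative to the center."""
    half = [s // 2 for s in shape_zyx]
    dz, dy, dx = np.meshgrid(
        np.arange(-half[0], half[0] + 1) * voxel_size[0],
        np.arange(-half[1], half[1] + 1) * voxel_size[1],
        np.arange(-half[2], half[2] + 1) * voxel_size[2],
        indexing="ij",
    )
    return dx, dy, dz


def local_orientation(
    shg: VolumetricImage,
    window_um=DEFAULT_WINDOW_UM,
    matrix_mask: Optional[np.ndarray] = None,
) -> OrientationField:
    """Estimate per-voxel fiber axes by intensity-weighted vector summation.

    For each voxel c the second-moment tensor ``M = sum_p I(p) v_p v_p^T`` is
    accumulated over window voxels p != c, where v_p is the unit displacement
    from c to p in physical coordinates.  The local fiber axis is the
    principal eigenvector of M.  Windows are truncated at stack borders.
    """
    win = window_voxels(window_um, shg.voxel_size)
    intens = shg.intensities.astype(float)
    dx, dy, dz = _offset_grid(win, shg.voxel_size)
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    center = tuple(s // 2 for s in win)
    r[center] = np.inf  # the center voxel contributes no displacement

    comps = {}
    for name, a, b in (
        ("xx", dx, dx), ("yy", dy, dy), ("zz", dz, dz),
        ("xy", dx, dy), ("xz", dx, dz), ("yz", dy, dz),
    ):
        kernel = a * b / r**2
        comps[name] = ndimage.correlate(intens, kernel, mode="constant", cval=0.0)
    wsum = ndimage.correlate(
        intens, np.where(np.isinf(r), 0.0, 1.0), mode="constant", cval=0.0
    )

    valid = wsum > 0
    if matrix_mask is not None:
        valid &= np.asarray(matrix_mask, dtype=bool)

    M = np.zeros(intens.shape + (3, 3))
    M[..., 0, 0] = comps["xx"]
    M[..., 1, 1] = comps["yy"]
    M[..., 2, 2] = comps["zz"]
    M[..., 0, 1] = M[..., 1, 0] = comps["xy"]
    M[..., 0, 2] = M[..., 2, 0] = comps["xz"]
    M[..., 1, 2] = M[..., 2, 1] = comps["yz"]

    theta = np.zeros(intens.shape)
    phi = np.zeros(intens.shape)
    coherence = np.zeros(intens.shape)
    if valid.any():
        evals, vecs = np.linalg.eigh(M[valid])  # ascending eigenvalues
        principal = vecs[..., :, 2]
        th, ph = angles_from_axes(principal)
        theta[valid] = th
        phi[valid] = ph
        coherence[valid] = (evals[..., 2] - evals[..., 1]) / np.maximum(
            evals[..., 2], 1e-300
        )
    return OrientationField(
        theta=theta,
        phi=phi,
        valid=valid,
        voxel_size=shg.voxel_size,
        coherence=coherence,
    )


def variance_from_axes(axes: np.ndarray) -> float:
    """3D directional variance of a flat set of axial unit vectors.

    Computes the mean dyadic ``T = mean(u u^T)`` and returns
    ``V = 3/2 (1 - lambda_max(T))``: 0 when all axes coincide, 1 when the
    axes are uniform on the hemisphere (lambda_max = 1/3).
    """
    u = np.asarray(axes, dtype=float)
    u = u.reshape(-1, 3)
    u = u[np.isfinite(u).all(axis=1)]
    if len(u) == 0:
        raise ValueError("no valid axes")
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    T = (u[:, :, None] * u[:, None, :]).mean(axis=0)
    lam_max = np.linalg.eigvalsh(T)[-1]
    return float(np.clip(1.5 * (1.0 - lam_max), 0.0, 1.0))


def directional_variance(
    orient: OrientationField,
    window_um=DEFAULT_WINDOW_UM,
    min_valid: int = 4,
) -> VarianceMap:
    """Windowed 3D directional variance of an orientation field.

    Per voxel, the mean dyadic of valid axial orientations within the window
    (center included) is formed and ``V = 3/2 (1 - lambda_max)`` computed,
    clipped to [0, 1].  Voxels whose window holds fewer than ``min_valid``
    orientations are invalid.
    """
    if not orient.valid.any():
        raise ValueError("orientation field has no valid voxels")
    win = window_voxels(window_um, orient.voxel_size)
    kernel = np.ones(win)

    u = axes_from_angles(orient.theta, orient.phi)
    u[~orient.valid] = 0.0

    count = ndimage.correlate(
        orient.valid.astype(float), kernel, mode="constant", cval=0.0
    )
    valid = count >= min_valid

    T = np.zeros(orient.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            s = ndimage.correlate(u[..., i] * u[..., j], kernel, mode="constant", cval=0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                T[..., i, j] = T[..., j, i] = s / count

    V = np.full(orient.shape, np.nan)
    if valid.any():
        lam_max = np.linalg.eigvalsh(T[valid])[..., -1]
        V[valid] = np.clip(1.5 * (1.0 - lam_max), 0.0, 1.0)
    win_phys = tuple(n * v for n, v in zip(win, orient.voxel_size))
    return VarianceMap(V=V, valid=valid, window_um=win_phys)


def zone_mean_variance(vmap: VarianceMap, zones) -> dict:
    """Average valid variance values per zone label.

    Returns ``{zone_name: {"mean": float | nan, "n": int}}``; empty zones are
    reported with ``n = 0`` and a NaN mean, and flagged on the map.
    """
    from .segmentation import ZONE_NAMES  # local import avoids a cycle

    labels = np.asarray(zones.labels if hasattr(zones, "labels") else zones)
    if labels.shape != vmap.V.shape:
        raise ValueError("zone map and variance map shapes differ")
    out = {}
    for code, name in ZONE_NAMES.items():
        if name == "background":
            continue
        sel = (labels == code) & vmap.valid
        n = int(sel.sum())
        if n == 0:
            out[name] = {"mean": float("nan"), "n": 0}
            if f"empty zone: {name}" not in vmap.flags:
                vmap.flags.append(f"empty zone: {name}")
        else:
            out[name] = {"mean": float(vmap.V[sel].mean()), "n": n}
    return out
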