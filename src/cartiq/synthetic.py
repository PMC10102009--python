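"""Phantoms with known ground truth for every pipeline stage.

Four generators stand in for raw two-photon data: fibrous SHG volumes with
controllable axial-orientation dispersion, a layered cartilage phantom with
zone truth, bi-exponential TCSPC decay cubes with a prescribed long-component
intensity fraction, and 2D cell fields with per-cell redox ratio and
cytoplasmic texture of a prescribed inverse-power-law PSD exponent.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import vonmises_fisher

from .fiber3d import OrientationField, angles_from_axes
from .image_io import DecayCube, VolumetricImage
from .segmentation import ZONE_CODES, ZoneLabelMap

#: Default sampling mirrors the acquisition geometry: 0.754 µm lateral
#: (512 px over 386 µm), 1 µm axial steps.
DEFAULT_VOXEL_SIZE = (1.0, 0.754, 0.754)


# ---------------------------------------------------------------------------
# Axial orientation sampling


def sample_axial_orientations(
    n: int,
    mean_axis=(1.0, 0.0, 0.0),
    kappa: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw axial unit vectors from a von Mises-Fisher distribution.

    Directions are sampled on the sphere and folded (u and -u identified) to
    the hemisphere around ``mean_axis``.  ``kappa=0`` is the uniform
    distribution; ``kappa=inf`` returns the mean axis exactly.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    mu = np.asarray(mean_axis, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if np.isinf(kappa):
        return np.tile(mu, (n, 1))
    if kappa == 0:
        u = rng.standard_normal((n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
    else:
        u = vonmises_fisher(mu, kappa).rvs(n, random_state=rng)
        u = np.atleast_2d(u)
    # fold to the hemisphere containing the mean axis
    flip = (u @ mu) < 0
    u[flip] *= -1
    return u


# ---------------------------------------------------------------------------
# Fibrous SHG volumes


@dataclass
class FiberSpec:
    """Straight-cylinder SHG volume description.

    ``fiber_radius`` defaults to 1 µm (2 µm diameter, within the typical
    1-2 µm fiber diameter range).  ``photon_scale=None`` yields a noise-free
    float stack with unit peak; otherwise intensities are scaled to that
    expected peak count and Poisson sampled.
    """

    volume_shape: tuple[int, int, int] = (16, 64, 64)  # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE  # µm
    n_fibers: int = 20
    fiber_radius: float = 1.0  # µm
    mean_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)  # (x, y, z)
    kappa: float = 8.0
    psf_sigma: tuple[float, float] = (0.0, 0.0)  # (lateral, axial) µm
    photon_scale: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.fiber_radius < min(self.voxel_size):
            raise ValueError(
                f"fiber radius {self.fiber_radius} µm is below one voxel "
                f"({min(self.voxel_size)} µm); fibers would be unresolvable"
            )


def _voxel_grid_um(shape, voxel_size):
    """Physical (x, y, z) coordinates of voxel centers, each shaped like the grid."""
    z = np.arange(shape[0]) * voxel_size[0]
    y = np.arange(shape[1]) * voxel_size[1]
    x = np.arange(shape[2]) * voxel_size[2]
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    return xx, yy, zz


def generate_fiber_stack(spec: FiberSpec) -> tuple[VolumetricImage, OrientationField]:
    """Rasterize straight cylinders with von Mises-Fisher axes into an SHG
    stack plus a per-voxel truth orientation field.

    Where cylinders overlap, the nearest fiber's axis wins; background
    voxels are invalid in the truth field.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    xx, yy, zz = _voxel_grid_um(shape, spec.voxel_size)
    extent = np.array(
        [shape[2] * spec.voxel_size[2], shape[1] * spec.voxel_size[1], shape[0] * spec.voxel_size[0]]
    )  # (x, y, z) µm

    axes = sample_axial_orientations(spec.n_fibers, spec.mean_axis, spec.kappa, rng)
    centers = rng.uniform(0.0, 1.0, size=(spec.n_fibers, 3)) * extent

    intens = np.zeros(shape)
    best_d2 = np.full(shape, np.inf)
    truth_axis = np.full(shape + (3,), np.nan)
    r2 = spec.fiber_radius**2
    for u, c in zip(axes, centers):
        dx = xx - c[0]
        dy = yy - c[1]
        dz = zz - c[2]
        proj = dx * u[0] + dy * u[1] + dz * u[2]
        d2 = dx**2 + dy**2 + dz**2 - proj**2
        inside = d2 <= r2
        intens[inside] = 1.0
        closer = inside & (d2 < best_d2)
        best_d2[closer] = d2[closer]
        truth_axis[closer] = u

    if any(s > 0 for s in spec.psf_sigma):
        lat, ax = spec.psf_sigma
        sigma_vox = (ax / spec.voxel_size[0], lat / spec.voxel_size[1], lat / spec.voxel_size[2])
        intens = ndimage.gaussian_filter(intens, sigma=sigma_vox)
    if spec.photon_scale is not None:
        peak = intens.max()
        if peak > 0:
            intens = rng.poisson(intens / peak * spec.photon_scale).astype(float)

    valid = np.isfinite(truth_axis[..., 0])
    theta = np.zeros(shape)
    phi = np.zeros(shape)
    if valid.any():
        th, ph = angles_from_axes(truth_axis[valid])
        theta[valid] = th
        phi[valid] = ph
    img = VolumetricImage(intensities=intens, voxel_size=spec.voxel_size, channel="SHG")
    truth = OrientationField(
        theta=theta,
        phi=phi,
        valid=valid,
        voxel_size=spec.voxel_size,
        meta={"fiber_axes": axes, "fiber_centers": centers},
    )
    return img, truth


# ---------------------------------------------------------------------------
# Layered cartilage phantom


@dataclass
class CartilageSpec:
    """Zone-layered cartilage phantom along depth (y).

    ``zone_fractions`` are depth fractions of (superficial, transitional,
    radial, calcified) and must sum to 1.  Superficial fibers run along the
    surface (+x), radial fibers along depth (+y), transitional fibers are
    broadly dispersed; a dark endplate band sits at the top of the calcified
    zone.
    """

    volume_shape: tuple[int, int, int] = (8, 96, 64)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    zone_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.3, 0.2)
    fiber_radius: float = 1.0
    fibers_per_zone: int = 18
    kappa_aligned: float = 600.0
    kappa_transitional: float = 1.0
    endplate_rows: int = 3
    endplate_level: float = 0.01  # endplate intensity vs fiber peak
    pad_top_rows: int = 0  # empty rows above the articular surface
    analysis_window_um: float = 5.3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.zone_fractions) - 1.0) > 1e-9:
            raise ValueError("zone depth fractions must sum to 1")


_ZONE_AXES = {
    "superficial": (1.0, 0.0, 0.0),  # parallel to the surface
    "transitional": (1.0, 0.0, 0.0),
    "radial": (0.0, 1.0, 0.0),  # perpendicular to the surface
    "calcified": (0.0, 1.0, 0.0),
}


def generate_cartilage_phantom(spec: CartilageSpec) -> tuple[VolumetricImage, ZoneLabelMap]:
    """Stack four independently generated fibrous bands along depth.

    Returns the SHG stack and a truth label map; metadata flags mark any
    zone thinner than one analysis window.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.volume_shape
    cart_rows = ny - spec.pad_top_rows
    rows = [int(round(f * cart_rows)) for f in spec.zone_fractions]
    rows[-1] = cart_rows - sum(rows[:-1])  # absorb rounding in the deepest zone

    flags = []
    stacks = []
    zone_axes = {}
    labels_1d = np.full(ny, ZONE_CODES["background"], dtype=np.uint8)
    y0 = spec.pad_top_rows
    zone_order = ("superficial", "transitional", "radial", "calcified")
    for zone, n_rows in zip(zone_order, rows):
        if n_rows <= 0:
            flags.append(f"zone {zone} has zero depth")
            continue
        if n_rows * spec.voxel_size[1] < spec.analysis_window_um:
            flags.append(f"zone {zone} thinner than one analysis window")
        kappa = (
            spec.kappa_transitional if zone == "transitional" else spec.kappa_aligned
        )
        sub = FiberSpec(
            volume_shape=(nz, n_rows, nx),
            voxel_size=spec.voxel_size,
            n_fibers=max(4, int(round(spec.fibers_per_zone * n_rows / max(cart_rows // 4, 1)))),
            fiber_radius=spec.fiber_radius,
            mean_axis=_ZONE_AXES[zone],
            kappa=kappa,
            seed=int(rng.integers(2**31)),
        )
        img, band_truth = generate_fiber_stack(sub)
        zone_axes[zone] = band_truth.meta["fiber_axes"]
        band = img.intensities
        if zone == "calcified":
            band = band.copy()
            band[:, : spec.endplate_rows, :] = spec.endplate_level
        stacks.append(band)
        labels_1d[y0 : y0 + n_rows] = ZONE_CODES[zone]
        y0 += n_rows

    intens = np.concatenate(
        [np.zeros((nz, spec.pad_top_rows, nx))] + stacks, axis=1
    )
    labels = np.zeros(spec.volume_shape, dtype=np.uint8)
    labels[:, :, :] = labels_1d[np.newaxis, :, np.newaxis]
    img = VolumetricImage(intensities=intens, voxel_size=spec.voxel_size, channel="SHG")
    return img, ZoneLabelMap(labels=labels, flags=flags, meta={"zone_axes": zone_axes})


# ---------------------------------------------------------------------------
# Bi-exponential decay cubes


@dataclass
class DecaySpec:
    """Bi-exponential TCSPC decay field with a per-pixel long-component
    intensity fraction.  ``sample_poisson=False`` yields noise-free expected
    counts (floats)."""

    image_shape: tuple[int, int] = (32, 32)
    tau_short: float = 0.4  # ns
    tau_long: float = 3.0  # ns
    f_long_map: np.ndarray | float = 0.5
    n_bins: int = 256
    rep_period: float = 12.5  # ns
    total_counts: float = 10_000.0  # expected photons per pixel
    sample_poisson: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.tau_short < self.tau_long < self.rep_period:
            raise ValueError("need 0 < tau_short < tau_long < rep_period")
        if self.n_bins < 8:
            raise ValueError("n_bins < 8 leaves the phasor ill-conditioned")
        f = np.broadcast_to(np.asarray(self.f_long_map, dtype=float), self.image_shape).copy()
        if f.min() < 0 or f.max() > 1:
            raise ValueError("f_long_map values must lie in [0, 1]")
        self.f_long_map = f


def _binned_exponential(tau: float, edges: np.ndarray) -> np.ndarray:
    """Photon mass per bin of a unit-intensity exponential decay.

    Integrates exp(-t/tau)/tau over each bin so the total over [0, inf)
    would be 1; truncation at the last edge is deliberate.
    """
    cdf = 1.0 - np.exp(-edges / tau)
    return np.diff(cdf)


def generate_decay_cube(spec: DecaySpec) -> tuple[DecayCube, np.ndarray]:
    """Per-pixel expected bi-exponential decays, optionally Poisson sampled.

    The long/short components are mixed by *intensity* fraction: a pixel with
    ``f_long = f`` emits a fraction f of its photons from the long-lifetime
    component.  Returns the cube and the truth f_long map.
    """
    rng = np.random.default_rng(spec.seed)
    edges = np.arange(spec.n_bins + 1) * (spec.rep_period / spec.n_bins)
    long_shape = _binned_exponential(spec.tau_long, edges)
    short_shape = _binned_exponential(spec.tau_short, edges)
    long_shape = long_shape / long_shape.sum()
    short_shape = short_shape / short_shape.sum()

    f = spec.f_long_map[np.newaxis, :, :]
    expected = spec.total_counts * (
        f * long_shape[:, None, None] + (1.0 - f) * short_shape[:, None, None]
    )
    counts = rng.poisson(expected).astype(np.int64) if spec.sample_poisson else expected
    cube = DecayCube(
        counts=counts,
        bin_width=spec.rep_period / spec.n_bins,
        rep_period=spec.rep_period,
        channel="NADH",
    )
    return cube, spec.f_long_map.copy()


# ---------------------------------------------------------------------------
# Metabolic cell fields


@dataclass
class CellFieldSpec:
    """2D cell field with nuclei, lipofuscin speckles, per-cell redox ratio
    and cytoplasmic texture of prescribed PSD power-law exponent."""

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.5  # µm
    n_cells: int = 12
    cell_radius: float = 12.0  # µm
    nucleus_radius: float = 4.0  # µm
    rr_per_cell: float | Sequence[float] = 0.4
    beta_true: float = 2.0
    lipofuscin_density: float = 0.01  # fraction of cytoplasm pixels
    lipofuscin_gain: float = 12.0  # multiple of the cytoplasm median
    noise: bool = False  # add Poisson noise to both channels
    photon_scale: float = 500.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be smaller than cell_radius")
        rr = np.atleast_1d(np.asarray(self.rr_per_cell, dtype=float))
        if np.any((rr <= 0) | (rr >= 1)):
            raise ValueError("rr_per_cell must lie strictly inside (0, 1); rr=1 divides by zero")


def power_law_texture(
    shape: tuple[int, int],
    beta: float,
    pixel_size_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise spectrally shaped so PSD(k) ~ k^-beta.

    The amplitude filter k^(-beta/2) achieves the prescribed exponent exactly
    in expectation; the output is standardized to zero mean, unit variance.
    """
    noise = rng.standard_normal(shape)
    f = np.fft.fft2(noise)
    ky = np.fft.fftfreq(shape[0], d=pixel_size_um)
    kx = np.fft.fftfreq(shape[1], d=pixel_size_um)
    k = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    amp = np.zeros_like(k)
    nonzero = k > 0
    amp[nonzero] = k[nonzero] ** (-beta / 2.0)
    tex = np.fft.ifft2(f * amp).real
    return (tex - tex.mean()) / tex.std()


def generate_metabolic_field(spec: CellFieldSpec):
    """Synthesize co-registered NAD(P)H and FAD planes plus truth masks.

    Cytoplasm carries PSD-shaped texture (exponent ``beta_true``) mapped
    affinely to positive intensities; nuclei are zero, lipofuscin speckles
    sit at ``lipofuscin_gain`` times the cytoplasm median, and FAD is scaled
    per cell so the noise-free pixel-wise redox ratio equals the requested
    value.  Returns ``(nadh, fad, masks, truth)`` where ``masks`` holds
    cell/nucleus/cytoplasm/lipofuscin booleans and ``truth`` the requested
    rr values and beta.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    rr = np.atleast_1d(np.asarray(spec.rr_per_cell, dtype=float))
    rr_cells = np.resize(rr, spec.n_cells)

    yy, xx = np.mgrid[0:h, 0:w]
    cell_mask = np.zeros((h, w), dtype=bool)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    cell_id = np.full((h, w), -1, dtype=int)
    r_cell = spec.cell_radius / spec.pixel_size
    r_nuc = spec.nucleus_radius / spec.pixel_size
    for i in range(spec.n_cells):
        cy = rng.uniform(r_cell, h - r_cell)
        cx = rng.uniform(r_cell, w - r_cell)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= r_cell**2
        cell_id[inside & (cell_id < 0)] = i
        cell_mask |= inside
        nucleus_mask |= d2 <= r_nuc**2
    cytoplasm = cell_mask & ~nucleus_mask

    tex = power_law_texture((h, w), spec.beta_true, spec.pixel_size, rng)
    # affine map to positive intensities; 6 sigma offset keeps clipping rare
    nadh = np.clip(tex + 6.0, 0.0, None) * 10.0
    nadh[~cytoplasm] = 0.0

    lipofuscin_mask = np.zeros((h, w), dtype=bool)
    cyto_idx = np.flatnonzero(cytoplasm)
    n_lipo = int(round(spec.lipofuscin_density * len(cyto_idx)))
    if n_lipo:
        chosen = rng.choice(cyto_idx, size=n_lipo, replace=False)
        lipofuscin_mask.flat[chosen] = True
        median = np.median(nadh[cytoplasm & ~lipofuscin_mask])
        nadh[lipofuscin_mask] = spec.lipofuscin_gain * median

    fad = np.zeros_like(nadh)
    for i in range(spec.n_cells):
        sel = (cell_id == i) & cytoplasm
        r = rr_cells[i]
        fad[sel] = nadh[sel] * r / (1.0 - r)

    if spec.noise:
        for arr in (nadh, fad):
            peak = arr.max()
            if peak > 0:
                arr[:] = rng.poisson(arr / peak * spec.photon_scale).astype(float)

    vs = (1.0, spec.pixel_size, spec.pixel_size)
    nadh_img = VolumetricImage(intensities=nadh[np.newaxis], voxel_size=vs, channel="NADH")
    fad_img = VolumetricImage(intensities=fad[np.newaxis], voxel_size=vs, channel="FAD")
    masks = {
        "cell": cell_mask[np.newaxis],
        "nucleus": nucleus_mask[np.newaxis],
        "cytoplasm": cytoplasm[np.newaxis],
        "lipofuscin": lipofuscin_mask[np.newaxis],
    }
    truth = {"rr_per_cell": rr_cells, "beta": spec.beta_true, "cell_id": cell_id[np.newaxis]}
    return nadh_img, fad_img, masks, truth
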