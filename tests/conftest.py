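import numpy as np
import pytest
from scipy import ndimage

from cartiq import fiber3d as f3
from cartiq import synthetic as syn
from cartiq.image_io import VolumetricImage

VOXEL = (1.0, 0.75, 0.75)


def make_cylinder_stack(
    shape=(24, 48, 48),
    voxel_size=VOXEL,
    axis="x",
    radius_um=1.0,
    psf=(0.4, 0.8),
):
    """Noise-free straight cylinder through the volume center.

    Returns (VolumetricImage, distance-to-axis map in µm, unit axis vector).
    """
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * voxel_size[0],
        np.arange(shape[1]) * voxel_size[1],
        np.arange(shape[2]) * voxel_size[2],
        indexing="ij",
    )
    # center on a voxel so a tight "core" region is populated
    cz = (shape[0] // 2) * voxel_size[0]
    cy = (shape[1] // 2) * voxel_size[1]
    cx = (shape[2] // 2) * voxel_size[2]
    if axis == "x":
        d = np.sqrt((yy - cy) ** 2 + (zz - cz) ** 2)
        u = np.array([1.0, 0.0, 0.0])
    elif axis == "y":
        d = np.sqrt((xx - cx) ** 2 + (zz - cz) ** 2)
        u = np.array([0.0, 1.0, 0.0])
    else:
        raise ValueError(axis)
    intens = (d <= radius_um).astype(float)
    if psf is not None:
        ax_s, lat_s = psf[0], psf[1]
        intens = ndimage.gaussian_filter(
            intens, (ax_s / voxel_size[0], lat_s / voxel_size[1], lat_s / voxel_size[2])
        )
    img = VolumetricImage(intensities=intens, voxel_size=voxel_size, channel="SHG")
    return img, d, u


@pytest.fixture(scope="session")
def metabolic_field():
    """Default metabolic phantom plus its truth masks (seed fixed)."""
    spec = syn.CellFieldSpec(seed=5)
    nadh, fad, masks, truth = syn.generate_metabolic_field(spec)
    return {"spec": spec, "nadh": nadh, "fad": fad, "masks": masks, "truth": truth}


@pytest.fixture(scope="session")
def cartilage_phantom():
    """Layered cartilage phantom with zone truth and its orientation field."""
    spec = syn.CartilageSpec(
        volume_shape=(8, 96, 64), voxel_size=VOXEL, seed=1
    )
    img, truth = syn.generate_cartilage_phantom(spec)
    orient = f3.local_orientation(img, matrix_mask=img.intensities > 0.1)
    return {"spec": spec, "img": img, "truth": truth, "orient": orient}


def zone_row_bounds(labels, code):
    rows = np.nonzero((labels == code).any(axis=(0, 2)))[0]
    return (int(rows.min()), int(rows.max())) if len(rows) else None
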