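"""Independent oracles used to cross-check pipeline implementations.

These deliberately use different algorithms (structure tensor, direct
eigen-solves, closed forms) from the code under test.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import structure_tensor


def structure_tensor_axes(volume: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """Per-voxel fiber axis as the smallest-eigenvalue eigenvector of the
    3D structure tensor; components returned in (x, y, z) order."""
    Azz, Azy, Azx, Ayy, Ayx, Axx = structure_tensor(volume, sigma=sigma, order="rc")
    T = np.stack(
        [
            np.stack([Axx, Ayx, Azx], axis=-1),
            np.stack([Ayx, Ayy, Azy], axis=-1),
            np.stack([Azx, Azy, Azz], axis=-1),
        ],
        axis=-2,
    )
    _, vecs = np.linalg.eigh(T)
    axes = vecs[..., :, 0]  # intensity is constant along the fiber
    return axes / np.linalg.norm(axes, axis=-1, keepdims=True)


def axial_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between axes (sign-insensitive), degrees."""
    dot = np.abs(np.sum(u * v, axis=-1))
    return np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))


def variance_eigen_oracle(axes: np.ndarray) -> float:
    """Directional variance by direct dyadic construction and eigen-solve,
    written independently of the library implementation."""
    u = np.asarray(axes, dtype=float).reshape(-1, 3)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    T = np.einsum("ni,nj->ij", u, u) / len(u)
    lam = np.linalg.eigvalsh(T).max()
    return 1.5 * (1.0 - lam)


def mono_exponential_phasor(tau: float, rep_period: float, harmonic: int = 1):
    """Closed-form phasor of a mono-exponential decay integrated over one
    full repetition period: G + iS = 1 / (1 - i n w tau)."""
    w = harmonic * 2.0 * np.pi / rep_period
    z = 1.0 / (1.0 - 1j * w * tau)
    return z.real, z.imag


def ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov distance."""
    from scipy.stats import ks_2samp

    return float(ks_2samp(a.ravel(), b.ravel()).statistic)
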