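"""Vein mask construction from a susceptibility-weighted phase volume.

Chain: unwrap the wrapped phase (Laplacian / spectral Poisson solve,
deterministic and robust on 3D volumes), high-pass filter to isolate abrupt
susceptibility-driven deviations, threshold, and dilate with a spherical
2 mm kernel.  A Euclidean distance transform then classifies voxels by
proximity to the vein mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn

__all__ = [
    "VeinMask",
    "unwrap_phase",
    "highpass_phase",
    "vein_mask",
    "near_vein",
    "DEFAULT_VEIN_THRESHOLD_RAD",
]

#: Default |filtered phase| threshold (radians); calibrated on the vein
#: phantom so that sensitivity >= 0.9 at false-positive fraction <= 0.05.
DEFAULT_VEIN_THRESHOLD_RAD = 0.8

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VeinMask:
    mask: np.ndarray
    pre_dilation: np.ndarray
    threshold_rad: float
    dilation_mm: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (1.5, 1.5, 1.5)


def _dct_laplacian_eigenvalues(shape) -> np.ndarray:
    lam = np.zeros(shape)
    for ax, n in enumerate(shape):
        k = np.arange(n).reshape([-1 if a == ax else 1 for a in range(len(shape))])
        lam = lam + 2.0 * np.cos(np.pi * k / n) - 2.0
    return lam


def _laplacian(x: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return idctn(lam * dctn(x, norm="ortho"), norm="ortho")


def unwrap_phase(phase_volume: np.ndarray) -> np.ndarray:
    """Unwrap a phase volume with values in (-pi, pi].

    Laplacian method (Schofield & Zhu): the Laplacian of the true phase is
    computed from sin/cos of the wrapped phase, then inverted spectrally
    under Neumann boundary conditions.  The continuous estimate is snapped
    to the wrapped input modulo 2*pi, so wrap-free input is returned exactly
    and ramps are recovered up to a global 2*pi offset.
    """
    psi = np.asarray(phase_volume, dtype=float)
    lam = _dct_laplacian_eigenvalues(psi.shape)
    rho = (np.cos(psi) * _laplacian(np.sin(psi), lam)
           - np.sin(psi) * _laplacian(np.cos(psi), lam))
    coeff = dctn(rho, norm="ortho")
    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = np.where(lam != 0, coeff / lam, 0.0)
    phi = idctn(coeff, norm="ortho")
    # congruence: keep the measured phase, adopt only the 2*pi offsets
    return psi + 2.0 * np.pi * np.round((phi - psi) / (2.0 * np.pi))


def highpass_phase(unwrapped: np.ndarray, fwhm_mm: float = 10.0,
                   voxel_size_mm=(1.5, 1.5, 1.5)) -> np.ndarray:
    """Unsharp-mask high-pass: input minus its Gaussian-smoothed version."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm * GAUSSIAN_FWHM_TO_SIGMA / s
                 for s in np.broadcast_to(voxel_size_mm, (3,))]
    return unwrapped - ndimage.gaussian_filter(unwrapped, sigma_vox)


def _ball(radius_mm: float, voxel_size_mm) -> np.ndarray:
    sizes = np.broadcast_to(voxel_size_mm, (3,)).astype(float)
    half = np.floor(radius_mm / sizes).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) * s
                          for h, s in zip(half, sizes)], indexing="ij")
    return sum(g ** 2 for g in grids) <= radius_mm ** 2


def vein_mask(filtered: np.ndarray, threshold_rad: float = DEFAULT_VEIN_THRESHOLD_RAD,
              voxel_size_mm=(1.5, 1.5, 1.5), dilation_mm: float = 2.0) -> VeinMask:
    """Threshold |filtered phase| and dilate with a spherical kernel."""
    if threshold_rad <= 0:
        raise ValueError("threshold_rad must be positive")
    core = np.abs(filtered) > threshold_rad
    if dilation_mm > 0 and core.any():
        mask = ndimage.binary_dilation(core, structure=_ball(dilation_mm,
                                                             voxel_size_mm))
    else:
        mask = core.copy()
    return VeinMask(mask, core, threshold_rad, dilation_mm,
                    tuple(np.broadcast_to(voxel_size_mm, (3,)).tolist()))


def near_vein(mask: VeinMask, distance_mm: float = 0.5,
              voxel_size_mm=None) -> np.ndarray:
    """Voxels whose center lies within ``distance_mm`` of a vein voxel center."""
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    sizes = voxel_size_mm if voxel_size_mm is not None else mask.voxel_size_mm
    if not mask.mask.any():
        return np.zeros_like(mask.mask)
    dist = ndimage.distance_transform_edt(~mask.mask, sampling=sizes)
    return dist <= distance_mm
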