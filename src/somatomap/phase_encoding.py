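"""Traveling-wave analysis: sinusoid fit, coherence/phase maps, fingertip ROIs.

A voxel's phase at the stimulation frequency encodes its preferred finger;
coherence (spectral amplitude at the stimulation frequency over total non-DC
amplitude) indexes response reliability.  ROIs are connected components of
supra-threshold gray-matter voxels within each of five 2*pi/5 phase bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .timeseries_prep import BoldRun

logger = logging.getLogger(__name__)

__all__ = [
    "PhaseMaps",
    "FingertipROI",
    "fit_sinusoid",
    "combine_forward_reverse",
    "define_fingertip_rois",
    "build_analysis_volume",
    "roi_center_of_mass",
    "coherence_to_p",
]


@dataclass
class PhaseMaps:
    """Per-voxel amplitude, phase in [0, 2*pi) and coherence in [0, 1]."""

    amplitude: np.ndarray
    phase: np.ndarray
    coherence: np.ndarray
    stim_freq_cycles_per_run: int
    n_time: int


@dataclass
class FingertipROI:
    """One finger's localizer-defined region."""

    finger: int                       # 1..5
    voxels: np.ndarray                # boolean volume
    compartment: str = "whole"        # whole | anterior | posterior

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


def fit_sinusoid(run: BoldRun, stim_freq_cycles_per_run: int) -> PhaseMaps:
    """DFT-based sinusoid fit at an integer stimulation frequency.

    Phase follows the convention ``x(t) = A cos(2 pi f0 t / N - phi)`` with
    ``phi`` in [0, 2*pi); coherence is the amplitude at the stimulation
    frequency divided by the root-sum-square over all positive frequencies
    (DC excluded, consistent with mean-zero percent-signal input).
    """
    if run.units != "percent":
        raise ValueError("fit_sinusoid expects percent-signal data")
    n = run.n_time
    k = int(stim_freq_cycles_per_run)
    if not 1 <= k < n / 2:
        raise ValueError(f"stimulation frequency bin {k} outside (0, Nyquist)")
    spectrum = np.fft.rfft(run.data, axis=-1)
    amps = np.abs(spectrum[..., 1:])
    total = np.sqrt((amps ** 2).sum(axis=-1))
    target = spectrum[..., k]
    amplitude = 2.0 * np.abs(target) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(total > 0, np.abs(target) / total, 0.0)
    phase = np.mod(-np.angle(target), 2 * np.pi)
    phase = np.where(np.abs(target) > 0, phase, np.nan)
    return PhaseMaps(amplitude, phase, coherence, k, n)


def combine_forward_reverse(fwd: BoldRun, rev: BoldRun) -> BoldRun:
    """Average a forward run with the time-mirror of a reverse run.

    The reverse run is reversed in time and rolled by one sample so that
    sample times align under periodic mirroring; first-order hemodynamic
    phase delays then cancel in the average.
    """
    if fwd.n_time != rev.n_time or fwd.tr_s != rev.tr_s:
        raise ValueError("forward/reverse runs must match in length and TR")
    mirrored = np.roll(rev.data[..., ::-1], 1, axis=-1)
    return replace(fwd, data=0.5 * (fwd.data + mirrored))


def _phase_bin(phase: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Half-open bins [2 pi (b-1)/n, 2 pi b/n); returns 1..n (0 where NaN)."""
    b = np.floor(phase / (2 * np.pi / n_bins)).astype(float) + 1
    b = np.where(np.isfinite(phase), np.clip(b, 1, n_bins), 0)
    return b.astype(int)


def define_fingertip_rois(
    maps: PhaseMaps,
    gray_mask: np.ndarray,
    coherence_threshold: float = 0.25,
    n_bins: int = 5,
    connectivity: int = 6,
) -> list[FingertipROI]:
    """Largest connected component per phase bin above the coherence threshold.

    Connectivity is 6 (face-adjacent) by default; pass 26 for full adjacency.
    Empty bins yield empty ROIs with a logged warning.
    """
    if maps.coherence.shape != gray_mask.shape:
        raise ValueError("maps and gray mask must be congruent")
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(gray_mask.ndim, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(gray_mask.ndim, gray_mask.ndim)
    else:
        raise ValueError("connectivity must be 6 or 26")
    bins = _phase_bin(maps.phase, n_bins)
    supra = gray_mask & (maps.coherence > coherence_threshold)
    rois = []
    for finger in range(1, n_bins + 1):
        candidate = supra & (bins == finger)
        labeled, n_comp = ndimage.label(candidate, structure=structure)
        if n_comp == 0:
            logger.warning("finger %d: no supra-threshold voxels", finger)
            rois.append(FingertipROI(finger, np.zeros_like(gray_mask)))
            continue
        sizes = ndimage.sum_labels(candidate, labeled, range(1, n_comp + 1))
        best = int(np.argmax(sizes)) + 1
        if n_comp > 1:
            logger.info("finger %d: kept largest of %d components", finger, n_comp)
        rois.append(FingertipROI(finger, labeled == best))
    return rois


def build_analysis_volume(
    rois: list[FingertipROI],
    brain_mask: np.ndarray,
    radius_voxels: float = 5.0,
    metric: str = "euclidean",
) -> np.ndarray:
    """Brain voxels within ``radius_voxels`` of any ROI voxel.

    Euclidean radius (lattice ball) by default; ``metric='chebyshev'`` gives
    a cube instead.
    """
    union = np.zeros_like(brain_mask)
    for roi in rois:
        union |= roi.voxels
    if not union.any():
        raise ValueError("all ROIs are empty")
    if metric == "euclidean":
        dist = ndimage.distance_transform_edt(~union)
        expanded = dist <= radius_voxels
    elif metric == "chebyshev":
        dist = ndimage.distance_transform_cdt(~union, metric="chessboard")
        expanded = dist <= radius_voxels
    else:
        raise ValueError("metric must be 'euclidean' or 'chebyshev'")
    return expanded & brain_mask


def roi_center_of_mass(roi: FingertipROI,
                       voxel_size_mm) -> np.ndarray:
    """Unweighted mean of member voxel centers, in mm (0-based, center at
    index * size)."""
    if roi.n_voxels == 0:
        raise ValueError(f"ROI for finger {roi.finger} is empty")
    idx = np.argwhere(roi.voxels)
    return idx.mean(axis=0) * np.asarray(voxel_size_mm, dtype=float)


def coherence_to_p(coherence: float | np.ndarray, n_time: int) -> np.ndarray:
    """Uncorrected p-value of an observed coherence under the white-noise null.

    For Gaussian noise, coherence^2 at one bin out of K positive-frequency
    bins follows Beta(1, K-1); the mapping depends on the series length
    through K = floor(n_time / 2).
    """
    k_bins = n_time // 2
    c = np.asarray(coherence, dtype=float)
    return (1.0 - c ** 2) ** (k_bins - 1)
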