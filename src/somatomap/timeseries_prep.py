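"""Time-series preprocessing: high-pass filtering and percent-signal conversion.

Both operations act on :class:`BoldRun` objects, whose data array keeps time
as the last axis (NIfTI 4D convention).  The filter is a brick-wall DFT
component removal -- zero phase and exactly testable pass/stop behaviour --
rather than an IIR design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BoldRun", "highpass", "highpass_matrix", "to_percent_signal"]


@dataclass
class BoldRun:
    """A 4D BOLD run: spatial axes first, time last.

    Parameters
    ----------
    data : ndarray, shape (..., n_time)
        Voxel time series.  Spatial layout is arbitrary but usually
        ``(nx, ny, nz, n_time)``.
    tr_s : float
        Repetition time in seconds.
    units : {"raw", "percent"}
        Unit state.  Transitions only raw -> percent.
    mask : ndarray of bool or None
        Brain mask congruent with the spatial axes.
    invalid : ndarray of bool or None
        Voxels flagged invalid (e.g. non-positive mean at conversion).
    """

    data: np.ndarray
    tr_s: float = 2.0
    units: str = "raw"
    mask: np.ndarray | None = None
    invalid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[-1] < 2:
            raise ValueError("BoldRun needs at least 2 time points")
        if self.units not in ("raw", "percent"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def n_time(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.data.shape[:-1]

    def flat(self) -> np.ndarray:
        """View the data as (n_voxels, n_time)."""
        return self.data.reshape(-1, self.n_time)


def highpass(run: BoldRun, cutoff_hz: float = 0.01) -> BoldRun:
    """Remove Fourier components strictly below ``cutoff_hz`` (keeping DC).

    The filter is idempotent and zero-phase by construction.
    """
    if run.units != "raw":
        raise ValueError("highpass expects raw units (filter before conversion)")
    nyquist = 0.5 / run.tr_s
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    n = run.n_time
    freqs = np.fft.rfftfreq(n, d=run.tr_s)
    spectrum = np.fft.rfft(run.data, axis=-1)
    stop = (freqs > 0) & (freqs < cutoff_hz)
    spectrum[..., stop] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=-1)
    return replace(run, data=filtered)


def highpass_matrix(matrix: np.ndarray, tr_s: float,
                    cutoff_hz: float = 0.01,
                    run_lengths=None) -> np.ndarray:
    """Apply the brick-wall high-pass to design-matrix columns, per run.

    Regressors must be filtered exactly like the data, otherwise the
    filter's passband mismatch biases the fitted coefficients.
    """
    matrix = np.asarray(matrix, dtype=float)
    lengths = run_lengths if run_lengths is not None else [matrix.shape[0]]
    if sum(lengths) != matrix.shape[0]:
        raise ValueError("run_lengths must sum to the number of rows")
    out = np.empty_like(matrix)
    start = 0
    for ln in lengths:
        block = matrix[start:start + ln]
        freqs = np.fft.rfftfreq(ln, d=tr_s)
        spec = np.fft.rfft(block, axis=0)
        spec[(freqs > 0) & (freqs < cutoff_hz)] = 0.0
        out[start:start + ln] = np.fft.irfft(spec, n=ln, axis=0)
        start += ln
    return out


def to_percent_signal(run: BoldRun) -> BoldRun:
    """Convert to percent-signal change: ``x -> 100 * (x - mean) / mean``.

    Voxels with non-positive temporal mean (inside the mask, if any) are set
    to NaN, flagged in ``invalid`` and logged; they never propagate silently.
    """
    if run.units != "raw":
        raise ValueError("run already converted")
    mean = run.data.mean(axis=-1)
    bad = mean <= 0
    if run.mask is not None:
        bad_in_mask = bad & run.mask
    else:
        bad_in_mask = bad
    if bad_in_mask.any():
        n_bad = int(bad_in_mask.sum())
        logger.warning("%d voxels with non-positive mean flagged invalid", n_bad)
        warnings.warn(f"{n_bad} voxels with non-positive mean set invalid",
                      RuntimeWarning, stacklevel=2)
    safe_mean = np.where(bad, 1.0, mean)
    pct = 100.0 * (run.data - mean[..., None]) / safe_mean[..., None]
    pct[bad] = np.nan
    invalid = bad_in_mask if bad_in_mask.any() else run.invalid
    return replace(run, data=pct, units="percent", invalid=invalid)
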