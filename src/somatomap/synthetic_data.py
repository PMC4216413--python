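"""Synthetic phantoms, paradigms, BOLD runs and vein phase volumes.

Everything the analysis chain consumes can be generated here with known
ground truth: a somatotopic phantom with five partially overlapping finger
bands (narrow tuning anteriorly, broad posteriorly), event-related and
cyclic phase-encoding paradigms, a linear BOLD forward model with AR(1)
noise and slow drift, and a wrapped phase volume with vein-like features.

Seeding: every generator takes one integer seed; multi-run generators derive
per-run sub-seeds as ``seed + run_index`` (documented, reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hrf_design import HRFTiming, double_gamma
from .timeseries_prep import BoldRun

__all__ = [
    "Phantom",
    "ParadigmER",
    "ParadigmPE",
    "NoiseSpec",
    "VeinPhantom",
    "make_somatotopic_phantom",
    "make_er_paradigm",
    "make_pe_paradigm",
    "simulate_bold",
    "make_vein_phantom",
]

COMPARTMENT_NONE = 0
COMPARTMENT_ANTERIOR = 1
COMPARTMENT_POSTERIOR = 2

#: Spacing between adjacent finger band centers (mm); matches the observed
#: adjacent-ROI cortical distances (~5.5 mm).
DEFAULT_BAND_SPACING_MM = 5.5
#: Center of the finger-1 band along axis 0 (mm).  Chosen so no voxel center
#: of the default 1.5 mm lattice falls exactly midway between two bands
#: (avoids preferred-finger ties).
DEFAULT_BAND_START_MM = 10.0


@dataclass
class Phantom:
    """Somatotopic phantom with per-voxel fingertip tuning and ground truth."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    tuning: np.ndarray                # (nx, ny, nz, 5) weights in [0, 1]
    compartment: np.ndarray           # int codes: 0 none, 1 anterior, 2 posterior
    gray_mask: np.ndarray
    brain_mask: np.ndarray
    band_centers_mm: np.ndarray = field(default=None, repr=False)

    @property
    def preferred_finger(self) -> np.ndarray:
        """Argmax finger (1..5) per gray voxel; 0 outside gray matter."""
        pref = np.argmax(self.tuning, axis=-1) + 1
        return np.where(self.gray_mask, pref, 0)


@dataclass
class ParadigmER:
    """Event-related paradigm: 30 trials (6 per finger), block-constrained."""

    events: list[tuple[float, int]]   # (onset_s, finger 1..5)
    run_duration_s: float
    tr_s: float = 2.0
    trial_model_duration_s: float = 1.0

    def validate(self) -> None:
        onsets = [on for on, _ in self.events]
        fingers = [f for _, f in self.events]
        if len(self.events) != 30:
            raise ValueError("ER run must contain 30 events")
        for f in range(1, 6):
            if fingers.count(f) != 6:
                raise ValueError(f"finger {f} must occur exactly 6 times")
        for on in onsets:
            if abs(on / self.tr_s - round(on / self.tr_s)) > 1e-9:
                raise ValueError("onsets must be multiples of TR")
        itis = np.diff(onsets)
        if not set(np.round(itis, 6)) <= {4.0, 6.0, 8.0, 10.0, 12.0}:
            raise ValueError("ITIs must lie in {4, 6, 8, 10, 12} s")
        for b in range(6):
            if sorted(fingers[5 * b: 5 * b + 5]) != [1, 2, 3, 4, 5]:
                raise ValueError(f"block {b} is not a permutation of fingers 1-5")

    def stimulus_trains(self, dt: float) -> np.ndarray:
        """(5, n_samples) boxcar indicator per finger on a ``dt`` grid."""
        n = int(round(self.run_duration_s / dt))
        trains = np.zeros((5, n))
        for onset, f in self.events:
            i0 = int(round(onset / dt))
            i1 = min(i0 + int(round(self.trial_model_duration_s / dt)), n)
            trains[f - 1, i0:i1] = 1.0
        return trains

    @property
    def periodic(self) -> bool:
        return False


@dataclass
class ParadigmPE:
    """Cyclic phase-encoding paradigm: fingers stimulated in fixed order."""

    cycle_period_s: float
    n_cycles: int
    direction: str = "forward"
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        epoch = self.cycle_period_s / 5.0
        if abs(epoch / self.tr_s - round(epoch / self.tr_s)) > 1e-9:
            raise ValueError("cycle_period_s must be divisible by 5 x TR")

    @property
    def run_duration_s(self) -> float:
        return self.cycle_period_s * self.n_cycles

    @property
    def stim_freq_cycles_per_run(self) -> int:
        return self.n_cycles

    def finger_epochs(self) -> list[tuple[float, float, int]]:
        """(start_s, end_s, finger) covering one cycle."""
        epoch = self.cycle_period_s / 5.0
        order = range(1, 6) if self.direction == "forward" else range(5, 0, -1)
        return [(i * epoch, (i + 1) * epoch, f) for i, f in enumerate(order)]

    def stimulus_trains(self, dt: float) -> np.ndarray:
        n = int(round(self.run_duration_s / dt))
        t = (np.arange(n) * dt) % self.cycle_period_s
        trains = np.zeros((5, n))
        for start, end, f in self.finger_epochs():
            trains[f - 1, (t >= start) & (t < end)] = 1.0
        return trains

    @property
    def periodic(self) -> bool:
        return True


@dataclass(frozen=True)
class NoiseSpec:
    """AR(1) noise plus one slow sinusoidal drift, in percent-signal units."""

    sigma: float = 0.3
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    drift_period_s: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ar1_rho) < 1:
            raise ValueError("stationary AR(1) requires |rho| < 1")


@dataclass
class VeinPhantom:
    """Wrapped phase volume with known vein locations."""

    phase_volume: np.ndarray          # radians in (-pi, pi]
    true_vein_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]


def make_somatotopic_phantom(
    grid_shape: tuple[int, int, int] = (32, 32, 8),
    anterior_fraction: float = 0.5,
    sigma_tuning_anterior_mm: float = 2.0,
    sigma_tuning_posterior_mm: float = 4.0,
    voxel_size_mm: float | tuple[float, float, float] = 1.5,
    band_spacing_mm: float = DEFAULT_BAND_SPACING_MM,
    band_start_mm: float = DEFAULT_BAND_START_MM,
    far_posterior_fraction: float = 0.2,
    far_posterior_tuning: float = 0.7,
    seed: int = 0,
) -> Phantom:
    """Five parallel finger bands along axis 0, compartments split on axis 1.

    Tuning of voxel ``v`` to finger ``f`` is ``exp(-d^2 / (2 sigma^2))`` with
    ``d`` the axis-0 distance (mm) to the finger-f band center and ``sigma``
    set by the voxel's compartment (anterior voxels are more narrowly tuned
    than posterior ones by default).

    The most posterior ``far_posterior_fraction`` of the gray slab gets
    uniform tuning to all five fingers: such voxels respond to every finger
    in an event-related run but carry (almost) no power at the fundamental
    of a traveling-wave run, so the localizer is blind to them -- the
    rationale for expanding the analysis volume beyond the ROIs.
    """
    if sigma_tuning_anterior_mm <= 0 or sigma_tuning_posterior_mm <= 0:
        raise ValueError("tuning sigmas must be positive")
    if any(n <= 0 for n in grid_shape):
        raise ValueError("grid_shape must be positive")
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    nx, ny, nz = grid_shape

    x_mm = np.arange(nx) * voxel_size_mm[0]
    centers = band_start_mm + band_spacing_mm * np.arange(5)

    brain = np.ones(grid_shape, dtype=bool)
    gray = np.zeros(grid_shape, dtype=bool)
    gray[1:-1, 1:-1, :] = True          # 1-voxel non-gray rim in-plane
    # restrict gray to the mapped band region (plus half a spacing on each
    # side) so every gray voxel carries measurable tuning
    in_bands = ((x_mm >= centers[0] - band_spacing_mm / 2)
                & (x_mm <= centers[-1] + band_spacing_mm / 2))
    gray &= in_bands[:, None, None]

    split = int(round(anterior_fraction * ny))
    compartment = np.zeros(grid_shape, dtype=np.int8)
    comp_plane = np.where(np.arange(ny) < split, COMPARTMENT_ANTERIOR,
                          COMPARTMENT_POSTERIOR)
    compartment[:] = comp_plane[None, :, None]
    compartment[~gray] = COMPARTMENT_NONE

    sigma = np.where(compartment == COMPARTMENT_ANTERIOR,
                     sigma_tuning_anterior_mm, sigma_tuning_posterior_mm)
    d = x_mm[:, None, None, None] - centers[None, None, None, :]   # (nx,1,1,5)
    tuning = np.exp(-d ** 2 / (2.0 * sigma[..., None] ** 2))
    far_start = int(round((1.0 - far_posterior_fraction) * ny))
    if far_start < ny:
        tuning[:, far_start:, :, :] = far_posterior_tuning
    tuning[~gray] = 0.0
    return Phantom(tuple(grid_shape), voxel_size_mm, tuning, compartment,
                   gray, brain, band_centers_mm=centers)


_ITI_CHOICES_S = (4.0, 6.0, 8.0, 10.0, 12.0)


def make_er_paradigm(n_runs: int, seed: int = 0, tr_s: float = 2.0,
                     tail_s: float = 20.0) -> list[ParadigmER]:
    """Generate ER runs: 6 blocks of 5 trials, each block a random permutation
    of the five fingers; ITIs uniform on {4, 6, 8, 10, 12} s; onsets on the
    volume grid.  Run ``i`` uses sub-seed ``seed + i``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = []
    for i in range(n_runs):
        rng = np.random.default_rng(seed + i)
        fingers = np.concatenate([rng.permutation(5) + 1 for _ in range(6)])
        itis = rng.choice(_ITI_CHOICES_S, size=29)
        onsets = np.concatenate([[0.0], np.cumsum(itis)])
        events = list(zip(onsets.tolist(), fingers.tolist()))
        duration = onsets[-1] + tail_s
        duration = np.ceil(duration / tr_s) * tr_s
        run = ParadigmER(events, float(duration), tr_s)
        run.validate()
        runs.append(run)
    return runs


def make_pe_paradigm(cycle_period_s: float, n_cycles: int,
                     direction: str = "forward", tr_s: float = 2.0) -> ParadigmPE:
    """Cyclic paradigm; period must divide evenly into five TR-aligned epochs."""
    return ParadigmPE(cycle_period_s, n_cycles, direction, tr_s)


def _ar1_noise(rng: np.random.Generator, shape_spatial, n_time: int,
               sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series with marginal std ``sigma``."""
    innov_sd = sigma * np.sqrt(1.0 - rho ** 2)
    eps = rng.standard_normal(shape_spatial + (n_time,))
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0] * sigma
    for t in range(1, n_time):
        out[..., t] = rho * out[..., t - 1] + innov_sd * eps[..., t]
    return out


def simulate_bold(
    phantom: Phantom,
    paradigm,
    noise: NoiseSpec,
    timing: HRFTiming | None = None,
    amplitude_percent: float = 1.5,
    baseline: float = 100.0,
    hrf_duration_s: float = 32.0,
) -> BoldRun:
    """Linear forward model on top of baseline 100.

    ``signal(v, t) = sum_f tuning(v, f) * (stim_f (*) h)(t)``, scaled so a
    unit-tuning voxel's single 1 s trial peaks at ``amplitude_percent`` of
    baseline, plus AR(1) noise and one sinusoidal drift (both in percent
    units).  Periodic paradigms are convolved circularly (steady state).
    """
    if timing is None:
        timing = HRFTiming()
    dt = timing.dt_s
    tr = paradigm.tr_s
    h = double_gamma(timing, hrf_duration_s)
    trains = paradigm.stimulus_trains(dt)
    if trains.shape[0] != phantom.tuning.shape[-1]:
        raise ValueError("paradigm/phantom finger-count mismatch")

    # unit-trial peak used as the percent-signal scale anchor
    trial = np.zeros_like(h)
    trial[: int(round(1.0 / dt))] = 1.0
    peak = np.convolve(trial, h).max()

    n_fine = trains.shape[1]
    if getattr(paradigm, "periodic", False):
        responses = np.array([
            np.real(np.fft.ifft(np.fft.fft(tr_f) * np.fft.fft(h, n_fine)))
            for tr_f in trains
        ])
    else:
        responses = np.array([np.convolve(tr_f, h)[:n_fine] for tr_f in trains])
    responses *= amplitude_percent / peak

    n_vol = int(round(paradigm.run_duration_s / tr))
    vol_idx = (np.arange(n_vol) * round(tr / dt)).astype(int)
    resp_tr = responses[:, vol_idx]                       # (5, n_vol)

    signal_pct = np.tensordot(phantom.tuning, resp_tr, axes=([3], [0]))

    rng = np.random.default_rng(noise.seed)
    data = np.full(phantom.grid_shape + (n_vol,), 0.0)
    data += signal_pct
    if noise.drift_amplitude != 0:
        t_s = np.arange(n_vol) * tr
        phase0 = rng.uniform(0, 2 * np.pi, size=phantom.grid_shape)
        drift = noise.drift_amplitude * np.sin(
            2 * np.pi * t_s / noise.drift_period_s + phase0[..., None])
        data += drift
    if noise.sigma > 0:
        data += _ar1_noise(rng, phantom.grid_shape, n_vol,
                           noise.sigma, noise.ar1_rho)
    raw = baseline * (1.0 + data / 100.0)
    return BoldRun(raw, tr_s=tr, units="raw", mask=phantom.brain_mask)


def make_vein_phantom(
    grid_shape: tuple[int, int, int] = (48, 48, 16),
    n_veins: int = 6,
    background_gradient_rad: float = 4.0 * np.pi,
    voxel_size_mm: float | tuple[float, float, float] = 1.5,
    vein_amplitude_rad: float = 2.5,
    vein_radius_mm: float = 1.0,
    seed: int = 0,
) -> VeinPhantom:
    """Wrapped phase volume: smooth ramp background + tube-shaped deviations.

    The background is a linear ramp along axis 0 spanning
    ``background_gradient_rad`` (it wraps when the span exceeds 2 pi).  Each
    vein is a straight tube parallel to a random axis with a Gaussian
    cross-section of scale ``vein_radius_mm``; the true mask records voxels
    within one radius of a tube axis.
    """
    if n_veins < 0:
        raise ValueError("n_veins must be >= 0")
    if np.isscalar(voxel_size_mm):
        voxel_size_mm = (float(voxel_size_mm),) * 3
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    coords = [np.arange(n) * s for n, s in zip(grid_shape, voxel_size_mm)]

    ramp = np.zeros(grid_shape)
    if background_gradient_rad != 0 and nx > 1:
        ramp += (background_gradient_rad
                 * (coords[0] / coords[0][-1]))[:, None, None]

    veins = np.zeros(grid_shape)
    true_mask = np.zeros(grid_shape, dtype=bool)
    grids = np.meshgrid(*coords, indexing="ij")
    for _ in range(n_veins):
        axis = int(rng.integers(0, 3))
        other = [a for a in range(3) if a != axis]
        c = [rng.uniform(coords[a][0], coords[a][-1]) for a in other]
        r2 = ((grids[other[0]] - c[0]) ** 2 + (grids[other[1]] - c[1]) ** 2)
        sign = rng.choice([-1.0, 1.0])
        veins += sign * vein_amplitude_rad * np.exp(-r2 / (2 * vein_radius_mm ** 2))
        true_mask |= r2 <= vein_radius_mm ** 2

    wrapped = np.angle(np.exp(1j * (ramp + veins)))
    return VeinPhantom(wrapped, true_mask, voxel_size_mm)
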