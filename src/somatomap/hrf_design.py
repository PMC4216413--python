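"""Canonical double-gamma HRF, orthogonalized derivative, and design matrices.

The canonical response is a difference of two gamma densities with unit
dispersion (scale 1 s); the shape of each gamma is ``time_to_peak + 1`` so
the density's mode falls exactly at the requested time to peak.  The curve
is normalized to unit maximum.

Design matrices come in two flavours:

- canonical: per finger, a 1 s boxcar train convolved with the HRF and with
  its orthogonalized temporal derivative (10 task columns);
- FIR: per finger, time-shifted indicator columns, one per lag 0..12 TRs
  (65 task columns), for nonparametric HRF deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HRFTiming",
    "DesignMatrix",
    "double_gamma",
    "orthogonalized_derivative",
    "build_canonical_design",
    "build_fir_design",
    "hrf_peak_times",
    "timing_from_peak_times",
]

OVERSAMPLE_DT_S = 0.1  # fine grid for convolving sub-TR boxcars


@dataclass(frozen=True)
class HRFTiming:
    """Timing parameters of the double-gamma HRF."""

    t_peak_pos_s: float = 6.0
    t_peak_neg_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dt_s: float = OVERSAMPLE_DT_S

    def __post_init__(self) -> None:
        if not 0 < self.t_peak_pos_s < self.t_peak_neg_s:
            raise ValueError("need 0 < t_peak_pos_s < t_peak_neg_s")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot_ratio must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")


@dataclass
class DesignMatrix:
    """Labeled time-by-regressor design.

    ``labels`` holds (finger, component) pairs; component is "magnitude" /
    "derivative" for canonical designs and "lag_<k>" for FIR designs.
    ``kernels`` (canonical only) maps each column label to its effective
    fine-grid response kernel, used to reconstruct fitted HRF shapes.
    """

    matrix: np.ndarray
    labels: list[tuple[int, str]]
    tr_s: float
    kernels: dict[tuple[int, str], np.ndarray] | None = field(default=None, repr=False)
    dt_fine_s: float | None = None
    deriv_mix: dict[int, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")

    @property
    def n_time(self) -> int:
        return self.matrix.shape[0]

    def column(self, finger: int, component: str) -> np.ndarray:
        return self.matrix[:, self.labels.index((finger, component))]

    def to_tsv(self, path) -> None:
        header = "\t".join(f"f{f}_{c}" for f, c in self.labels)
        np.savetxt(path, self.matrix, delimiter="\t", header=header, comments="")


def double_gamma(timing: HRFTiming, duration_s: float = 32.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF on ``timing.dt_s`` steps.

    Returns ``h`` with ``max(h) == 1`` exactly and ``h[0] == 0``.
    """
    if duration_s <= timing.t_peak_neg_s:
        raise ValueError("duration_s must exceed t_peak_neg_s")
    t = np.arange(0.0, duration_s + timing.dt_s / 2, timing.dt_s)
    pos = stats.gamma.pdf(t, a=timing.t_peak_pos_s + 1.0, scale=1.0)
    neg = stats.gamma.pdf(t, a=timing.t_peak_neg_s + 1.0, scale=1.0)
    h = pos / pos.max() - timing.undershoot_ratio * neg / neg.max()
    return h / h.max()


def orthogonalized_derivative(h: np.ndarray, dt_s: float = OVERSAMPLE_DT_S) -> np.ndarray:
    """Finite-difference dh/dt, Gram-Schmidt orthogonalized against h."""
    h = np.asarray(h, dtype=float)
    dh = np.gradient(h, dt_s)
    hh = float(h @ h)
    if hh == 0 or not np.any(dh):
        warnings.warn("constant HRF: derivative regressor is zero",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(h)
    return dh - (float(dh @ h) / hh) * h


def _boxcar_train(onsets_s, duration_s: float, run_duration_s: float,
                  dt: float) -> np.ndarray:
    n = int(round(run_duration_s / dt))
    train = np.zeros(n)
    for onset in onsets_s:
        if onset < 0 or onset >= run_duration_s:
            raise ValueError(f"event onset {onset} s outside run")
        i0 = int(round(onset / dt))
        i1 = min(i0 + int(round(duration_s / dt)), n)
        train[i0:i1] = 1.0
    return train


#: the negative peak is searched within this window after the positive peak
#: (physiological undershoot delays run ~6-12 s; an unbounded search can
#: drift into flat numerical tails)
UNDERSHOOT_WINDOW_S = 14.0


def peak_times_of_curve(h: np.ndarray, dt_s: float) -> tuple[float, float]:
    """Argmax of a sampled HRF-like curve and the subsequent argmin, the
    latter restricted to ``UNDERSHOOT_WINDOW_S`` after the positive peak."""
    i_pos = int(np.argmax(h))
    i_hi = min(i_pos + 1 + int(round(UNDERSHOOT_WINDOW_S / dt_s)), h.size)
    i_neg = i_pos + 1 + int(np.argmin(h[i_pos + 1: i_hi]))
    return i_pos * dt_s, i_neg * dt_s


def hrf_peak_times(timing: HRFTiming,
                   dt_s: float = 0.01) -> tuple[float, float]:
    """Numeric positive/negative peak locations of the double-gamma curve.

    Because the positive gamma's tail overlaps the undershoot, the curve's
    actual extrema sit slightly away from the nominal timing parameters;
    this function measures them on a fine grid.
    """
    fine = HRFTiming(timing.t_peak_pos_s, timing.t_peak_neg_s,
                     timing.undershoot_ratio, dt_s)
    duration = max(32.0, timing.t_peak_neg_s + UNDERSHOOT_WINDOW_S + 2.0)
    return peak_times_of_curve(double_gamma(fine, duration), dt_s)


def timing_from_peak_times(peak_pos_s: float, peak_neg_s: float,
                           undershoot_ratio: float = 1.0 / 6.0,
                           dt_s: float = 0.01) -> HRFTiming:
    """Invert :func:`hrf_peak_times`: gamma timing parameters whose curve
    peaks at the measured locations.

    The positive-peak parameter is solved by damped fixed-point iteration
    (the map is near-identity there); the negative-peak parameter by
    bisection, since the measured undershoot location increases
    monotonically with it.  Targets outside the attainable range are
    clamped to the nearest bound.
    """
    if not 0 < peak_pos_s < peak_neg_s:
        raise ValueError("need 0 < peak_pos_s < peak_neg_s")
    t1 = peak_pos_s
    t2 = max(peak_neg_s, t1 + 2.0)
    for _ in range(3):
        # positive peak: damped fixed point
        for _ in range(30):
            c1, _ = hrf_peak_times(HRFTiming(t1, max(t2, t1 + 1.0),
                                             undershoot_ratio), dt_s)
            e1 = peak_pos_s - c1
            if abs(e1) < dt_s:
                break
            t1 = max(t1 + 0.8 * e1, 0.5)
        # negative peak: the map t2 -> measured undershoot location is
        # V-shaped; solve on its increasing (physiological) right branch by
        # walking down from large t2 to bracket the crossing, then bisect.
        def c2_at(t2v: float) -> float:
            return hrf_peak_times(HRFTiming(t1, t2v, undershoot_ratio),
                                  dt_s)[1]

        grid = np.arange(t1 + UNDERSHOOT_WINDOW_S + 4.0, t1 + 1.0, -0.25)
        bracket = None
        prev = grid[0]
        for t2v in grid[1:]:
            if c2_at(t2v) < peak_neg_s:
                bracket = (t2v, prev)
                break
            prev = t2v
        if bracket is None:
            # target below the attainable minimum: clamp to the argmin
            cands = np.arange(t1 + 1.0, t1 + UNDERSHOOT_WINDOW_S, 0.25)
            t2 = float(cands[np.argmin([abs(c2_at(c) - peak_neg_s)
                                        for c in cands])])
        else:
            lo, hi = bracket
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if c2_at(mid) < peak_neg_s:
                    lo = mid
                else:
                    hi = mid
                if hi - lo < dt_s:
                    break
            t2 = 0.5 * (lo + hi)
    return HRFTiming(t1, t2, undershoot_ratio)


def _as_paradigm_list(paradigm) -> list:
    return list(paradigm) if isinstance(paradigm, (list, tuple)) else [paradigm]


def build_canonical_design(paradigm, timing: HRFTiming,
                           hrf_duration_s: float = 32.0) -> DesignMatrix:
    """Canonical ER design: 10 task columns (magnitude + derivative per finger).

    ``paradigm`` may be a single run or a list of runs; multi-run designs
    are convolved per run (no cross-run bleed) and stacked in time.  Boxcar
    trains are convolved on a 0.1 s grid and decimated to volume times.
    Each derivative column is residualized against its own finger's
    magnitude column per run, so within-finger orthogonality holds exactly
    and the design of concatenated paradigms equals the concatenation of
    per-run designs; the (run-averaged) mixing coefficient is folded into
    the stored effective kernels.
    """
    paradigms = _as_paradigm_list(paradigm)
    dt = timing.dt_s
    h = double_gamma(timing, hrf_duration_s)
    dh = orthogonalized_derivative(h, dt)
    tr = paradigms[0].tr_s

    # normalize by the single-trial peak so magnitude betas read directly as
    # peak percent-signal amplitudes
    trial = np.zeros_like(h)
    trial[: int(round(paradigms[0].trial_model_duration_s / dt))] = 1.0
    peak = np.convolve(trial, h).max()
    h = h / peak
    dh = dh / peak

    columns, labels, kernels, mixes = [], [], {}, {}
    for finger in range(1, 6):
        mag_parts, der_parts, run_mixes = [], [], []
        for par in paradigms:
            if par.tr_s != tr:
                raise ValueError("all runs must share one TR")
            run_dur = par.run_duration_s
            n_vol = int(round(run_dur / tr))
            vol_idx = (np.arange(n_vol) * round(tr / dt)).astype(int)
            onsets = [on for on, f in par.events if f == finger]
            train = _boxcar_train(onsets, par.trial_model_duration_s,
                                  run_dur, dt)
            mag_r = np.convolve(train, h)[: len(train)][vol_idx]
            der_r = np.convolve(train, dh)[: len(train)][vol_idx]
            norm2 = float(mag_r @ mag_r)
            mix_r = float(der_r @ mag_r) / norm2 if norm2 > 0 else 0.0
            mag_parts.append(mag_r)
            der_parts.append(der_r - mix_r * mag_r)
            run_mixes.append(mix_r)
        mag = np.concatenate(mag_parts)
        der = np.concatenate(der_parts)
        mix = float(np.mean(run_mixes))
        columns += [mag, der]
        labels += [(finger, "magnitude"), (finger, "derivative")]
        kernels[(finger, "magnitude")] = h
        kernels[(finger, "derivative")] = dh - mix * h
        mixes[finger] = mix
    return DesignMatrix(np.column_stack(columns), labels, tr, kernels, dt, mixes)


def build_fir_design(paradigm, n_lags: int = 13) -> DesignMatrix:
    """FIR deconvolution design: indicator columns at lags 0..n_lags-1 TRs.

    Accepts a single run or a list of runs (stacked in time, lags never
    crossing run boundaries).
    """
    paradigms = _as_paradigm_list(paradigm)
    tr = paradigms[0].tr_s
    columns = {f: [] for f in range(1, 6)}
    for par in paradigms:
        n_vol = int(round(par.run_duration_s / tr))
        for finger in range(1, 6):
            onset_vols = []
            for onset, f in par.events:
                if f != finger:
                    continue
                v = onset / tr
                if abs(v - round(v)) > 1e-9:
                    raise ValueError(f"onset {onset} s not TR-aligned")
                onset_vols.append(int(round(v)))
            block = np.zeros((n_vol, n_lags))
            for lag in range(n_lags):
                for v in onset_vols:
                    if v + lag < n_vol:
                        block[v + lag, lag] = 1.0
            columns[finger].append(block)
    cols, labels = [], []
    for finger in range(1, 6):
        stacked = np.vstack(columns[finger])
        for lag in range(n_lags):
            cols.append(stacked[:, lag])
            labels.append((finger, f"lag_{lag}"))
    return DesignMatrix(np.column_stack(cols), labels, tr)
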