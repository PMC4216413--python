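"""Event-related GLMs: OLS, subject timing estimation, tapered-ACF GLS,
one-sided contrast tests, and FIR deconvolution.

The canonical analysis is a two-step procedure: an OLS fit with default HRF
timing, reconstruction of the fitted HRF in each localizer ROI to estimate
the subject's positive/negative peak latencies, then a GLS refit using a
noise correlation matrix built from Tukey-tapered autocorrelations of
tile-averaged residuals (20 x 20 in-slice tiles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cholesky, solve_triangular, toeplitz

from .hrf_design import (DesignMatrix, HRFTiming, double_gamma,
                         orthogonalized_derivative, peak_times_of_curve,
                         timing_from_peak_times)
from .timeseries_prep import BoldRun

logger = logging.getLogger(__name__)

__all__ = [
    "GLMFit",
    "NoiseModel",
    "StatMaps",
    "fit_ols",
    "estimate_subject_timing",
    "estimate_noise_acf",
    "fit_gls",
    "contrast_ttest",
    "fit_deconvolution",
    "deconvolved_curves",
]

EIGENVALUE_FLOOR = 1e-6   # PD repair floor for tapered correlation matrices


@dataclass
class NoiseModel:
    """Tile-wise tapered noise autocorrelation.

    ``acf[i]`` is the Tukey-tapered autocorrelation sequence of tile ``i``
    (lag 0 first, zero beyond the taper length); ``tile_index`` maps each
    voxel to its tile.
    """

    acf: np.ndarray                   # (n_tiles, n_lags)
    raw_acf: np.ndarray = field(repr=False, default=None)
    tile_index: np.ndarray = None     # voxel -> tile id
    taper_m: int = 0
    tile_shape: tuple[int, int] = (20, 20)


@dataclass
class GLMFit:
    """Mass-univariate GLM fit over a spatial grid."""

    design: DesignMatrix
    x_full: np.ndarray                # (n_time, p) incl. nuisance columns
    column_labels: list[tuple[int, str]]
    beta: np.ndarray                  # (..., p)
    stderr: np.ndarray                # (..., p)
    residuals: np.ndarray = field(repr=False, default=None)  # (..., n_time)
    dof: int = 0
    sigma2: np.ndarray = field(repr=False, default=None)
    noise: NoiseModel | None = None
    method: str = "OLS"
    valid: np.ndarray = field(repr=False, default=None)

    def coef(self, finger: int, component: str) -> np.ndarray:
        return self.beta[..., self.column_labels.index((finger, component))]

    def coef_stderr(self, finger: int, component: str) -> np.ndarray:
        return self.stderr[..., self.column_labels.index((finger, component))]


@dataclass
class StatMaps:
    """Per-finger voxelwise statistics within the analysis volume."""

    t: dict[int, np.ndarray]
    p: dict[int, np.ndarray]
    p_fwe: dict[int, np.ndarray] = None
    p_fdr: dict[int, np.ndarray] = None
    z_fwe: dict[int, np.ndarray] = None
    z_fdr: dict[int, np.ndarray] = None
    analysis_volume: np.ndarray = None


def _nuisance_block(n_time: int, run_lengths) -> tuple[np.ndarray, list]:
    """Per-run intercept columns."""
    if run_lengths is None:
        run_lengths = [n_time]
    if sum(run_lengths) != n_time:
        raise ValueError("run_lengths must sum to the run length")
    cols = np.zeros((n_time, len(run_lengths)))
    start = 0
    labels = []
    for i, ln in enumerate(run_lengths):
        cols[start:start + ln, i] = 1.0
        labels.append((0, f"intercept_{i}"))
        start += ln
    return cols, labels


def _check_rank(x: np.ndarray, labels) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        dep = [labels[j] for j in range(x.shape[1])
               if abs(r[j, j]) < 1e-10 * abs(r[0, 0])]
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {x.shape[1]}); "
            f"dependent columns: {dep}")


def _mass_univariate(x: np.ndarray, y_flat: np.ndarray, dof_loss: int = 0):
    """OLS solve for (n_vox, T) data; returns beta, stderr, resid, sigma2, dof."""
    n_time, p = x.shape
    dof = n_time - np.linalg.matrix_rank(x) - dof_loss
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    beta = y_flat @ x @ xtx_inv.T                          # (n_vox, p)
    resid = y_flat - beta @ x.T
    sigma2 = (resid ** 2).sum(axis=-1) / dof
    stderr = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
    return beta, stderr, resid, sigma2, dof


def _fit_linear(design: DesignMatrix, run: BoldRun, run_lengths,
                whiten=None, method="OLS", dof_loss: int = 0) -> GLMFit:
    nuis, nuis_labels = _nuisance_block(run.n_time, run_lengths)
    x = np.column_stack([design.matrix, nuis])
    labels = list(design.labels) + nuis_labels
    if x.shape[0] != run.n_time:
        raise ValueError("design rows must equal run length")
    _check_rank(x, labels)

    y = run.flat()
    valid = np.isfinite(y).all(axis=-1)
    spatial = run.spatial_shape
    p = x.shape[1]
    beta = np.full((y.shape[0], p), np.nan)
    stderr = np.full((y.shape[0], p), np.nan)
    resid = np.full_like(y, np.nan)
    sigma2 = np.full(y.shape[0], np.nan)

    if whiten is None:
        b, se, r, s2, dof = _mass_univariate(x, y[valid], dof_loss)
        beta[valid], stderr[valid], resid[valid], sigma2[valid] = b, se, r, s2
    else:
        dof = None
        for tile_voxels, w in whiten:
            sel = tile_voxels & valid
            if not sel.any():
                continue
            xw = w(x)
            yw = w(y[sel].T).T
            b, se, rw, s2, dof = _mass_univariate(xw, yw, dof_loss)
            beta[sel], stderr[sel], sigma2[sel] = b, se, s2
            resid[sel] = y[sel] - b @ x.T      # residuals in original units
        if dof is None:
            raise ValueError("no valid voxels to fit")

    shape = spatial
    return GLMFit(
        design=design, x_full=x, column_labels=labels,
        beta=beta.reshape(shape + (p,)), stderr=stderr.reshape(shape + (p,)),
        residuals=resid.reshape(shape + (run.n_time,)), dof=dof,
        sigma2=sigma2.reshape(shape), method=method,
        valid=valid.reshape(shape))


def fit_ols(design: DesignMatrix, run: BoldRun,
            run_lengths=None, dof_loss: int = 0) -> GLMFit:
    """Ordinary least-squares fit (intercept per run added automatically).

    ``dof_loss`` discounts residual degrees of freedom already removed from
    the data outside the model (e.g. high-pass-filtered frequency bins).
    """
    return _fit_linear(design, run, run_lengths, whiten=None, method="OLS",
                       dof_loss=dof_loss)


TIMING_SEARCH_DT_S = 0.01
TIMING_CURVE_DURATION_S = 40.0


def estimate_subject_timing(fit: GLMFit, rois, timing0: HRFTiming,
                            invert_to_parameters: bool = True) -> HRFTiming:
    """Estimate subject HRF timing from the step-1 OLS fit.

    For each localizer ROI, the fitted HRF of the ROI's own finger is
    reconstructed from ROI-mean magnitude/derivative betas on a 0.01 s grid;
    the positive peak is its argmax and the negative peak the subsequent
    argmin (within the undershoot window).  The measured peak times are
    averaged across ROIs and, by default, inverted through the curve-peak
    map (:func:`timing_from_peak_times`) to gamma timing parameters, so
    that a fit with ``beta_derivative == 0`` returns ``timing0`` exactly.
    With ``invert_to_parameters=False`` the raw mean peak times are
    returned instead.
    """
    fine = HRFTiming(timing0.t_peak_pos_s, timing0.t_peak_neg_s,
                     timing0.undershoot_ratio, TIMING_SEARCH_DT_S)
    h = double_gamma(fine, TIMING_CURVE_DURATION_S)
    dh = orthogonalized_derivative(h, TIMING_SEARCH_DT_S)

    t_pos, t_neg = [], []
    for roi in rois:
        if roi.n_voxels == 0:
            continue
        sel = roi.voxels & fit.valid
        if not sel.any():
            continue
        b_mag = float(np.nanmean(fit.coef(roi.finger, "magnitude")[sel]))
        b_der = float(np.nanmean(fit.coef(roi.finger, "derivative")[sel]))
        mix = (fit.design.deriv_mix or {}).get(roi.finger, 0.0)
        h_hat = b_mag * h + b_der * (dh - mix * h)
        if h_hat.max() <= 0:
            warnings.warn(f"ROI finger {roi.finger}: non-positive fitted HRF, "
                          "excluded from timing estimate", RuntimeWarning,
                          stacklevel=2)
            continue
        p_pos, p_neg = peak_times_of_curve(h_hat, TIMING_SEARCH_DT_S)
        t_pos.append(p_pos)
        t_neg.append(p_neg)
    if not t_pos:
        raise ValueError("no usable ROI for timing estimation")
    p_pos, p_neg = float(np.mean(t_pos)), float(np.mean(t_neg))
    if not invert_to_parameters:
        return HRFTiming(p_pos, p_neg, timing0.undershoot_ratio, timing0.dt_s)
    inv = timing_from_peak_times(p_pos, p_neg, timing0.undershoot_ratio,
                                 TIMING_SEARCH_DT_S)
    return HRFTiming(inv.t_peak_pos_s, inv.t_peak_neg_s,
                     timing0.undershoot_ratio, timing0.dt_s)


def estimate_subject_timing_nonlinear(run: BoldRun, paradigms, rois,
                                      timing_init: HRFTiming,
                                      run_lengths=None,
                                      design_filter=None) -> HRFTiming:
    """Refine subject timing by profiled nonlinear least squares.

    The canonical two-step's derivative basis spans only first-order timing
    perturbations, which leaves the undershoot parameter weakly identified
    when the subject's latency is far from the default.  This refinement
    minimizes the full GLM residual of the five ROI-mean time series over
    the two gamma timing parameters (all linear coefficients profiled out),
    which is exact in the noiseless limit.
    """
    from scipy.optimize import minimize

    from .hrf_design import build_canonical_design

    series = []
    for roi in rois:
        if roi.n_voxels == 0:
            continue
        flat = run.flat()[roi.voxels.reshape(-1)]
        flat = flat[np.isfinite(flat).all(axis=-1)]
        if len(flat):
            series.append(flat.mean(axis=0))
    if not series:
        raise ValueError("no usable ROI for timing refinement")
    y = np.column_stack(series)                       # (T, n_rois)
    nuis, _ = _nuisance_block(y.shape[0], run_lengths)

    def sse(params) -> float:
        t1, t2 = params
        if not (0.5 < t1 < 12.0 and t1 + 1.0 < t2 < 30.0):
            return 1e12
        design = build_canonical_design(paradigms,
                                        HRFTiming(t1, t2,
                                                  timing_init.undershoot_ratio))
        task = design.matrix
        if design_filter is not None:
            task = design_filter(task)
        x = np.column_stack([task, nuis])
        resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        return float((resid ** 2).sum())

    x0 = [timing_init.t_peak_pos_s, timing_init.t_peak_neg_s]
    res = minimize(sse, x0, method="Nelder-Mead",
                   options={"xatol": 0.01, "fatol": 1e-12, "maxiter": 200})
    t1, t2 = res.x
    return HRFTiming(float(t1), float(t2), timing_init.undershoot_ratio,
                     timing_init.dt_s)


def _tukey_taper(n_lags: int, m: int) -> np.ndarray:
    k = np.arange(n_lags)
    taper = 0.5 * (1.0 + np.cos(np.pi * k / m))
    taper[k > m] = 0.0
    return taper


def _acf_of(series: np.ndarray) -> np.ndarray | None:
    """Pooled autocorrelation of one or more demeaned series (rows)."""
    series = np.atleast_2d(series)
    s = series - series.mean(axis=-1, keepdims=True)
    n_time = s.shape[-1]
    spec = np.fft.rfft(s, 2 * n_time, axis=-1)
    acov = np.fft.irfft(np.abs(spec) ** 2, 2 * n_time, axis=-1)[..., :n_time]
    acov = acov.sum(axis=0)
    if acov[0] == 0:
        return None
    return acov / acov[0]


def _residual_acf_debias(raw: np.ndarray, x_model: np.ndarray,
                         n_lags: int) -> np.ndarray:
    """Invert the ACF shrinkage caused by projecting out the design.

    Residuals ``r = (I - H) e`` have autocovariances ``tr(S_k M V M)``
    instead of ``tr(S_k V)`` (``M = I - H``, ``S_k`` the lag-k shift).  The
    true ACF is recovered by a short multiplicative fixed-point iteration
    on the predicted-vs-observed normalized autocovariances.
    """
    n_time = x_model.shape[0]
    m = np.eye(n_time) - x_model @ np.linalg.pinv(x_model)
    n_lags = min(n_lags, n_time - 1)
    rho = raw[: n_lags + 1].copy()
    obs = raw[: n_lags + 1]
    for _ in range(3):
        v = toeplitz(np.r_[rho, np.zeros(n_time - n_lags - 1)])
        mvm = m @ v @ m
        pred = np.array([np.trace(mvm, offset=k) for k in range(n_lags + 1)])
        pred /= pred[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(np.abs(pred) > 1e-12, obs / pred, 1.0)
        rho = np.clip(rho * np.clip(ratio, 0.5, 2.0), -1.0, 1.0)
        rho[0] = 1.0
    out = np.zeros_like(raw)
    out[: n_lags + 1] = rho
    return out


def estimate_noise_acf(residuals: np.ndarray, brain_mask: np.ndarray,
                       tile_shape: tuple[int, int] = (20, 20),
                       taper_m: int | None = None,
                       method: str = "pooled",
                       x_model: np.ndarray | None = None) -> NoiseModel:
    """Tukey-tapered noise ACF per in-slice residual tile.

    Tiles are fixed ``tile_shape`` squares in the first two (in-slice) axes,
    one set per slice, anchored at index 0.  Tiles without brain voxels
    inherit the nearest populated tile's ACF (logged).

    ``method="pooled"`` (default) pools lagged products over all in-brain
    voxels of the tile, which keeps the estimate's variance low when voxel
    noise is close to independent; ``method="mean-series"`` takes the ACF of
    the tile-averaged series instead (appropriate when a common noise
    component dominates, but an order of magnitude noisier otherwise).

    ``x_model``, when given (the full design the residuals came from),
    enables an exact de-biasing of the projection-induced ACF shrinkage
    (:func:`_residual_acf_debias`).
    """
    if method not in ("pooled", "mean-series"):
        raise ValueError("method must be 'pooled' or 'mean-series'")
    nx, ny, nz, n_time = residuals.shape
    if taper_m is None:
        taper_m = int(round(2.0 * np.sqrt(n_time)))
    taper_m = min(taper_m, n_time - 1)
    n_tx = -(-nx // tile_shape[0])
    n_ty = -(-ny // tile_shape[1])

    tile_index = np.zeros((nx, ny, nz), dtype=int)
    centers, raw_list = [], []
    taper = _tukey_taper(n_time, taper_m)
    tid = 0
    for z in range(nz):
        for tx in range(n_tx):
            for ty in range(n_ty):
                sx = slice(tx * tile_shape[0], min((tx + 1) * tile_shape[0], nx))
                sy = slice(ty * tile_shape[1], min((ty + 1) * tile_shape[1], ny))
                tile_index[sx, sy, z] = tid
                sel = brain_mask[sx, sy, z]
                block = residuals[sx, sy, z]
                series = block[sel & np.isfinite(block).all(axis=-1)]
                if series.size == 0:
                    raw_list.append(None)
                elif method == "mean-series":
                    raw_list.append(_acf_of(series.mean(axis=0)))
                else:
                    raw_list.append(_acf_of(series))
                centers.append(((sx.start + sx.stop) / 2,
                                (sy.start + sy.stop) / 2, z))
                tid += 1

    if x_model is not None:
        raw_list = [None if r is None
                    else _residual_acf_debias(r, x_model, taper_m)
                    for r in raw_list]

    centers = np.asarray(centers, dtype=float)
    good = [i for i, r in enumerate(raw_list) if r is not None]
    if not good:
        raise ValueError("no brain voxels in any tile")
    for i, r in enumerate(raw_list):
        if r is None:
            d = np.linalg.norm(centers[good] - centers[i], axis=1)
            donor = good[int(np.argmin(d))]
            logger.info("tile %d empty; inheriting ACF from tile %d", i, donor)
            raw_list[i] = raw_list[donor]
    raw = np.asarray(raw_list)
    return NoiseModel(acf=raw * taper, raw_acf=raw, tile_index=tile_index,
                      taper_m=taper_m, tile_shape=tuple(tile_shape))


def _whitener(acf: np.ndarray, run_lengths) -> callable:
    """Block-diagonal whitening transform from a tapered ACF sequence."""
    chols = []
    for ln in run_lengths:
        v = toeplitz(acf[:ln])
        try:
            ell = cholesky(v, lower=True)
        except np.linalg.LinAlgError:
            w, q = np.linalg.eigh(v)
            n_fix = int((w < EIGENVALUE_FLOOR).sum())
            logger.warning("non-PD noise matrix: flooring %d eigenvalues", n_fix)
            v = (q * np.maximum(w, EIGENVALUE_FLOOR)) @ q.T
            ell = cholesky(v, lower=True)
        chols.append(ell)

    def whiten(arr: np.ndarray) -> np.ndarray:
        out = np.empty_like(arr, dtype=float)
        start = 0
        for ell in chols:
            ln = ell.shape[0]
            out[start:start + ln] = solve_triangular(
                ell, arr[start:start + ln], lower=True)
            start += ln
        return out

    return whiten


def fit_gls(design: DesignMatrix, run: BoldRun, noise: NoiseModel,
            run_lengths=None, dof_loss: int = 0) -> GLMFit:
    """Generalized least squares by tile-wise prewhitening.

    Each voxel inherits its tile's Toeplitz correlation matrix (per-run
    block-diagonal when ``run_lengths`` is given); design and data are
    transformed with the inverse Cholesky factor and fitted by OLS.
    """
    lengths = run_lengths if run_lengths is not None else [run.n_time]
    tile_flat = noise.tile_index.reshape(-1)
    whiten_jobs = []
    for tid in np.unique(tile_flat):
        whiten_jobs.append((tile_flat == tid,
                            _whitener(noise.acf[tid], lengths)))
    fit = _fit_linear(design, run, run_lengths, whiten=whiten_jobs,
                      method="GLS", dof_loss=dof_loss)
    fit.noise = noise
    return fit


def contrast_ttest(fit: GLMFit, finger: int, side: str = "greater"):
    """One-sided t-test on the magnitude coefficient of one finger.

    Returns ``(t, p)`` maps; invalid voxels get ``t = nan, p = 1``.
    """
    t = fit.coef(finger, "magnitude") / fit.coef_stderr(finger, "magnitude")
    if side == "greater":
        p = stats.t.sf(t, fit.dof)
    elif side == "less":
        p = stats.t.cdf(t, fit.dof)
    else:
        raise ValueError("side must be 'greater' or 'less'")
    bad = ~np.isfinite(t)
    p = np.where(bad, 1.0, p)
    return t, p


def fit_deconvolution(fir_design: DesignMatrix, run: BoldRun,
                      run_lengths=None) -> GLMFit:
    """OLS fit of the FIR (deconvolution) design."""
    return _fit_linear(fir_design, run, run_lengths, whiten=None,
                       method="OLS")


def deconvolved_curves(fit: GLMFit, n_lags: int = 13) -> np.ndarray:
    """Reshape FIR betas to (..., 5 fingers, n_lags)."""
    task = fit.beta[..., : 5 * n_lags]
    return task.reshape(task.shape[:-1] + (5, n_lags))
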