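"""Preprocessing chain for PDA chromatograms.

Order of operations in the pipeline: smooth, mask the solvent front, correct
the baseline per wavelength channel with arPLS (asymmetrically reweighted
penalized least squares), then scale areas by the internal standard.

arPLS fits a smooth baseline z to a trace y by iteratively re-solving

    z = argmin  sum_i w_i (y_i - z_i)^2  +  lambda * ||D2 z||^2

where D2 is the second-order difference operator, and updating the weights
from the statistics (mean m, std s) of the negative residuals
d_i = y_i - z_i < 0 via the logistic

    w_i = 1 / (1 + exp(2 (d_i - (2 s - m)) / s)).

Points far above the baseline (peaks) get weight ~0, drift gets weight ~1,
so the baseline follows gradient-induced drift while ignoring analyte peaks.
The linear system is symmetric pentadiagonal and solved in banded form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import savgol_filter

from .chromdata import PDAChromatogram
from .errors import InternalStandardError, ParameterError, ValidationError

__all__ = [
    "BaselineResult",
    "InternalStandardScale",
    "smooth",
    "arpls_baseline",
    "correct_baseline",
    "mask_solvent_front",
    "internal_standard_scale",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineResult:
    """Fitted baseline, final arPLS weights, and convergence diagnostics."""

    baseline: np.ndarray
    weights: np.ndarray
    iterations: int
    converged: bool

    def __post_init__(self):
        if self.baseline.shape != self.weights.shape:
            raise ValidationError("baseline and weights must have equal length")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValidationError("arPLS weights must lie in [0, 1]")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


@dataclass(frozen=True)
class InternalStandardScale:
    """Internal-standard area normalization factor (nominal / measured)."""

    measured_area: float
    nominal_area: float
    factor: float
    out_of_range: bool = False


def smooth(pda: PDAChromatogram, window: int = 7, polyorder: int = 3
           ) -> PDAChromatogram:
    """Savitzky-Golay smoothing along the time axis, per wavelength channel.

    Local polynomial least squares preserves polynomial signals up to
    ``polyorder`` exactly, so peak areas are nearly conserved for peaks wider
    than the window.
    """
    n = pda.times.size
    if window % 2 == 0:
        raise ParameterError("smoothing window must be odd")
    if window <= polyorder:
        raise ParameterError("smoothing window must exceed the polynomial order")
    if window >= n:
        raise ParameterError(
            f"smoothing window {window} must be smaller than the trace ({n} points)")
    smoothed = savgol_filter(pda.absorbance, window, polyorder, axis=0)
    return pda.replace(absorbance=smoothed)


def _second_difference_bands(n: int) -> np.ndarray:
    """Upper banded form (3 x n) of D2^T D2 for solveh_banded."""
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n - 1, -4.0)
    off1[[0, -1]] = -2.0
    off2 = np.full(n - 2, 1.0)
    ab = np.zeros((3, n))
    ab[0, 2:] = off2
    ab[1, 1:] = off1
    ab[2, :] = main
    return ab


@njit(cache=True)
def _solve_penta_batch(d, e, f, b):  # pragma: no cover - exercised via wrappers
    """Solve K symmetric pentadiagonal SPD systems sharing off-diagonals.

    ``d`` (n, K) holds each system's main diagonal; ``e`` (n-1,) and ``f``
    (n-2,) the shared first/second sub-diagonals; ``b`` (n, K) the right-hand
    sides. LDL^T factorization, sequential over rows, vectorized over the K
    systems (the arPLS weight vector differs per channel but the smoothness
    penalty does not).
    """
    n, K = d.shape
    c = np.empty((n, K))       # D of LDL^T
    alpha = np.zeros((n, K))   # L[i, i-1]
    beta = np.zeros((n, K))    # L[i, i-2]
    c[0] = d[0]
    alpha[1] = e[0] / c[0]
    c[1] = d[1] - alpha[1] ** 2 * c[0]
    for i in range(2, n):
        beta[i] = f[i - 2] / c[i - 2]
        alpha[i] = (e[i - 1] - beta[i] * alpha[i - 1] * c[i - 2]) / c[i - 1]
        c[i] = d[i] - beta[i] ** 2 * c[i - 2] - alpha[i] ** 2 * c[i - 1]
    z = np.empty((n, K))
    z[0] = b[0]
    z[1] = b[1] - alpha[1] * z[0]
    for i in range(2, n):
        z[i] = b[i] - alpha[i] * z[i - 1] - beta[i] * z[i - 2]
    x = z / c
    x[n - 2] -= alpha[n - 1] * x[n - 1]
    for i in range(n - 3, -1, -1):
        x[i] -= alpha[i + 1] * x[i + 1] + beta[i + 2] * x[i + 2]
    return x


@njit(cache=True)
def _arpls_batch_core(Y, main, off1, off2, sigma_floor, neg_floor, ratio,
                      max_iter):  # pragma: no cover - exercised via wrappers
    n, K = Y.shape
    W = np.ones((n, K))
    Z_out = Y.copy()
    W_out = np.ones((n, K))
    done = np.zeros(K, dtype=np.bool_)
    iterations = np.ones(K, dtype=np.int64)
    for it in range(1, max_iter + 1):
        # compact the still-active channels so converged ones cost nothing
        idx = np.where(~done)[0]
        ka = idx.size
        if ka == 0:
            break
        d_sys = np.empty((n, ka))
        B = np.empty((n, ka))
        for i in range(n):
            for j in range(ka):
                k = idx[j]
                d_sys[i, j] = main[i] + W[i, k]
                B[i, j] = W[i, k] * Y[i, k]
        Za = _solve_penta_batch(d_sys, off1, off2, B)
        Z = np.empty((n, K))
        for i in range(n):
            for j in range(ka):
                Z[i, idx[j]] = Za[i, j]
        for k in idx:
            iterations[k] = it
            # negative-residual statistics for this channel
            cnt = 0
            mean = 0.0
            for i in range(n):
                d = Y[i, k] - Z[i, k]
                if d < -neg_floor[k]:
                    cnt += 1
                    mean += d
            if cnt == 0:
                # baseline at/below the data everywhere: converged
                for i in range(n):
                    Z_out[i, k] = Z[i, k]
                done[k] = True
                continue
            mean /= cnt
            var = 0.0
            for i in range(n):
                d = Y[i, k] - Z[i, k]
                if d < -neg_floor[k]:
                    var += (d - mean) ** 2
            s = max(np.sqrt(var / cnt), sigma_floor[k])
            change2 = 0.0
            norm2 = 0.0
            for i in range(n):
                d = Y[i, k] - Z[i, k]
                expo = 2.0 * (d - (2.0 * s - mean)) / s
                if expo > 500.0:
                    expo = 500.0
                elif expo < -500.0:
                    expo = -500.0
                w_new = 1.0 / (1.0 + np.exp(expo))
                change2 += (w_new - W[i, k]) ** 2
                norm2 += W[i, k] ** 2
                W_out[i, k] = w_new
                Z_out[i, k] = Z[i, k]
            W[:, k] = W_out[:, k]
            if norm2 > 0.0 and np.sqrt(change2 / norm2) < ratio:
                done[k] = True
        if done.all():
            break
    return Z_out, W_out, iterations, done


def _arpls_batch(Y: np.ndarray, lambda_s: float, ratio: float, max_iter: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """arPLS on every column of Y (n x K) simultaneously.

    Returns (baselines, weights, iterations, converged), each per channel.
    """
    n, K = Y.shape
    scale = np.maximum(np.max(np.abs(Y), axis=0), 1.0)
    sigma_floor = 10 * np.finfo(float).eps * scale
    bands = _second_difference_bands(n)
    neg_floor = 1e-9 * scale
    Z, W, iterations, done = _arpls_batch_core(
        np.ascontiguousarray(Y, dtype=float), lambda_s * bands[2],
        lambda_s * bands[1, 1:], lambda_s * bands[0, 2:],
        sigma_floor, neg_floor, ratio, max_iter)
    return Z, np.clip(W, 0.0, 1.0), iterations, done


def arpls_baseline(y, lambda_s: float = 1e4, ratio: float = 1e-6,
                   max_iter: int = 100) -> BaselineResult:
    """Estimate a drift baseline under a peaked trace by arPLS.

    Parameters
    ----------
    y : array
        Intensity trace (AU), length >= 5.
    lambda_s : float
        Smoothness penalty on the second difference of the baseline. Larger
        values give stiffer baselines; the 1e4 default tracks gradient-shaped
        drift, including its corners at the program breakpoints, at ~1 Hz
        sampling while staying stiff over peak widths of a few seconds.
    ratio : float
        Convergence threshold on the relative change of the weight vector.
    max_iter : int
        Iteration cap.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 5:
        raise ValidationError("y must be a 1-D trace with at least 5 points")
    if not np.all(np.isfinite(y)):
        raise ValidationError("y contains non-finite values")
    if not lambda_s > 0:
        raise ParameterError("lambda_s must be positive")
    if not 0 < ratio < 1:
        raise ParameterError("ratio must lie in (0, 1)")

    Z, W, iterations, done = _arpls_batch(y[:, None], lambda_s, ratio,
                                          max_iter)
    return BaselineResult(baseline=Z[:, 0], weights=W[:, 0],
                          iterations=int(iterations[0]),
                          converged=bool(done[0]))


def correct_baseline(pda: PDAChromatogram, lambda_s: float = 1e4,
                     ratio: float = 1e-6, max_iter: int = 100,
                     channels=None,
                     estimate_on: PDAChromatogram | None = None
                     ) -> PDAChromatogram:
    """Subtract an arPLS baseline from every (or each selected) channel.

    All channels share the smoothness penalty, so they are fitted
    simultaneously through the batched pentadiagonal solver.

    ``estimate_on`` lets the baseline be estimated on a different rendering
    of the same chromatogram than it is subtracted from — in the pipeline the
    baseline is estimated on the unsmoothed data and subtracted from the
    smoothed data. arPLS's asymmetric reweighting assumes serially
    uncorrelated noise; local-polynomial smoothing correlates it, which
    pushes the fitted baseline several noise-sigmas below the true drift and
    systematically inflates every downstream peak area.
    """
    src = estimate_on if estimate_on is not None else pda
    if src.absorbance.shape != pda.absorbance.shape:
        raise ValidationError("estimate_on must share the pda's shape")
    a = pda.absorbance.copy()
    if channels is None:
        Z, _, iters, _ = _arpls_batch(src.absorbance, lambda_s, ratio,
                                      max_iter)
        a = a - Z
    else:
        idx = list(channels)
        Z, _, iters, _ = _arpls_batch(src.absorbance[:, idx], lambda_s,
                                      ratio, max_iter)
        a[:, idx] = a[:, idx] - Z
    logger.debug("arPLS corrected %d channels, median iterations %.0f",
                 Z.shape[1], float(np.median(iters)))
    return pda.replace(absorbance=a)


def mask_solvent_front(pda: PDAChromatogram, t_dead: float) -> PDAChromatogram:
    """Mark ``t < t_dead`` as dead volume, excluded from peak search/integration."""
    if not 0 <= t_dead < pda.times[-1]:
        raise ParameterError(
            f"t_dead={t_dead} must lie in [0, run length {pda.times[-1]} s)")
    return pda.replace(t_dead=float(t_dead))


def internal_standard_scale(pda: PDAChromatogram, ist_window, ist_lambda: float,
                            nominal_area: float, clip=(0.5, 2.0),
                            warn=(0.8, 1.25)) -> InternalStandardScale:
    """Measure the internal-standard peak area and form the scale factor.

    Integrates the baseline-corrected channel nearest ``ist_lambda`` over
    ``ist_window`` (trapezoid rule). The factor nominal/measured multiplies
    all subsequently reported areas, correcting joint injection/dilution
    variability. Factors outside ``warn`` are flagged; outside ``clip`` they
    are clipped (gross liquid-handling failure, not a correctable drift).
    """
    t0, t1 = float(ist_window[0]), float(ist_window[1])
    sl = pda.window_slice(t0, t1)
    seg = pda.channel(ist_lambda)[sl]
    if seg.size < 2:
        raise InternalStandardError(
            f"internal-standard window [{t0}, {t1}] s holds <2 samples")
    measured = float(np.trapezoid(seg, pda.times[sl]))
    noise_floor = 1e-3 * nominal_area
    if measured <= noise_floor:
        raise InternalStandardError(
            f"internal standard not found: measured area {measured:.3g} AU*s "
            f"<= detection floor {noise_floor:.3g} AU*s in [{t0}, {t1}] s")
    factor = nominal_area / measured
    out = not (warn[0] <= factor <= warn[1])
    if out:
        logger.warning("internal-standard factor %.3f outside [%.2f, %.2f]",
                       factor, *warn)
    clipped = min(max(factor, clip[0]), clip[1])
    if clipped != factor:
        logger.warning("internal-standard factor %.3f clipped to %.3f",
                       factor, clipped)
    return InternalStandardScale(measured_area=measured,
                                 nominal_area=nominal_area,
                                 factor=clipped, out_of_range=out)
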