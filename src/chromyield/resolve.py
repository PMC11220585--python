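"""Multivariate curve resolution of the MS-located PDA window.

The window absorbance matrix ``A_w`` (I_w time points x J wavelengths) is
factored as ``A_w = C S^T + E`` with non-negative elution profiles C and
non-negative spectra S (columns normalized to unit maximum; magnitudes live
in C). Alternating non-negative least squares from a purest-variable
(SIMPLISMA-style) initialization is run for N = 1, 2, 3 components in turn;
the first N whose lack of fit — the time integral of the wavelength-RMS
residual, in AU*s — falls below the acceptance threshold (default 0.2 AU*s)
is kept. If even N = 3 fails, the window is flagged overloaded and the
caller decides whether to withhold the sample.

The target component is the one whose elution apex is nearest the MS
retention time, and it is integrated at the reddest absorption maximum of
its resolved spectrum, where overlap with UV-absorbing impurities and
solvents is least likely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import AssignmentAmbiguousError, ValidationError

__all__ = ["ResolvedComponents", "TargetPeak", "mcr_als", "lack_of_fit",
           "resolve_window", "assign_target", "reddest_peak",
           "integrate_target"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResolvedComponents:
    """MCR outputs: C (I_w x N), S (J x N), residual E, and diagnostics."""

    C: np.ndarray
    S: np.ndarray
    residual: np.ndarray
    lack_of_fit: float
    n_components: int
    converged: bool
    iterations: int = 0
    flagged_overloaded: bool = False

    def __post_init__(self):
        if np.any(self.C < 0) or np.any(self.S < 0):
            raise ValidationError("C and S must be elementwise non-negative")
        if self.lack_of_fit < 0:
            raise ValidationError("lack_of_fit must be non-negative")


@dataclass(frozen=True)
class TargetPeak:
    """Integrated, internal-standard-corrected target peak."""

    component_index: int
    lambda_red: float
    area: float
    area_uncertainty: float
    apex_time: float

    def __post_init__(self):
        if self.area < 0:
            raise ValidationError("area must be non-negative")


def _nnls_small(G: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for few (<= ~4) unknowns, vectorized.

    Solves min ||G x - b||, x >= 0 for every column b of B by enumerating
    active sets (all subsets of variables allowed nonzero), which is exact
    for small N. Returns X of shape (N, K).
    """
    m, n = G.shape
    k = B.shape[1]
    best_obj = np.full(k, np.inf)
    X = np.zeros((n, k))
    norm_b2 = np.einsum("ik,ik->k", B, B)
    # all-zero solution is the baseline candidate
    best_obj[:] = norm_b2
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            Gs = G[:, subset]
            sol, *_ = np.linalg.lstsq(Gs, B, rcond=None)
            feasible = np.all(sol >= -1e-12, axis=0)
            if not np.any(feasible):
                continue
            resid = B - Gs @ sol
            obj = np.einsum("ik,ik->k", resid, resid)
            # tie tolerance relative to each column's own energy, so tiny
            # peak-tail columns are still fitted rather than zeroed
            better = feasible & (obj < best_obj - 1e-12 * norm_b2)
            if np.any(better):
                best_obj[better] = obj[better]
                X[:, better] = 0.0
                X[np.ix_(list(subset), np.where(better)[0])] = \
                    np.clip(sol[:, better], 0.0, None)
    return X


def _purest_rows(A: np.ndarray, n: int) -> list[int]:
    """Indices of the n most mutually dissimilar (purest) time rows of A.

    Maximum-angle selection: start from the strongest row, then repeatedly
    take the row with the largest residual after projection onto the span of
    the rows already chosen. Deterministic given the data.
    """
    norms = np.linalg.norm(A, axis=1)
    chosen = [int(np.argmax(norms))]
    basis = []
    v = A[chosen[0]]
    nv = np.linalg.norm(v)
    if nv > 0:
        basis.append(v / nv)
    for _ in range(1, n):
        R = A.copy()
        for b in basis:
            R -= np.outer(R @ b, b)
        resid = np.linalg.norm(R, axis=1)
        resid[chosen] = -1.0
        j = int(np.argmax(resid))
        chosen.append(j)
        v = R[j]
        nv = np.linalg.norm(v)
        if nv > 0:
            basis.append(v / nv)
    return chosen


def mcr_als(A_w: np.ndarray, n: int, tol: float = 1e-8, max_iter: int = 500,
            seed: int = 0, dt: float = 1.0) -> ResolvedComponents:
    """Alternating non-negative least squares factorization of one window.

    Parameters
    ----------
    A_w : 2-D array
        Window absorbance, time rows x wavelength columns.
    n : int
        Number of components to fit.
    tol : float
        Stop when the relative change of the Frobenius residual drops below
        this.
    max_iter : int
        Iteration cap.
    seed : int
        Reserved for degenerate tie-breaks; the purest-variable
        initialization itself is deterministic.
    dt : float
        Sampling interval (s), used for the lack-of-fit metric.
    """
    A_w = np.asarray(A_w, dtype=float)
    if A_w.ndim != 2:
        raise ValidationError("window must be a 2-D matrix")
    if not np.all(np.isfinite(A_w)):
        raise ValidationError("window contains non-finite values")
    I_w, J = A_w.shape
    if n < 1:
        raise ValidationError("component count must be >= 1")
    if I_w < n or J < n:
        raise ValidationError(
            f"window {A_w.shape} too small for {n} components")

    if not np.any(A_w > 0):
        # degenerate all-zero window: a single zero component, perfect fit
        return ResolvedComponents(
            C=np.zeros((I_w, 1)), S=np.zeros((J, 1)),
            residual=np.zeros_like(A_w), lack_of_fit=0.0,
            n_components=1, converged=True, iterations=0)

    rows = _purest_rows(A_w, n)
    S = np.clip(A_w[rows].T, 0.0, None)  # J x n
    maxes = S.max(axis=0)
    rng = np.random.default_rng(seed)
    for k in range(n):
        if maxes[k] <= 0:  # degenerate tie-break: seed a random spectrum
            S[:, k] = rng.random(J)
            maxes[k] = S[:, k].max()
    S = S / S.max(axis=0)

    prev_resid = np.inf
    converged = False
    it = 0
    C = np.zeros((I_w, n))
    C_prev = S_prev = None
    beta = 1.0  # extrapolation length; ALS alone converges linearly and
    # slowly near a zero-residual solution, so accepted extrapolations along
    # the iterate difference are used to accelerate the tail
    for it in range(1, max_iter + 1):
        C = _nnls_small(S, A_w.T).T          # I_w x n
        S = _nnls_small(C, A_w)              # n x J -> transpose below
        S = S.T
        # push magnitude into C, keep S unit-maximum
        maxes = S.max(axis=0)
        for k in range(n):
            if maxes[k] <= 0:
                S[:, k] = rng.random(J)
                S[:, k] /= S[:, k].max()
            else:
                S[:, k] /= maxes[k]
                C[:, k] *= maxes[k]
        resid = float(np.linalg.norm(A_w - C @ S.T))
        if C_prev is not None:
            C_x = np.clip(C + beta * (C - C_prev), 0.0, None)
            S_x = np.clip(S + beta * (S - S_prev), 0.0, None)
            maxes = S_x.max(axis=0)
            if np.all(maxes > 0):
                S_x = S_x / maxes
                C_x = C_x * maxes
                resid_x = float(np.linalg.norm(A_w - C_x @ S_x.T))
                if resid_x < resid:
                    C, S, resid = C_x, S_x, resid_x
                    beta = min(beta * 2.0, 256.0)
                else:
                    beta = max(beta / 4.0, 1.0)
        C_prev, S_prev = C, S
        if prev_resid < np.inf:
            denom = max(prev_resid, 1e-300)
            if abs(prev_resid - resid) / denom < tol:
                converged = True
                prev_resid = resid
                break
        prev_resid = resid
    E = A_w - C @ S.T
    return ResolvedComponents(C=C, S=S, residual=E,
                              lack_of_fit=lack_of_fit(E, dt),
                              n_components=n, converged=converged,
                              iterations=it)


def lack_of_fit(E: np.ndarray, dt: float) -> float:
    """Time-integrated wavelength-RMS residual, in AU*s.

    ``dt * sum_t sqrt(mean_lambda E(t, .)^2)`` — has the units of a peak
    area and is insensitive to the number of wavelength channels.
    """
    E = np.asarray(E, dtype=float)
    if not np.all(np.isfinite(E)):
        raise ValidationError("residual contains non-finite values")
    return float(dt * np.sum(np.sqrt(np.mean(E * E, axis=1))))


def resolve_window(A_w: np.ndarray, dt: float, threshold: float = 0.2,
                   max_n: int = 3, tol: float = 1e-8, max_iter: int = 500,
                   seed: int = 0) -> ResolvedComponents:
    """Fit 1, 2, ... components until the lack of fit clears the threshold.

    Returns the first acceptable factorization; if ``max_n`` components still
    leave a lack of fit above ``threshold`` the result is flagged overloaded
    (more species co-elute than the method can resolve — the sample should be
    withheld or rerun with a longer gradient).
    """
    best = None
    for n in range(1, max_n + 1):
        rc = mcr_als(A_w, n, tol=tol, max_iter=max_iter, seed=seed, dt=dt)
        logger.debug("MCR n=%d: lack_of_fit=%.4g AU*s (threshold %.3g)",
                     n, rc.lack_of_fit, threshold)
        if rc.lack_of_fit < threshold:
            return rc
        best = rc
    return ResolvedComponents(
        C=best.C, S=best.S, residual=best.residual,
        lack_of_fit=best.lack_of_fit, n_components=best.n_components,
        converged=best.converged, iterations=best.iterations,
        flagged_overloaded=True)


def assign_target(rc: ResolvedComponents, ms_apex_pda_frame: float,
                  window_times, max_distance: float | None = None) -> int:
    """Pick the component whose elution apex is nearest the MS retention time.

    Ties (apexes equidistant within one sample) go to the more intense
    component and are logged. An apex farther than ``max_distance`` (defaults
    to half the window span) raises an ambiguity error rather than guessing.
    """
    window_times = np.asarray(window_times, dtype=float)
    if rc.C.shape[0] != window_times.size:
        raise ValidationError("window_times length must match C rows")
    apex_idx = np.argmax(rc.C, axis=0)
    apex_times = window_times[apex_idx]
    apex_heights = rc.C[apex_idx, np.arange(rc.n_components)]
    dist = np.abs(apex_times - ms_apex_pda_frame)
    if max_distance is None:
        max_distance = 0.5 * (window_times[-1] - window_times[0])
    dt = window_times[1] - window_times[0] if window_times.size > 1 else 0.0
    order = np.lexsort((-apex_heights, dist))
    best = int(order[0])
    if rc.n_components > 1:
        second = int(order[1])
        if abs(dist[best] - dist[second]) <= dt:
            logger.info("target assignment tie between components %d and %d "
                        "broken by apex intensity", best, second)
    if dist[best] > max_distance:
        raise AssignmentAmbiguousError(
            f"nearest component apex at {apex_times[best]:.1f} s is "
            f"{dist[best]:.1f} s from the MS apex "
            f"{ms_apex_pda_frame:.1f} s (limit {max_distance:.1f} s)")
    return best


def reddest_peak(spectrum, wavelengths, prominence: float = 0.05,
                 lambda_floor: float = 220.0,
                 min_height: float = 0.1) -> float:
    """Longest-wavelength qualifying absorption maximum of a spectrum.

    A qualifying maximum is a local maximum with prominence at least
    ``prominence`` of the global maximum and height at least ``min_height``
    of it, at wavelengths >= ``lambda_floor`` (below ~220 nm acetonitrile and
    DMSO absorb). Real absorption bands are tens of nm wide, so the spectrum
    is lightly smoothed along wavelength first; together with the height
    floor this keeps single-channel noise bumps in the red tail of a weak
    resolved spectrum from being mistaken for a band. Falls back to the
    global maximum over the admissible range when no local maximum qualifies.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if spectrum.max() <= 0:
        raise ValidationError("spectrum has no positive maximum")
    admissible = wavelengths >= lambda_floor
    if not np.any(admissible):
        raise ValidationError("no wavelengths above the search floor")
    s = spectrum[admissible]
    wl = wavelengths[admissible]
    if s.size >= 9:
        from scipy.signal import savgol_filter

        s = savgol_filter(s, 9, 2)
    idx, _ = find_peaks(s, prominence=prominence * s.max(),
                        height=min_height * s.max())
    if idx.size:
        return float(wl[idx[-1]])
    return float(wl[int(np.argmax(s))])


def integrate_target(rc: ResolvedComponents, component_index: int,
                     lambda_red: float, wavelengths, window_times,
                     dt: float, ist_factor: float = 1.0) -> TargetPeak:
    """Integrate the resolved target at its reddest absorption maximum.

    area = ist_factor * dt * sum_t C(t, k) * S(lambda_red, k); the
    uncertainty is the lack of fit restricted to the component's support
    (times where its profile exceeds 5% of apex) — the contribution of
    unresolved residual to the reported area.
    """
    k = component_index
    if not 0 <= k < rc.n_components:
        raise ValidationError(f"component index {k} out of range")
    wavelengths = np.asarray(wavelengths, dtype=float)
    j = int(np.argmin(np.abs(wavelengths - lambda_red)))
    c = rc.C[:, k]
    s_red = float(rc.S[j, k])
    area = float(ist_factor * dt * np.sum(c) * s_red)
    apex = float(np.max(c))
    support = c >= 0.05 * apex if apex > 0 else np.zeros_like(c, dtype=bool)
    lof_support = lack_of_fit(rc.residual[support], dt) if np.any(support) else 0.0
    window_times = np.asarray(window_times, dtype=float)
    apex_time = float(window_times[int(np.argmax(c))])
    return TargetPeak(component_index=k, lambda_red=float(lambda_red),
                      area=area, area_uncertainty=float(ist_factor * lof_support),
                      apex_time=apex_time)
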