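"""Locating the product peak in the extracted-ion (MS) traces.

The expected product's m/z is formed from its monoisotopic mass and an adduct
rule (e.g. [M+H]+ at exact mass + 1.00728 Da). The most intense MS peak at
that m/z fixes the retention time; the PDA->MS transit delay is estimated by
cross-correlating the total-absorbance trace with the summed MS intensity,
and the peak window is mapped back into the PDA time frame for resolution.

MS intensity is used only to rank candidate peaks within a trace, never to
quantify: electrospray ionizability and UV absorption are uncorrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .chromdata import AnalyteSpec, MSTrace, PDAChromatogram, SystemConstants
from .config import MSConfig
from .errors import (
    ConfigurationError,
    ProductNotDetectedError,
    TargetInDeadVolumeError,
    ValidationError,
)

__all__ = ["AdductRule", "MSPeak", "ADDUCTS", "target_mz", "find_ms_peak",
           "estimate_delay", "locate_target"]

logger = logging.getLogger(__name__)

PROTON_MASS = 1.00728  # Da


@dataclass(frozen=True)
class AdductRule:
    """Mass shift and polarity of an MS adduct channel."""

    label: str
    mass_shift: float
    polarity: str = "positive"


#: Common singly charged adducts of drug-like molecules.
ADDUCTS = {
    "M+H": AdductRule("M+H", +PROTON_MASS, "positive"),
    "M+Na": AdductRule("M+Na", +22.98922, "positive"),
    "M+NH4": AdductRule("M+NH4", +18.03383, "positive"),
    "M-H": AdductRule("M-H", -PROTON_MASS, "negative"),
}


@dataclass(frozen=True)
class MSPeak:
    """A detected extracted-ion peak (times in the frame noted by the caller)."""

    apex_time: float
    window: tuple
    apex_intensity: float
    snr: float
    mz: float
    adduct: str = ""

    def __post_init__(self):
        t0, t1 = self.window
        if not (t0 < self.apex_time < t1):
            raise ValidationError(
                f"apex {self.apex_time} must lie inside window ({t0}, {t1})")


def target_mz(analyte: AnalyteSpec, adduct: AdductRule) -> float:
    """m/z of the analyte under the adduct rule (singly charged)."""
    return analyte.exact_mass + adduct.mass_shift


def find_ms_peak(trace: MSTrace, min_snr: float = 10.0) -> list[MSPeak]:
    """Detect peaks in one extracted-ion trace, most intense first.

    The noise floor is the scaled median absolute deviation (1.4826 * MAD) of
    the whole trace — robust against the peaks themselves. A peak's window is
    the contiguous region above 5% of its apex, extended outward to the
    nearest local minima.
    """
    t = trace.times
    # detect on the offset-free intensity so a constant spray background
    # does not count toward peak height
    y = trace.intensity - float(np.median(trace.intensity))
    mad = float(np.median(np.abs(y - np.median(y))))
    noise = 1.4826 * mad
    if noise <= 0:
        # noiseless trace: any structure is signal
        noise = max(1e-9 * float(np.max(y)), 1e-12)
    idx, _ = find_peaks(y, height=min_snr * noise)
    if idx.size == 0:
        raise ProductNotDetectedError([trace.mz])
    peaks = []
    for i in idx:
        apex = float(y[i])
        lo = i
        while lo > 0 and y[lo - 1] >= 0.05 * apex and y[lo - 1] <= y[lo]:
            lo -= 1
        hi = i
        while hi < y.size - 1 and y[hi + 1] >= 0.05 * apex and y[hi + 1] <= y[hi]:
            hi += 1
        # extend at least one sample so the apex is strictly interior
        lo = max(lo - 1, 0) if lo == i else lo
        hi = min(hi + 1, y.size - 1) if hi == i else hi
        peaks.append(MSPeak(apex_time=float(t[i]),
                            window=(float(t[lo]), float(t[hi])),
                            apex_intensity=apex,
                            snr=apex / noise,
                            mz=trace.mz))
    peaks.sort(key=lambda p: -p.apex_intensity)
    return peaks


def _support_corr(a: np.ndarray, b: np.ndarray, frac: float = 0.05,
                  min_points: int = 5) -> float | None:
    """Pearson correlation restricted to the joint peak support of a and b.

    Only samples where both aligned signals exceed ``frac`` of their maxima
    enter the correlation: detector-specific features (a UV-silent or
    non-ionizing species seen by only one detector) would otherwise dilute
    the statistic toward zero. Symmetric in (a, b), so delay estimation is
    antisymmetric under swapping the detectors. Returns None when the
    overlap is too small to be meaningful.
    """
    if a.max() <= 0 or b.max() <= 0:
        return None
    sup_a = a > frac * a.max()
    sup_b = b > frac * b.max()
    mask = sup_a & sup_b
    # the joint support must cover most of the smaller signal's support,
    # otherwise a single accidental peak pairing can win over the true
    # alignment of every peak
    required = max(min_points,
                   int(0.5 * min(int(sup_a.sum()), int(sup_b.sum()))))
    if int(mask.sum()) < required:
        return None
    aa = a[mask] - a[mask].mean()
    bb = b[mask] - b[mask].mean()
    na, nb = np.linalg.norm(aa), np.linalg.norm(bb)
    if na <= 0 or nb <= 0:
        return None
    return float(np.dot(aa, bb) / (na * nb))


def estimate_delay(pda: PDAChromatogram, ms_traces, max_lag: float = 30.0,
                   min_corr: float = 0.3,
                   fallback: float | None = None) -> float:
    """PDA->MS transit delay (s), as MS_time - PDA_time.

    Maximizes the cross-correlation between the total-absorbance trace (sum
    over wavelengths) and the summed MS intensity, interpolated to the PDA
    grid, over integer lags within ``max_lag``; at each lag the correlation
    is evaluated only over the joint peak support of the two aligned signals
    (see :func:`_support_corr`). If the best correlation is below
    ``min_corr`` the configured ``fallback`` delay is returned (a
    :class:`ConfigurationError` is raised if there is none).
    """
    pda_sig = pda.absorbance.sum(axis=1)
    ms_sig = np.zeros_like(pda_sig)
    for tr in ms_traces:
        ms_sig += np.interp(pda.times, tr.times, tr.intensity,
                            left=0.0, right=0.0)
    # remove residual offsets so peak supports are defined against zero
    pda_sig = np.clip(pda_sig - np.median(pda_sig), 0.0, None)
    ms_sig = np.clip(ms_sig - np.median(ms_sig), 0.0, None)
    dt = pda.dt
    max_shift = max(int(round(max_lag / dt)), 1)

    best_corr, best_lag = -np.inf, 0
    n = pda_sig.size
    for lag in range(-max_shift, max_shift + 1):
        if lag >= 0:
            a, b = pda_sig[: n - lag], ms_sig[lag:]
        else:
            a, b = pda_sig[-lag:], ms_sig[: n + lag]
        if a.size < 8:
            continue
        c = _support_corr(a, b)
        if c is not None and c > best_corr:
            best_corr, best_lag = c, lag
    if best_corr < min_corr:
        if fallback is not None:
            logger.warning(
                "delay cross-correlation %.2f below %.2f; using configured "
                "delay %.2f s", best_corr, min_corr, fallback)
            return float(fallback)
        raise ConfigurationError(
            f"delay estimation failed (best correlation {best_corr:.2f}) and "
            "no pda_ms_delay configured")
    return best_lag * dt


def locate_target(pda: PDAChromatogram, ms_traces, analyte: AnalyteSpec,
                  constants: SystemConstants,
                  ms_config: MSConfig = MSConfig()) -> MSPeak:
    """Find the product peak across the analyte's adducts, in the PDA frame.

    The most intense detected peak over all adduct channels wins; the delay
    is subtracted to map its apex/window into the PDA frame, and the window
    is widened by ``window_pad`` on each side for curve resolution.
    """
    searched = []
    candidates = []
    for label in analyte.adducts:
        rule = ADDUCTS.get(label)
        if rule is None:
            raise ConfigurationError(f"unknown adduct rule {label!r}")
        mz = target_mz(analyte, rule)
        searched.append(mz)
        matches = [tr for tr in ms_traces
                   if abs(tr.mz - mz) <= ms_config.mz_tol]
        for tr in matches:
            try:
                for p in find_ms_peak(tr, min_snr=ms_config.min_snr):
                    candidates.append(replace(p, adduct=label))
            except ProductNotDetectedError:
                continue
    if not candidates:
        raise ProductNotDetectedError(searched)
    best = max(candidates, key=lambda p: p.apex_intensity)
    if constants.pda_ms_delay is not None:
        # the transit delay is a plumbing property, calibrated once per
        # platform; a configured value beats re-estimating it from data in
        # which the target may be UV-weak
        delay = float(constants.pda_ms_delay)
    else:
        delay = estimate_delay(pda, ms_traces, max_lag=ms_config.max_lag,
                               min_corr=ms_config.min_corr, fallback=None)
    pad = ms_config.window_pad
    t0 = best.window[0] - delay - pad
    t1 = best.window[1] - delay + pad
    apex = best.apex_time - delay
    if apex < pda.t_dead:
        raise TargetInDeadVolumeError(
            f"target apex {apex:.1f} s lies inside the solvent-front mask "
            f"(t_dead={pda.t_dead} s)")
    t0 = max(t0, pda.t_dead, float(pda.times[0]))
    t1 = min(t1, float(pda.times[-1]))
    logger.info("target located: m/z %.4f (%s) apex %.1f s (PDA frame), "
                "window [%.1f, %.1f] s, SNR %.0f",
                best.mz, best.adduct, apex, t0, t1, best.snr)
    return replace(best, apex_time=apex, window=(t0, t1))
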