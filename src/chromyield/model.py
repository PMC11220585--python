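"""End-to-end yield estimation as a Model/Results pair.

:class:`ReactionYieldModel` holds one chromatogram pair, the expected product
and the run configuration; :meth:`~ReactionYieldModel.fit` executes the full
chain — smooth, mask the solvent front, arPLS baseline, internal-standard
scaling, MS target location, MCR window resolution, target assignment,
integration at the reddest absorption maximum, gradient-composition-weighted
extinction coefficient, Beer-Lambert moles, yield, uncertainty propagation
and the dynamic-range check — and returns a :class:`YieldResult` carrying
the estimate, its uncertainty, all stage diagnostics, and a ``summary()``
table. :func:`run_campaign` maps the model over a simulated (or converted)
campaign and scores it against a truth table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .chromdata import AnalyteSpec, PDAChromatogram, load_ms, load_pda
from .config import RunConfig
from .errors import ChromYieldError
from .mslocate import locate_target
from .preprocess import (
    correct_baseline,
    internal_standard_scale,
    mask_solvent_front,
    smooth,
)
from .quantify import (
    epsilon_at_elution,
    gradient_fraction,
    make_predictor,
    moles_from_area,
    propagate_uncertainty,
    signal_check,
    yield_from_moles,
)
from .resolve import (
    assign_target,
    integrate_target,
    reddest_peak,
    resolve_window,
)

__all__ = ["ReactionYieldModel", "YieldResult", "PipelineStageError",
           "estimate_yield", "run_campaign"]

logger = logging.getLogger(__name__)

_STAGE_HINTS = {
    "locate_target": "check the adduct list and MS channel m/z values",
    "internal_standard_scale": "check the internal-standard window/wavelength",
    "resolve_window": "window may hold more species than resolvable",
    "load": "check the file dialect and axes headers",
}


class PipelineStageError(ChromYieldError):
    """Wraps a stage failure with the stage name and a remediation hint."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        hint = _STAGE_HINTS.get(stage, "")
        msg = f"stage {stage!r} failed: {original}"
        if hint:
            msg += f" — {hint}"
        super().__init__(msg)


@dataclass(frozen=True)
class YieldResult:
    """Fit output: the yield estimate with uncertainties and diagnostics.

    ``yield_fraction`` is None when the window was flagged overloaded (more
    than three co-eluting components): such samples are withheld rather than
    reported with an untrustworthy number.
    """

    yield_fraction: float | None
    rel_uncertainty: float | None
    moles_injected: float | None
    sample_conc: float | None
    flags: frozenset
    target_area: float | None
    area_uncertainty: float | None
    lambda_red: float | None
    apex_time: float | None
    epsilon_used: float | None
    epsilon_rel_std: float | None
    phi_acn: float | None
    n_components: int | None
    lack_of_fit: float | None
    ist_factor: float | None
    ms_mz: float | None
    ms_adduct: str | None
    signal_status: str | None
    suggested_injection_factor: float | None
    config_digest: str
    version: str
    timings: dict = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        lines = ["Calibration-free HPLC yield estimate",
                 "=" * 44]

        def row(k, v):
            lines.append(f"{k:<30}{v}")

        if self.yield_fraction is None:
            row("yield", "withheld (window overloaded)")
        else:
            row("yield", f"{self.yield_fraction:.3f} "
                         f"(+- {self.rel_uncertainty * self.yield_fraction:.3f})")
            row("moles injected", f"{self.moles_injected:.3e} mol")
            row("sample concentration", f"{self.sample_conc * 1e3:.3f} mM")
        if self.target_area is not None:
            row("target area", f"{self.target_area:.4f} AU*s "
                               f"(+- {self.area_uncertainty:.4f})")
            row("quantification wavelength", f"{self.lambda_red:.0f} nm")
            row("apex time", f"{self.apex_time:.1f} s")
        if self.epsilon_used is not None:
            row("epsilon (at elution)", f"{self.epsilon_used:.3e} L/(mol cm) "
                                        f"[phi_acn={self.phi_acn:.3f}]")
        if self.n_components is not None:
            row("MCR components", f"{self.n_components} "
                                  f"(lack of fit {self.lack_of_fit:.4f} AU*s)")
        if self.ist_factor is not None:
            row("internal-standard factor", f"{self.ist_factor:.4f}")
        if self.ms_mz is not None:
            row("MS channel", f"m/z {self.ms_mz:.4f} ({self.ms_adduct})")
        if self.signal_status is not None:
            row("signal check", f"{self.signal_status} "
                                f"(suggest x{self.suggested_injection_factor:g} "
                                "injection)")
        row("flags", ", ".join(sorted(self.flags)) or "none")
        row("config digest", self.config_digest)
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable run report (lossless for all numeric fields)."""
        d = dataclasses.asdict(self)
        d["flags"] = sorted(self.flags)
        return d

    @classmethod
    def from_report(cls, d: dict) -> "YieldResult":
        d = dict(d)
        d["flags"] = frozenset(d.get("flags", []))
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_report(), indent=2, sort_keys=True)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text + "\n")
        return text


class ReactionYieldModel:
    """One chromatogram pair + expected product + configuration.

    Parameters
    ----------
    pda : PDAChromatogram
        Raw PDA absorbance matrix.
    ms_traces : sequence of MSTrace
        Extracted-ion traces covering the product adduct channels.
    analyte : AnalyteSpec
        Expected product structure, monoisotopic mass and adduct list.
    config : RunConfig
        Stage parameters and instrument constants.
    epsilon_predictor : object, optional
        Anything with ``predict(analyte, solvent) -> EpsilonPrediction``;
        defaults to the predictor named in ``config.epsilon``.
    """

    def __init__(self, pda: PDAChromatogram, ms_traces, analyte: AnalyteSpec,
                 config: RunConfig | None = None, epsilon_predictor=None):
        self.pda = pda
        self.ms_traces = list(ms_traces)
        self.analyte = analyte
        self.config = config or RunConfig()
        self.epsilon_predictor = (epsilon_predictor
                                  or make_predictor(self.config.epsilon))

    @classmethod
    def from_files(cls, pda_path, ms_path, analyte: AnalyteSpec,
                   config: RunConfig | None = None,
                   epsilon_predictor=None) -> "ReactionYieldModel":
        try:
            pda = load_pda(pda_path)
            ms = load_ms(ms_path)
        except ChromYieldError as exc:
            raise PipelineStageError("load", exc) from exc
        return cls(pda, ms, analyte, config=config,
                   epsilon_predictor=epsilon_predictor)

    def fit(self, seed: int = 0) -> YieldResult:
        """Run the full estimation chain and return the results object."""
        cfg = self.config
        pp, mcr, msc = cfg.preprocess, cfg.mcr, cfg.ms
        timings = {}
        flags = set()

        def _stage(name, fn, *args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except ChromYieldError as exc:
                raise PipelineStageError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            logger.debug("stage %s: %.3f s", name, timings[name])
            return out

        pda = _stage("smooth", smooth, self.pda,
                     window=pp.smooth_window, polyorder=pp.smooth_polyorder)
        pda = _stage("mask_solvent_front", mask_solvent_front, pda, pp.t_dead)
        # baseline estimated on the raw trace (uncorrelated noise), removed
        # from the smoothed one
        raw = self.pda.replace(t_dead=pda.t_dead)
        pda = _stage("correct_baseline", correct_baseline, pda,
                     lambda_s=pp.baseline_lambda, ratio=pp.baseline_ratio,
                     max_iter=pp.baseline_max_iter, estimate_on=raw)
        ist = _stage("internal_standard_scale", internal_standard_scale, pda,
                     pp.ist_window, pp.ist_wavelength,
                     cfg.system.ist_nominal_area,
                     clip=pp.ist_factor_clip, warn=pp.ist_factor_warn)
        if ist.out_of_range:
            flags.add("ist_out_of_range")

        ms_peak = _stage("locate_target", locate_target, pda, self.ms_traces,
                         self.analyte, cfg.system, msc)

        sl = pda.window_slice(*ms_peak.window)
        window_times = pda.times[sl]
        A_w = pda.absorbance[sl]
        rc = _stage("resolve_window", resolve_window, A_w, pda.dt,
                    threshold=mcr.threshold, max_n=mcr.max_components,
                    tol=mcr.tol, max_iter=mcr.max_iter, seed=seed)

        status, factor = signal_check(pda, ms_peak.window,
                                      a_max=cfg.signal.a_max,
                                      a_min=cfg.signal.a_min)
        if status != "ok":
            flags.add(status)

        common = dict(config_digest=cfg.digest(), version=_pkg_version,
                      ist_factor=ist.factor, ms_mz=ms_peak.mz,
                      ms_adduct=ms_peak.adduct, signal_status=status,
                      suggested_injection_factor=factor,
                      n_components=rc.n_components,
                      lack_of_fit=rc.lack_of_fit, timings=timings)

        if rc.flagged_overloaded:
            # more co-eluting species than resolvable: withhold the yield
            flags.add("overloaded")
            return YieldResult(
                yield_fraction=None, rel_uncertainty=None,
                moles_injected=None, sample_conc=None,
                flags=frozenset(flags), target_area=None,
                area_uncertainty=None, lambda_red=None, apex_time=None,
                epsilon_used=None, epsilon_rel_std=None, phi_acn=None,
                **common)

        k = _stage("assign_target", assign_target, rc, ms_peak.apex_time,
                   window_times)
        lam_red = _stage("reddest_peak", reddest_peak, rc.S[:, k],
                         pda.wavelengths, prominence=mcr.prominence,
                         lambda_floor=mcr.lambda_floor,
                         min_height=mcr.min_band_height)
        peak = _stage("integrate_target", integrate_target, rc, k, lam_red,
                      pda.wavelengths, window_times, pda.dt,
                      ist_factor=ist.factor)

        phi = gradient_fraction(peak.apex_time, cfg.gradient)
        pred_w = _stage("predict_epsilon_water", self.epsilon_predictor.predict,
                        self.analyte, "water")
        pred_a = _stage("predict_epsilon_acn", self.epsilon_predictor.predict,
                        self.analyte, "acetonitrile")
        eps, rel_std_eps = epsilon_at_elution(pred_w, pred_a, phi)

        moles = moles_from_area(peak.area, eps, cfg.system)
        sample_conc, yield_fraction, yflags = yield_from_moles(moles, cfg.system)
        flags |= yflags
        if peak.area > 0:
            rel_unc = propagate_uncertainty(peak.area, peak.area_uncertainty,
                                            rel_std_eps)
        else:
            flags.add("weak_signal")
            rel_unc = float("nan")

        return YieldResult(
            yield_fraction=yield_fraction, rel_uncertainty=rel_unc,
            moles_injected=moles, sample_conc=sample_conc,
            flags=frozenset(flags), target_area=peak.area,
            area_uncertainty=peak.area_uncertainty, lambda_red=peak.lambda_red,
            apex_time=peak.apex_time, epsilon_used=eps,
            epsilon_rel_std=rel_std_eps, phi_acn=phi, **common)


def estimate_yield(pda_path, ms_path, analyte: AnalyteSpec,
                   config: RunConfig | str | None = None,
                   seed: int = 0) -> YieldResult:
    """Convenience wrapper: load files, fit, return the results object."""
    if isinstance(config, str):
        config = RunConfig.from_json(config)
    model = ReactionYieldModel.from_files(pda_path, ms_path, analyte,
                                          config=config)
    return model.fit(seed=seed)


def run_campaign(samples, config: RunConfig, epsilon_predictor=None,
                 truth_table: pd.DataFrame | None = None,
                 seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Fit every sample of a campaign; score against truth when available.

    ``samples`` is an iterable of objects with ``sample_id``, ``pda``,
    ``ms_traces`` and ``target_spec`` attributes (e.g.
    :class:`~chromyield.simulate.SimSample`). Partial failures are recorded
    per sample and the campaign continues.

    Returns (per-sample table, summary statistics). With a truth table the
    statistics include MAE, RMSE and median absolute relative error of the
    yields over the scored (non-withheld, matched) rows.
    """
    rows = []
    for s in samples:
        row = {"sample_id": s.sample_id}
        try:
            model = ReactionYieldModel(s.pda, list(s.ms_traces), s.target_spec,
                                       config=config,
                                       epsilon_predictor=epsilon_predictor)
            res = model.fit(seed=seed)
            row.update(yield_est=res.yield_fraction,
                       rel_uncertainty=res.rel_uncertainty,
                       area=res.target_area,
                       n_components=res.n_components,
                       lack_of_fit=res.lack_of_fit,
                       ist_factor=res.ist_factor,
                       flags=",".join(sorted(res.flags)), error=None)
        except ChromYieldError as exc:
            logger.warning("sample %s failed: %s", s.sample_id, exc)
            row.update(yield_est=None, rel_uncertainty=None, area=None,
                       n_components=None, lack_of_fit=None, ist_factor=None,
                       flags="", error=str(exc))
        rows.append(row)
    table = pd.DataFrame(rows)
    stats: dict = {"n_samples": len(table),
                   "n_failed": int(table["error"].notna().sum()),
                   "n_withheld": int(table["yield_est"].isna().sum()
                                     - table["error"].notna().sum())}
    if truth_table is not None:
        merged = table.merge(truth_table[["sample_id", "true_yield"]],
                             on="sample_id", how="left", indicator=True)
        unmatched = merged["_merge"] != "both"
        stats["n_unmatched"] = int(unmatched.sum())
        scored = merged[~unmatched & merged["yield_est"].notna()]
        err = scored["yield_est"] - scored["true_yield"]
        rel = np.abs(err) / scored["true_yield"]
        stats.update(
            n_scored=len(scored),
            mae=float(np.mean(np.abs(err))) if len(scored) else float("nan"),
            rmse=float(np.sqrt(np.mean(err ** 2))) if len(scored)
            else float("nan"),
            median_abs_rel_err=float(np.median(rel)) if len(scored)
            else float("nan"))
        table = merged.drop(columns=["_merge"])
    return table, stats
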