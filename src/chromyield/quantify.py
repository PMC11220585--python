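"""Beer-Lambert quantification with a predicted molar extinction coefficient.

For a flow cell of path length l (cm) and flow rate Q (L/s), the absorbance
at the quantification wavelength is A(t) = eps * l * c(t). Integrating over
the chromatographic peak links the peak area a (AU*s) to the injected moles:

    n = Q * a / (eps * l)

so no calibration standard is needed once eps is known. Here eps comes from a
pluggable predictor (per solvent); because elution happens mid-gradient, the
predictions for pure water and pure acetonitrile are combined linearly at the
volumetric acetonitrile fraction of the elution time — for water-acetonitrile
the polarity-composition relationship is close enough to linear on a
volumetric basis for this weighted average to hold.

Yield follows from the injected moles, the injection volume, the crude ->
sample dilution, and the initial reactant concentration c0_r:

    yield = (n / V_inj) * dilution_factor / c0_r
"""

from __future__ import annotations

import json
import logging
import math
import shlex
import subprocess
from dataclasses import dataclass, field

import numpy as np

from .chromdata import (
    AnalyteSpec,
    GradientProgram,
    PDAChromatogram,
    SystemConstants,
)
from .errors import (
    ConfigurationError,
    EpsilonUnavailableError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "EpsilonPrediction",
    "YieldEstimate",
    "TablePredictor",
    "ExternalEnsembleAdapter",
    "gradient_fraction",
    "epsilon_at_elution",
    "moles_from_area",
    "area_from_moles",
    "yield_from_moles",
    "propagate_uncertainty",
    "signal_check",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


@dataclass(frozen=True)
class EpsilonPrediction:
    """Ensemble summary of a log10 extinction-coefficient prediction."""

    log10_eps_mean: float
    log10_eps_std: float
    lambda_max_pred: float
    solvent: str
    n_models: int = 1

    def __post_init__(self):
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")
        if self.log10_eps_std < 0:
            raise ValidationError("ensemble std must be >= 0")
        if self.n_models == 1 and self.log10_eps_std != 0:
            raise ValidationError("a single model has zero ensemble spread")


@dataclass(frozen=True)
class YieldEstimate:
    """Moles injected, inferred yield, and propagated relative uncertainty."""

    moles_injected: float
    sample_conc: float
    yield_fraction: float
    rel_uncertainty: float
    flags: frozenset = frozenset()

    def __post_init__(self):
        if self.moles_injected < 0 or self.yield_fraction < 0:
            raise ValidationError("moles and yield must be non-negative")
        if self.rel_uncertainty < 0:
            raise ValidationError("rel_uncertainty must be non-negative")


class TablePredictor:
    """Extinction-coefficient lookup keyed by (smiles, solvent).

    Entries are dicts with ``log10_eps`` (mean), optional ``log10_eps_std``
    (ensemble spread, default 0), optional ``lambda_max`` (nm) and
    ``n_models``. This is the default predictor for tests and simulations;
    a trained ensemble is attached through
    :class:`ExternalEnsembleAdapter` instead.
    """

    def __init__(self, table: dict | None = None):
        self._table: dict = {}
        if table:
            for key, entry in table.items():
                smiles, solvent = key if isinstance(key, tuple) else key.split("|", 1)
                self._table[(smiles, solvent)] = dict(entry)

    @classmethod
    def from_csv(cls, path) -> "TablePredictor":
        import pandas as pd

        df = pd.read_csv(path)
        table = {}
        for _, row in df.iterrows():
            entry = {"log10_eps": float(row["log10_eps"])}
            if "log10_eps_std" in df.columns and not pd.isna(row.get("log10_eps_std")):
                entry["log10_eps_std"] = float(row["log10_eps_std"])
            if "lambda_max" in df.columns and not pd.isna(row.get("lambda_max")):
                entry["lambda_max"] = float(row["lambda_max"])
            if "n_models" in df.columns and not pd.isna(row.get("n_models")):
                entry["n_models"] = int(row["n_models"])
            table[(str(row["smiles"]), str(row["solvent"]))] = entry
        return cls(table)

    def add(self, smiles: str, solvent: str, log10_eps: float,
            log10_eps_std: float = 0.0, lambda_max: float = float("nan"),
            n_models: int = 1) -> None:
        self._table[(smiles, solvent)] = {
            "log10_eps": log10_eps, "log10_eps_std": log10_eps_std,
            "lambda_max": lambda_max, "n_models": n_models}

    def predict(self, analyte, solvent: str) -> EpsilonPrediction:
        smiles = analyte.smiles if isinstance(analyte, AnalyteSpec) else str(analyte)
        entry = self._table.get((smiles, solvent))
        if entry is None:
            raise EpsilonUnavailableError(
                f"no epsilon available for ({smiles!r}, {solvent!r})")
        n_models = int(entry.get("n_models", 1))
        std = float(entry.get("log10_eps_std", 0.0))
        if n_models == 1:
            std = 0.0
        return EpsilonPrediction(
            log10_eps_mean=float(entry["log10_eps"]),
            log10_eps_std=std,
            lambda_max_pred=float(entry.get("lambda_max", float("nan"))),
            solvent=solvent, n_models=n_models)


class ExternalEnsembleAdapter:
    """Adapter to an externally trained prediction ensemble.

    Runs ``command`` as a subprocess, passing ``{"smiles": ..., "solvent":
    ...}`` as JSON on stdin and expecting ``{"log10_eps": [per-model values],
    "lambda_max": [per-model values]}`` on stdout. The per-model values are
    reduced to mean and population standard deviation. No model is trained or
    shipped in this package.
    """

    def __init__(self, command: str, timeout: float = 120.0):
        if not command:
            raise ConfigurationError("adapter command must be non-empty")
        self.command = command
        self.timeout = timeout

    def predict(self, analyte, solvent: str) -> EpsilonPrediction:
        smiles = analyte.smiles if isinstance(analyte, AnalyteSpec) else str(analyte)
        payload = json.dumps({"smiles": smiles, "solvent": solvent})
        try:
            proc = subprocess.run(
                shlex.split(self.command), input=payload, capture_output=True,
                text=True, timeout=self.timeout, check=True)
            out = json.loads(proc.stdout)
            values = [float(v) for v in out["log10_eps"]]
        except (OSError, subprocess.SubprocessError, KeyError,
                ValueError, json.JSONDecodeError) as exc:
            raise EpsilonUnavailableError(
                f"epsilon adapter failed for ({smiles!r}, {solvent!r}): {exc}"
            ) from exc
        if not values:
            raise EpsilonUnavailableError("adapter returned no predictions")
        lam = out.get("lambda_max", [])
        lam_mean = float(np.mean(lam)) if lam else float("nan")
        n = len(values)
        return EpsilonPrediction(
            log10_eps_mean=float(np.mean(values)),
            log10_eps_std=float(np.std(values)) if n > 1 else 0.0,
            lambda_max_pred=lam_mean, solvent=solvent, n_models=n)


def make_predictor(epsilon_config):
    """Build the predictor named by an :class:`~chromyield.config.EpsilonConfig`."""
    if epsilon_config.predictor == "table":
        if epsilon_config.table_path:
            return TablePredictor.from_csv(epsilon_config.table_path)
        table = {tuple(k.split("|", 1)): v
                 for k, v in epsilon_config.table.items()} \
            if epsilon_config.table else {}
        return TablePredictor(table)
    if epsilon_config.predictor == "adapter":
        return ExternalEnsembleAdapter(epsilon_config.adapter_command)
    raise ConfigurationError(
        f"unknown epsilon predictor {epsilon_config.predictor!r}")


def gradient_fraction(t: float, program: GradientProgram) -> float:
    """Volumetric acetonitrile fraction at elution time ``t`` (s)."""
    if program is None or len(program.breakpoints) < 2:
        raise ConfigurationError("gradient program is empty")
    t0, t1 = program.breakpoints[0][0], program.breakpoints[-1][0]
    if t < t0 or t > t1:
        logger.warning("time %.1f s outside gradient program [%g, %g]; clamped",
                       t, t0, t1)
    return program.fraction(t)


def epsilon_at_elution(pred_water: EpsilonPrediction,
                       pred_acn: EpsilonPrediction,
                       phi_acn: float) -> tuple[float, float]:
    """Extinction coefficient at the elution composition.

    Linear-epsilon volumetric weighting of the two pure-solvent predictions:
    ``eps = phi * 10**mean_acn + (1 - phi) * 10**mean_water``. The relative
    uncertainty is the same weighting of the log10 ensemble spreads,
    linearized: ``rel_std = ln(10) * (phi*std_acn + (1-phi)*std_water)``.
    """
    if not 0.0 <= phi_acn <= 1.0:
        raise ParameterError(f"phi_acn={phi_acn} must lie in [0, 1]")
    eps = (phi_acn * 10.0 ** pred_acn.log10_eps_mean
           + (1.0 - phi_acn) * 10.0 ** pred_water.log10_eps_mean)
    rel_std = LN10 * (phi_acn * pred_acn.log10_eps_std
                      + (1.0 - phi_acn) * pred_water.log10_eps_std)
    return float(eps), float(rel_std)


def moles_from_area(area: float, eps: float, constants: SystemConstants
                    ) -> float:
    """Injected moles from a peak area via Beer-Lambert: n = Q a / (eps l)."""
    if not eps > 0:
        raise ParameterError(f"extinction coefficient must be positive, got {eps}")
    if area < 0:
        raise ParameterError("area must be non-negative")
    return constants.flow_rate_l_per_s * area / (eps * constants.path_length)


def area_from_moles(moles: float, eps: float, constants: SystemConstants
                    ) -> float:
    """Inverse of :func:`moles_from_area`: a = n eps l / Q."""
    if not eps > 0:
        raise ParameterError(f"extinction coefficient must be positive, got {eps}")
    return moles * eps * constants.path_length / constants.flow_rate_l_per_s


def yield_from_moles(moles: float, constants: SystemConstants
                     ) -> tuple[float, float, set]:
    """(sample concentration mol/L, yield fraction, flags) from injected moles.

    sample_conc = n / V_inj; the crude concentration is sample_conc times the
    dilution factor; yield is crude concentration over the initial reactant
    concentration. Yields above 1.05 are flagged, never clipped — over-unity
    values are diagnostic (co-eluting look-alikes), not errors.
    """
    if moles < 0:
        raise ParameterError("moles must be non-negative")
    v_inj_l = constants.injection_volume * 1e-6
    sample_conc = moles / v_inj_l
    crude_conc = sample_conc * constants.dilution_factor
    yield_fraction = crude_conc / constants.reactant_conc
    flags = {"yield_gt_1"} if yield_fraction > 1.05 else set()
    return sample_conc, yield_fraction, flags


def propagate_uncertainty(area: float, area_uncertainty: float,
                          rel_std_eps: float) -> float:
    """Relative yield uncertainty: quadrature of area and epsilon terms."""
    if area <= 0:
        raise ParameterError("area must be positive for uncertainty propagation")
    return math.sqrt((area_uncertainty / area) ** 2 + rel_std_eps ** 2)


def signal_check(pda: PDAChromatogram, window, a_max: float = 2.0,
                 a_min: float = 0.01) -> tuple[str, float]:
    """Dynamic-range check of the window apex.

    Returns (status, suggested_injection_factor): ``saturated`` -> rerun at
    half the injection volume, ``weak`` -> rerun at twice, ``ok`` -> keep.
    """
    sl = pda.window_slice(float(window[0]), float(window[1]))
    seg = pda.absorbance[sl]
    if seg.size == 0:
        raise ParameterError("signal-check window contains no samples")
    apex = float(np.max(seg))
    if apex >= a_max:
        return "saturated", 0.5
    if apex < a_min:
        return "weak", 2.0
    return "ok", 1.0
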