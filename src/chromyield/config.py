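"""Run configuration: JSON-backed blocks for every pipeline stage.

The configuration mirrors the stages of the workflow: ``system`` (instrument
constants), ``gradient`` (mobile-phase program), ``preprocess`` (smoothing,
baseline, solvent mask, internal standard), ``ms`` (adducts, SNR, delay),
``mcr`` (resolution), ``signal`` (dynamic-range thresholds) and ``epsilon``
(extinction-coefficient predictor). ``RunConfig.digest()`` hashes the
canonical JSON so every report records exactly the configuration used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .chromdata import GradientProgram, SystemConstants
from .errors import ConfigurationError

__all__ = ["RunConfig", "PreprocessConfig", "MSConfig", "MCRConfig",
           "SignalConfig", "EpsilonConfig"]


@dataclass(frozen=True)
class PreprocessConfig:
    smooth_window: int = 7            # points, odd
    smooth_polyorder: int = 3
    baseline_lambda: float = 1e4      # arPLS second-difference penalty
    baseline_ratio: float = 1e-6      # arPLS convergence threshold
    baseline_max_iter: int = 100
    t_dead: float = 24.0              # s, solvent-front mask
    ist_window: tuple = (345.0, 375.0)   # s, internal-standard integration window
    ist_wavelength: float = 250.0     # nm
    ist_factor_clip: tuple = (0.5, 2.0)
    ist_factor_warn: tuple = (0.8, 1.25)


@dataclass(frozen=True)
class MSConfig:
    adducts: tuple = ("M+H",)
    mz_tol: float = 0.5               # Da, unit-resolution quadrupole
    min_snr: float = 10.0
    max_lag: float = 30.0             # s, delay search range
    min_corr: float = 0.3             # normalized cross-correlation significance
    window_pad: float = 5.0           # s, widen MS window each side


@dataclass(frozen=True)
class MCRConfig:
    threshold: float = 0.2            # AU*s lack-of-fit acceptance
    max_components: int = 3
    tol: float = 1e-8
    max_iter: int = 500
    prominence: float = 0.05          # fraction of spectrum maximum
    min_band_height: float = 0.1      # fraction of spectrum maximum
    lambda_floor: float = 220.0       # nm, reddest-peak search floor


@dataclass(frozen=True)
class SignalConfig:
    a_max: float = 2.0                # AU, PDA saturation
    a_min: float = 0.01               # AU, weak-signal apex


@dataclass(frozen=True)
class EpsilonConfig:
    predictor: str = "table"          # "table" | "adapter"
    table_path: str | None = None
    table: dict = field(default_factory=dict)  # inline {(smiles|solvent): entry}
    adapter_command: str | None = None


@dataclass(frozen=True)
class RunConfig:
    system: SystemConstants = field(default_factory=SystemConstants)
    gradient: GradientProgram = field(default_factory=GradientProgram.default_8min)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    ms: MSConfig = field(default_factory=MSConfig)
    mcr: MCRConfig = field(default_factory=MCRConfig)
    signal: SignalConfig = field(default_factory=SignalConfig)
    epsilon: EpsilonConfig = field(default_factory=EpsilonConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        d = {name: enc(getattr(self, name)) for name in
             ("system", "preprocess", "ms", "mcr", "signal", "epsilon")}
        # gradient serialized in minutes for readability, converted on load
        d["gradient"] = {
            "breakpoints_min": [[t / 60.0, f]
                                for t, f in self.gradient.breakpoints]
        }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(str(path), "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def sub(klass, key):
            block = d.get(key, {})
            if not isinstance(block, dict):
                raise ConfigurationError(f"config block {key!r} must be an object")
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - names
            if unknown:
                raise ConfigurationError(
                    f"unknown keys in config block {key!r}: {sorted(unknown)}")
            kwargs = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in block.items()}
            return klass(**kwargs)

        grad_block = d.get("gradient", {})
        if "breakpoints_min" in grad_block:
            gradient = GradientProgram(tuple(
                (60.0 * t, f) for t, f in grad_block["breakpoints_min"]))
        elif "breakpoints" in grad_block:
            gradient = GradientProgram(tuple(map(tuple, grad_block["breakpoints"])))
        else:
            gradient = GradientProgram.default_8min()
        return cls(
            system=sub(SystemConstants, "system"),
            gradient=gradient,
            preprocess=sub(PreprocessConfig, "preprocess"),
            ms=sub(MSConfig, "ms"),
            mcr=sub(MCRConfig, "mcr"),
            signal=sub(SignalConfig, "signal"),
            epsilon=sub(EpsilonConfig, "epsilon"),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(str(path)) as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """SHA-256 of the canonical JSON encoding (tamper check for reports)."""
        canonical = json.dumps(self.to_dict(), sort_keys=True,
                               separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
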