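"""Typed exceptions raised by the pipeline.

Every stage raises a subclass of :class:`ChromYieldError` so the orchestrator
can attach the stage name and a remediation hint before surfacing it.
"""


class ChromYieldError(Exception):
    """Base class for all package errors."""


class ValidationError(ChromYieldError):
    """An object failed its type invariants (non-finite data, bad axes...)."""


class FormatError(ChromYieldError):
    """A file could not be parsed into the declared layout."""


class ParameterError(ChromYieldError):
    """A parameter is outside its admissible range."""


class ConfigurationError(ChromYieldError):
    """The run configuration is missing a required entry."""


class ChannelLookupError(ChromYieldError):
    """No extracted-ion channel matches the requested m/z."""

    def __init__(self, requested, available):
        self.requested = requested
        self.available = list(available)
        super().__init__(
            f"no MS channel within tolerance of m/z {requested:.4f}; "
            f"available channels: {self.available}"
        )


class ProductNotDetectedError(ChromYieldError):
    """No MS peak above the SNR threshold for any searched adduct mass.

    Signals reaction failure or ionization failure, not a software fault.
    """

    def __init__(self, mz_searched):
        self.mz_searched = list(mz_searched)
        super().__init__(
            "product mass not detected — no MS peak above threshold at "
            f"m/z {self.mz_searched}; check the adduct list"
        )


class TargetInDeadVolumeError(ChromYieldError):
    """The located target window overlaps the masked solvent front."""


class AssignmentAmbiguousError(ChromYieldError):
    """No resolved component apexes close enough to the MS retention time."""


class InternalStandardError(ChromYieldError):
    """Internal-standard peak absent or below the detection threshold."""


class EpsilonUnavailableError(ChromYieldError):
    """No extinction-coefficient prediction for the analyte/solvent pair."""
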