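"""Exception types shared across the package."""


class ManducaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ManducaError):
    """A template, schedule, or experiment configuration is invalid."""


class DimensionMismatchError(ManducaError):
    """An instance and a stimulus schedule disagree on glomerulus count."""


class SimulationDivergedError(ManducaError):
    """A firing rate became non-finite during integration."""


class UndefinedMetricError(ManducaError):
    """A readout metric is undefined for the given response sets."""


class InjuryDomainError(ManducaError):
    """An injury specification implies total destruction or is out of range."""
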