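"""Exception hierarchy shared across the pipeline."""


class DynFncError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DynFncError, ValueError):
    """Invalid configuration value (bad pair index, non-PD covariance, ...)."""


class ArgumentError(DynFncError, ValueError):
    """Invalid argument to an operation."""


class DegenerateDataError(DynFncError, ValueError):
    """Input has no usable variation (constant component, zero pooled SD, ...)."""


class InsufficientDataError(DynFncError, ValueError):
    """Too few time points / windows / subjects for the requested operation."""


class RankDeficiencyError(DynFncError, ValueError):
    """A regression design (spatial maps, ...) is rank deficient."""


class AlignmentError(DynFncError, ValueError):
    """Paired inputs do not describe the same subjects."""


class StageDependencyError(DynFncError, RuntimeError):
    """A pipeline stage was asked to run before its inputs exist."""


class EmptySelectionError(DynFncError, RuntimeError):
    """Feature selection retained nothing in every cross-validation fold."""
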