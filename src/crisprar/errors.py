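"""Exception hierarchy and warnings used across the package."""


class CrisprarError(Exception):
    """Base class for all package errors."""


class InvalidKineticsError(CrisprarError, ValueError):
    """Promoter switching rates violate the model's domain (e.g. k_on+k_off <= 0)."""


class ParameterDomainError(CrisprarError, ValueError):
    """A regulation parameter produced a rate outside (0, wild-type]."""


class InvalidSummaryError(CrisprarError, ValueError):
    """A summary statistic (mean, noise) is outside its valid domain."""


class NotMatchedError(CrisprarError, ValueError):
    """Two kinetics were compared at matched mean but their mean ratio differs."""


class ConfigurationError(CrisprarError, ValueError):
    """Invalid library/pipeline configuration (bad strengths, duplicate names, empty grids)."""


class NotARepressorError(CrisprarError, ValueError):
    """Fold change > 1 handed to the repression-strength estimator."""


class NotAnActivatorError(CrisprarError, ValueError):
    """Fold change < 1 handed to the activation-strength estimator."""


class IncompleteEstimationError(CrisprarError, ValueError):
    """A construct is missing an estimated regulation strength."""


class InsufficientDataError(CrisprarError, ValueError):
    """Too few points/events for the requested statistic."""


class DegenerateFitError(CrisprarError, ValueError):
    """Zero variance in the regressor: the line is not identifiable."""


class UndefinedNoiseError(CrisprarError, ValueError):
    """eta^2 = sigma^2/mu^2 is undefined because mu is zero."""


class NormalizationError(CrisprarError, ValueError):
    """No usable no-sgRNA control for mean normalization."""


class InsufficientSampleError(CrisprarError, ValueError):
    """Sample too small to estimate a standard error."""


class SaturationWarning(UserWarning):
    """Fold change outside the range the two-state model can express; estimate clamped."""


class GatingWarning(UserWarning):
    """Gating removed an unusually large fraction of events, or was disabled."""


class StationarityWarning(UserWarning):
    """Burn-in shorter than a few relaxation times; sample may not be stationary."""
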