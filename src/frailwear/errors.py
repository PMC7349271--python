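"""Exception hierarchy. Every stage raises a subclass of FrailwearError so
pipelines can abort with the failing stage named."""


class FrailwearError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrailwearError):
    """Invalid configuration value (bad class name, window shorter than one sample, ...)."""


class FormatError(FrailwearError):
    """On-disk session data violates the schema (missing column, unknown phase, non-monotone time)."""


class GenerationError(FrailwearError):
    """Synthetic session could not be generated (e.g., a phase with no samples)."""


class ResamplingError(FrailwearError):
    """Resampling preconditions violated (fewer than two samples)."""


class ComputationError(FrailwearError):
    """Feature computation on invalid input (empty window)."""


class AssemblyError(FrailwearError):
    """Feature-matrix assembly failed (session missing a protocol phase)."""


class RankingError(FrailwearError):
    """Feature ranking impossible (single-class labels, no features)."""


class StratificationError(FrailwearError):
    """Stratified folds cannot be built (a class has fewer records than folds)."""


class ContractError(FrailwearError):
    """Model applied to a matrix whose feature names differ from training."""


class ExperimentError(FrailwearError):
    """Phase-subset experiment has an empty restriction or unknown phases."""
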