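"""Exception hierarchy for the analysis chain.

Stage errors carry enough context (well, strain, batch, position) that a
failure in a long pipeline run names the offending record.
"""


class AlascanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AlascanError):
    """Invalid simulation or pipeline configuration."""


class GatingError(AlascanError):
    """Scatter gating left no events in a well."""


class SummarizationError(AlascanError):
    """A strain cannot be summarized (missing condition, too few replicates)."""


class UndefinedFoldError(SummarizationError):
    """Fold induction undefined because the uninduced mean is zero."""


class ThresholdError(AlascanError):
    """Library too small for threshold estimation."""


class NormalizationError(AlascanError):
    """Spectral-count normalization failed (empty set, no usable standard)."""


class BatchAnchorError(AlascanError):
    """A measurement batch has no anchor-strain sample."""


class JoinError(AlascanError):
    """Induction and abundance streams cannot be joined uniquely."""


class ValidationError(AlascanError):
    """Residue metadata disagrees with the reference sequence."""
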