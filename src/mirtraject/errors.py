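"""Exception hierarchy shared across the pipeline."""


class MirtrajectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirtrajectError):
    """Invalid generator/analysis configuration."""


class ParseError(MirtrajectError):
    """Malformed tabular input (names the offending row/column)."""


class FormatError(MirtrajectError):
    """Structurally invalid file (e.g. RCC missing a required section)."""


class ValidationError(MirtrajectError):
    """Manifest or data-contract violation."""


class StageError(MirtrajectError):
    """Normalization stage applied out of order or twice."""


class NormalizationError(MirtrajectError):
    """Degenerate data encountered while computing scale factors."""


class EstimationError(MirtrajectError):
    """Model cannot be fitted (non-identifiable or insufficient data)."""


class InsufficientDataError(EstimationError):
    """Too few observations for the requested fit."""
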