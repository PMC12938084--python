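"""Exception hierarchy for coevodist."""


class CoevodistError(Exception):
    """Base class for package errors."""


class MSAFormatError(CoevodistError):
    """Alignment file violates format expectations (lengths, alphabet, query)."""


class EmptyInputError(CoevodistError):
    """An input file or collection contained no usable records."""


class DimensionError(CoevodistError):
    """Array shapes incompatible with the declared protein length or channels."""


class UndefinedCorrelationError(CoevodistError):
    """Pearson correlation requested on a zero-variance sample."""


class GenerationError(CoevodistError):
    """Synthetic structure generation failed (e.g. self-avoidance retries exhausted)."""


class TrainingDivergedError(CoevodistError):
    """Loss became non-finite during optimisation."""


class ConfigError(CoevodistError):
    """Checkpoint / feature-manifest / configuration mismatch."""
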