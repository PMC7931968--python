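"""Exception hierarchy shared across the toolkit.

Every error raised by the public API derives from :class:`TgxddiError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class TgxddiError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TgxddiError):
    """A file does not conform to its declared format (bad header, bad cell)."""


class ValidationError(TgxddiError):
    """An input violates a documented invariant (duplicate ids, bad range)."""


class CoverageError(ValidationError):
    """Panel coverage below the acceptable fraction; lists missing genes."""

    def __init__(self, message: str, missing: list[str], coverage: float):
        super().__init__(message)
        self.missing = missing
        self.coverage = coverage


class PairingError(ValidationError):
    """Treated/control sample pairing is not total."""


class InsufficientReplicatesError(ValidationError):
    """A tested arm has fewer than two replicates."""


class TrainingError(ValidationError):
    """Classifier training preconditions not met (class too small, bad delta)."""


class FoldError(TgxddiError):
    """Cross-validation folds would leave a class with too few training samples."""


class AlignmentError(ValidationError):
    """Sample gene ids do not align with the model or reference genes."""


class DegenerateModelError(TgxddiError):
    """A model has no usable structure (no surviving genes, zero variance)."""


class FittingError(TgxddiError):
    """Dose-response fitting preconditions not met."""


class PotencyUndefinedError(TgxddiError):
    """No usable per-gene benchmark dose; the panel median is undefined."""
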