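"""Exception hierarchy shared across the package."""


class PlmGraphError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PlmGraphError):
    """A structure or sequence file could not be parsed."""


class ChainNotFoundError(PlmGraphError, KeyError):
    """Requested chain is absent or empty."""


class ModelIndexError(PlmGraphError, IndexError):
    """Requested coordinate model does not exist in the file."""


class ValidationError(PlmGraphError, ValueError):
    """An input violates a documented precondition."""


class ShapeError(ValidationError):
    """Array dimensions are inconsistent."""


class NodeAlignmentError(ShapeError):
    """Embedding rows do not match graph nodes; sequence/structure
    reconciliation is required before feature integration."""


class ConfigError(PlmGraphError, ValueError):
    """A run configuration is invalid."""


class DivergenceError(PlmGraphError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class ChainGenerationError(PlmGraphError, RuntimeError):
    """Self-avoiding backbone sampling exhausted its retry budget;
    consider loosening the turning-angle or clash constraints."""


class UndefinedMetricError(PlmGraphError, ValueError):
    """The requested statistic is undefined for the given input
    (e.g. AUROC with a single class)."""
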