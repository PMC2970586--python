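"""Exception hierarchy for the geo-imputation pipeline."""


class GeoimputeError(Exception):
    """Base class for all package errors."""


class InvalidStageError(GeoimputeError):
    """Stage code outside the 0-7 / unknown coding scheme."""


class InvalidCategoryError(GeoimputeError):
    """Demographic category cannot be mapped to a subgroup."""


class DegenerateGeometryError(GeoimputeError):
    """Polygon with zero area or too few vertices."""


class NoDestinationError(GeoimputeError):
    """No facility supplied as a travel destination."""


class UnreachableError(GeoimputeError):
    """Origin disconnected from every facility on the network."""


class EmptyInputError(GeoimputeError):
    """An operation requiring data received none."""


class InvalidDrawError(GeoimputeError):
    """Uniform draw outside [0, 1)."""


class CapacityExhaustedError(GeoimputeError):
    """More cases in a (zone, subgroup) than the subgroup population."""


class EmptySupportError(GeoimputeError):
    """A (zone, subgroup) cell has zero census population."""


class MissingCovariateError(GeoimputeError):
    """A case's unit lacks a distance covariate."""


class NonConvergenceError(GeoimputeError):
    """Optimizer failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class AnalysisQualityError(GeoimputeError):
    """Too many replicate fits failed for summaries to be trustworthy."""


class SchemaError(GeoimputeError):
    """Input table violates the expected schema."""


class IntegrityError(GeoimputeError):
    """Cross-table reference (e.g. block -> zone) is dangling."""


class ConfigError(GeoimputeError):
    """Invalid run or generator configuration."""
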