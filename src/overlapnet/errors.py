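"""Exception hierarchy shared across the package."""


class OverlapNetError(Exception):
    """Base class for all package-specific errors."""


class MissingFileError(OverlapNetError, FileNotFoundError):
    pass


class SchemaError(OverlapNetError, ValueError):
    """Input table does not match the documented schema.

    ``rows`` carries the offending row indices/records when available.
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows or []


class DuplicateRegionError(SchemaError):
    pass


class NonPositiveError(OverlapNetError, ValueError):
    pass


class AffineError(OverlapNetError, ValueError):
    pass


class OutOfBoundsError(OverlapNetError, ValueError):
    pass


class GridMismatchError(OverlapNetError, ValueError):
    pass


class ZeroVarianceError(OverlapNetError, ValueError):
    pass


class ShapeMismatchError(OverlapNetError, ValueError):
    pass


class SpecError(OverlapNetError, ValueError):
    pass


class InfeasibleSupportError(SpecError):
    pass


class DivergenceError(OverlapNetError, RuntimeError):
    pass


class RankError(OverlapNetError, ValueError):
    pass


class ModelStateError(OverlapNetError, RuntimeError):
    pass


class ConfigMismatchError(OverlapNetError, ValueError):
    pass


class ConstantTraitError(OverlapNetError, ValueError):
    pass


class LengthMismatchError(OverlapNetError, ValueError):
    pass


class ClassImbalanceError(OverlapNetError, ValueError):
    pass


class EstimatorError(OverlapNetError, ValueError):
    pass


class InsufficientDataError(OverlapNetError, ValueError):
    pass
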