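"""Exception hierarchy for anovahd.

All package errors derive from :class:`AnovaHDError` so callers can catch
one base class at the CLI boundary.
"""


class AnovaHDError(Exception):
    """Base class for all anovahd errors."""


class ZeroVarianceColumn(AnovaHDError):
    """A column is constant and cannot be scaled or correlated."""

    def __init__(self, feature_id):
        self.feature_id = feature_id
        super().__init__(f"column {feature_id!r} has zero sample variance")


class MissingValues(AnovaHDError):
    """Input contains missing entries; lists (sample, feature) coordinates."""

    def __init__(self, coordinates):
        self.coordinates = list(coordinates)
        shown = ", ".join(f"({s}, {f})" for s, f in self.coordinates[:5])
        more = "" if len(self.coordinates) <= 5 else f" and {len(self.coordinates) - 5} more"
        super().__init__(f"missing values at {shown}{more}")


class DuplicateIds(AnovaHDError):
    """Sample or feature identifiers are not unique."""


class ParseError(AnovaHDError):
    """A file could not be parsed; message carries the line number."""


class DimensionMismatch(AnovaHDError):
    """Vector/matrix dimensions are incompatible."""


class SampleMismatch(AnovaHDError):
    """Two matrices do not share the same samples in the same order."""


class ConstantResponse(AnovaHDError):
    """The response vector has zero variance."""


class DegenerateSpan(AnovaHDError):
    """A random span vector was numerically constant twice in a row."""


class NumericalEigenFailure(AnovaHDError):
    """Eigendecomposition of the kernel did not converge."""


class NumericalSVDFailure(AnovaHDError):
    """Singular value decomposition did not converge."""


class NegativeEigenvalue(AnovaHDError):
    """Kernel eigenvalue below the negative tolerance — not a valid PSD kernel."""


class InvalidSpec(AnovaHDError):
    """A sampler or simulation specification is invalid."""


class ScalingRequired(AnovaHDError):
    """An operation requires a specific scaling_state on its input."""


class InvalidFraction(AnovaHDError):
    """Nested-design fraction yields an empty or complete column subset."""


class InvalidCount(AnovaHDError):
    """A requested subset size is out of range."""


class TooFewSamples(AnovaHDError):
    """Not enough samples for the requested cross-validation folds."""
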