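"""Exception hierarchy for the coldmeta pipeline.

Every error raised on bad user input derives from :class:`ColdMetaError`,
so callers (and the CLI) can catch one base class.
"""


class ColdMetaError(Exception):
    """Base class for all coldmeta errors."""


class InvalidInputError(ColdMetaError, ValueError):
    """A scalar argument violates its precondition."""


class SchemaError(ColdMetaError, ValueError):
    """A study table violates the CSV schema; message carries the row number."""


class ClassificationError(ColdMetaError, ValueError):
    """A (MAT, MAP) point cannot be assigned to any configured biome region."""


class DegreesOfFreedomError(ColdMetaError, ValueError):
    """Pooled SD undefined: n_w + n_c - 2 < 1."""


class ZeroVarianceError(ColdMetaError, ValueError):
    """Both arm SDs are zero; the standardized difference is undefined."""


class DataIntegrityError(ColdMetaError, ValueError):
    """Rows sharing a control cluster disagree on their control arm."""


class NumericalError(ColdMetaError, ArithmeticError):
    """A linear-algebra step failed (singular covariance etc.)."""


class EmptySetError(ColdMetaError, ValueError):
    """An aggregate operation received zero effects."""


class InsufficientDataError(ColdMetaError, ValueError):
    """Fewer effects than design columns in a regression."""


class CollinearityError(ColdMetaError, ValueError):
    """Rank-deficient regression design; message lists aliased terms."""

    def __init__(self, aliased, message=None):
        self.aliased = list(aliased)
        super().__init__(message or f"design is rank deficient; aliased terms: {self.aliased}")


class ScenarioError(ColdMetaError, ValueError):
    """A simulation scenario is internally inconsistent."""


class LookupError_(ColdMetaError, KeyError):
    """Unknown fixture or factor name."""
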