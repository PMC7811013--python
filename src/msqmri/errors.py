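"""Exception hierarchy.

All package errors derive from :class:`MsqmriError` so callers can catch one
type; each subclass also derives from the closest builtin so untargeted
``except ValueError`` style handling keeps working.
"""


class MsqmriError(Exception):
    """Base class for all msqmri errors."""


class ConfigurationError(MsqmriError, ValueError):
    """Invalid cohort or pipeline configuration."""


class AlignmentError(MsqmriError, ValueError):
    """Image volumes do not share shape, voxel size, or space tag."""


class FormatError(MsqmriError, ValueError):
    """Malformed input data (labels, probabilities, tables)."""


class DomainError(MsqmriError, ValueError):
    """Argument outside its mathematical domain."""


class DesignError(MsqmriError, ValueError):
    """A regression design that cannot be fitted (too few rows, no levels)."""


class SingularDesignError(DesignError):
    """Rank-deficient regression design.

    Parameters
    ----------
    aliased : list of str
        Names of design columns that are linearly dependent on earlier ones.
    """

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "singular design matrix; aliased columns: " + ", ".join(self.aliased)
        )


class DependencyError(MsqmriError, RuntimeError):
    """A pipeline stage was requested before its inputs exist."""
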