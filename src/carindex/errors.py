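"""Exception hierarchy for carindex.

All errors derive from :class:`CarindexError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class CarindexError(Exception):
    """Base class for all carindex errors."""


class InvalidInputError(CarindexError, ValueError):
    """Malformed or out-of-contract input (empty names, bad factors, ...)."""


class DegenerateBudgetError(CarindexError, ValueError):
    """A budget whose total appropriation is zero: the CRI is undefined."""


class DegeneratePopulationError(CarindexError, ValueError):
    """A count table with zero denominator population."""


class InconsistentCountsError(CarindexError, ValueError):
    """Cell counts that exceed or fail to sum to their stated total."""


class MissingDataError(CarindexError, ValueError):
    """A required table or variable is absent for a city."""


class InsufficientDataError(CarindexError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateVariableError(CarindexError, ValueError):
    """A variable with zero spread cannot be z-standardized."""


class CollinearityError(CarindexError, ValueError):
    """Rank-deficient regression design.

    Attributes
    ----------
    columns : list of str
        Names of the offending (linearly dependent) design columns.
    """

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns or [])


class InvalidLabelError(CarindexError, KeyError):
    """An unknown variable, variant, or exposure label."""


class FeasibilityError(CarindexError, ValueError):
    """A synthetic budget target incompatible with the configured shares."""
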