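"""Exception hierarchy.

Every error the pipeline raises deliberately derives from :class:`ChemoplsError`
so the end-to-end driver can isolate a failing stratum without masking
programming errors.
"""


class ChemoplsError(Exception):
    """Base class for all errors raised by chemopls."""


class TableFormatError(ChemoplsError, ValueError):
    """Malformed table or GMT file (duplicate ids, short lines, ...)."""


class TableParseError(ChemoplsError, ValueError):
    """A cell could not be parsed; the message names row and column."""


class ConsistencyError(ChemoplsError, ValueError):
    """Cross-file or cross-set inconsistency (sample missing in metadata,
    selected metabolites outside the universe, ...)."""


class ConfigError(ChemoplsError, ValueError):
    """Invalid generator or pipeline configuration."""


class DataError(ChemoplsError, ValueError):
    """Data violates an operation's precondition (e.g. non-positive
    internal-standard value)."""


class UsageError(ChemoplsError, ValueError):
    """Operation applied to the wrong kind of input (e.g. media subtraction
    on a pellet stratum)."""


class FoldError(ChemoplsError, ValueError):
    """A cross-validation fold would empty a class; use fewer folds."""


class DegenerateComponentError(ChemoplsError, ValueError):
    """Requested more components than the data support."""


class SelectionCollapseError(ChemoplsError, ValueError):
    """|w*| selection retained fewer than two metabolites."""
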