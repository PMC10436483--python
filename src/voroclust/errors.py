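"""Exception hierarchy.

All package errors derive from :class:`VoroclustError` so callers can catch
broadly; geometry failures and absent cluster signal are kept distinct
because the latter is an ordinary outcome on clusterless data, not a bug.
"""


class VoroclustError(Exception):
    """Base class for all errors raised by voroclust."""


class FormatError(VoroclustError):
    """Input table does not match the declared dialect (missing columns...)."""


class ParseError(VoroclustError):
    """A value in the input table could not be interpreted as a number."""


class EmptyInputError(VoroclustError):
    """An operation received zero localizations / zero usable cells."""


class GeometryError(VoroclustError):
    """Degenerate or numerically failing geometric configuration."""


class NoClusterSignalError(VoroclustError):
    """Experimental cell-size PDF never exceeds the null: nothing to segment."""


class ConfigurationError(VoroclustError):
    """Invalid or infeasible simulation / run configuration."""
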