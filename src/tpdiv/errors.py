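"""Exception hierarchy.

``ConfigurationError`` marks bad parameters (user-supplied knobs), ``InputError``
marks malformed data, ``UsageError`` marks calls that violate an operation's
contract (e.g. asking for functional richness of an un-thresholded density).
All derive from ``TPDivError`` so callers can catch the package's failures
in one clause.
"""


class TPDivError(Exception):
    """Base class for all tpdiv errors."""


class ConfigurationError(TPDivError, ValueError):
    """A parameter value is outside its legal range."""


class InputError(TPDivError, ValueError):
    """Input data are malformed (duplicates, bad types, unknown categories)."""


class UsageError(TPDivError, RuntimeError):
    """An operation was called out of order or on an object in the wrong state."""


class DegenerateNullError(TPDivError, RuntimeError):
    """A null distribution has zero spread; effect sizes are undefined."""
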