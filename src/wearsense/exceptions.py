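"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: format/data-quality problems -> 2,
configuration/parameter problems -> 3, violated internal invariants -> 4.
"""


class WearSenseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WearSenseError):
    """A file does not conform to the expected dialect (missing column, no header...)."""


class DataQualityError(WearSenseError):
    """A file parses but its content is unusable (non-monotone time, excess jitter...)."""


class ParameterError(WearSenseError, ValueError):
    """A parameter value is outside its valid domain."""


class InvariantError(WearSenseError):
    """An internal consistency check failed; indicates a bug, not bad input."""
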