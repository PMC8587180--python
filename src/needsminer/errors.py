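"""Exception hierarchy shared across the package.

Distinguishing parse errors (malformed input files) from validation errors
(well-formed but inconsistent data) lets the CLI map them to distinct exit
codes and lets callers recover selectively.
"""


class NeedsminerError(Exception):
    """Base class for all package errors."""


class ParseError(NeedsminerError):
    """A file could not be parsed; the message names the offending row."""


class ValidationError(NeedsminerError):
    """Parsed data violates a domain invariant (unknown code, label cap, ...)."""
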