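"""Exception hierarchy.

Exit-code mapping used by the CLI: runtime failures exit 1, input schema or
validation failures exit 2.
"""


class PoisonscanError(Exception):
    """Base class for all package errors."""


class ValidationError(PoisonscanError, ValueError):
    """A value violates a documented precondition or invariant."""


class ParseError(ValidationError):
    """Malformed textual input; the message names the offending token/line."""


class ConfigurationError(PoisonscanError, ValueError):
    """Unknown dialect, unknown config key, or inconsistent configuration."""


class GenerationError(PoisonscanError, RuntimeError):
    """Synthetic-data generation hit an infeasible configuration."""
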