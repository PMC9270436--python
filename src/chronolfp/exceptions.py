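"""Exception hierarchy for chronolfp."""


class ChronoLfpError(Exception):
    """Base class for all chronolfp errors."""


class ConfigError(ChronoLfpError, ValueError):
    """An invalid configuration field or combination of fields."""


class ValidationError(ChronoLfpError, ValueError):
    """Data that violates a container invariant (order, sign, length)."""


class ParseError(ChronoLfpError, ValueError):
    """A file that does not conform to the documented schema."""


class AnalysisError(ChronoLfpError, RuntimeError):
    """An analysis stage that cannot proceed on the given input."""
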