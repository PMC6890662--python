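"""Exception types shared across the package."""


class BasecompError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BasecompError, ValueError):
    """A file could not be parsed; the message names the offending row/column."""


class ValidationError(BasecompError, ValueError):
    """An input violates a documented invariant."""


class DegenerateInputError(BasecompError, ValueError):
    """An input is structurally valid but makes the requested statistic undefined."""
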