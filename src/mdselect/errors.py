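"""Exception hierarchy."""


class MDSelectError(Exception):
    """Base class for package errors."""


class ParseError(MDSelectError):
    """Malformed input file."""


class ConfigurationError(MDSelectError):
    """Inconsistent or incomplete run configuration."""


class ValidationError(MDSelectError):
    """Data violates a structural invariant."""
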