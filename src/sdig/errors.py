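"""Exception hierarchy for the sdig package."""


class SdigError(Exception):
    """Base class for all errors raised by sdig."""


class FormatError(SdigError):
    """A file does not follow the expected tabular dialect."""


class ValidationError(SdigError):
    """Parsed data violates a domain invariant (labels, signs, pairing)."""


class DegenerateInputError(SdigError):
    """Input is structurally valid but the requested quantity is undefined
    (e.g. an all-zero expression vector, or two zero-variance groups)."""


class ConfigError(SdigError):
    """A pipeline or dataset configuration is incomplete or inconsistent."""
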