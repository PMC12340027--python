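"""Exception types shared across the package."""


class ToneChangeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ToneChangeError, ValueError):
    """An experiment configuration violates its invariants."""


class DomainError(ToneChangeError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class StructuralError(ToneChangeError, ValueError):
    """Input has the wrong shape for the operation (e.g. odd-length trial)."""
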