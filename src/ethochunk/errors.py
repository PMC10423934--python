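"""Exception types shared across the package."""


class EthochunkError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EthochunkError, ValueError):
    """A domain object violates one of its invariants."""


class ParseError(EthochunkError, ValueError):
    """A file does not conform to its documented schema."""
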