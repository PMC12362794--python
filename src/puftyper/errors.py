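"""Exception types shared across the pipeline."""


class PufTyperError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PufTyperError):
    """Invalid locus, pattern or run configuration."""


class EmptyProfileError(PufTyperError):
    """A profile with zero indel reads cannot be used downstream."""


class ComplexIndelError(PufTyperError):
    """The read differs from the reference by more than one contiguous indel."""
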