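"""Exception hierarchy.

All package-specific failures derive from :class:`SplicevoError` so callers
(and the CLI) can distinguish user-facing input problems from genuine bugs.
"""


class SplicevoError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(SplicevoError):
    """A gene model or isoform violates a structural invariant."""


class RangeError(SplicevoError):
    """A genomic coordinate falls outside its sequence."""


class ConfigurationError(SplicevoError):
    """A required configuration value is missing or inconsistent."""


class InputError(SplicevoError):
    """An input file or in-memory argument is malformed."""


class AmbiguousProductError(SplicevoError):
    """A PCR primer matches more than one site in a single mRNA."""


class NonStopWarning(UserWarning):
    """Translation ran off the end of the mRNA without hitting a stop codon."""
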