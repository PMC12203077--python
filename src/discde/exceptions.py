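"""Exception hierarchy.

The CLI maps these onto distinct exit codes (I/O = 2, validation = 3,
numerical = 4); library users can catch :class:`DiscError` to trap anything
raised by this package.
"""


class DiscError(Exception):
    """Base class for all errors raised by discde."""


class DiscIOError(DiscError):
    """A file could not be read, parsed, or written."""


class ValidationError(DiscError):
    """Inputs violate a documented contract (shapes, IDs, ranks, ranges)."""


class NumericalError(DiscError):
    """A computation failed numerically (overflow, degenerate system)."""
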