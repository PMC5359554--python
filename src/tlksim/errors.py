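"""Exception types shared across the package."""


class TlksimError(Exception):
    """Base class for all package errors."""


class ValidationError(TlksimError, ValueError):
    """An input file, table or parameter set violates its contract."""


class RangeError(TlksimError, ValueError):
    """A query falls outside the tabulated/configured domain (no extrapolation)."""
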