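"""Exception hierarchy."""


class StrokewaveError(Exception):
    """Base class for all package errors."""


class DataError(StrokewaveError):
    """Malformed or inconsistent input data."""


class NoStrokesError(StrokewaveError):
    """Fewer than two drive starts detected; nothing to segment."""
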