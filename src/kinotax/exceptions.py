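"""Exception hierarchy shared across the package."""


class KinotaxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KinotaxError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(KinotaxError, ValueError):
    """An input file violates the expected tabular format."""


class DegenerateDataError(KinotaxError, ValueError):
    """Data degenerate for the requested operation (constant column, too few values)."""


class LookupMissingError(KinotaxError, KeyError):
    """A referenced id (sample, cell line, kinase) is absent from its table."""
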