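"""Exception types shared across the package."""


class DysbioError(Exception):
    """Base class for all package-specific errors."""


class ProfileParseError(DysbioError):
    """A profile file could not be parsed (malformed row or cell)."""


class EmptyTableError(DysbioError):
    """A table required to be non-empty had no usable rows."""


class AlignmentError(DysbioError):
    """Tables that must share sample identifiers do not."""


class ConfigurationError(DysbioError):
    """Invalid reference assets or parameter configuration."""
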