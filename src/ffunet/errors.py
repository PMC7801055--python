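"""Exception types shared across the package."""


class FFUNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(FFUNetError, ValueError):
    """A configuration value violates its documented invariant."""


class DegenerateInputError(FFUNetError, ValueError):
    """Input is valid in shape but degenerate in content (e.g. constant image)."""


class ShapeError(FFUNetError, ValueError):
    """Array shapes are incompatible with the requested operation."""
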