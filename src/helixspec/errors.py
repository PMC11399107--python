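"""Exception hierarchy shared across the package."""


class HelixspecError(Exception):
    """Base class for all package errors."""


class FormatError(HelixspecError):
    """The input file could not be parsed under the named standard."""


class InputError(HelixspecError):
    """The input parsed but does not describe a usable protein–DNA complex."""


class AmbiguityError(InputError):
    """More than one disconnected DNA duplex was found."""


class GeometryError(HelixspecError):
    """Degenerate geometry (collinear anchors, missing neighbors)."""


class ConfigError(HelixspecError):
    """Invalid or inconsistent configuration."""
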