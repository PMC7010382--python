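"""Exception hierarchy for wrdmd."""


class WRDMDError(Exception):
    """Base class for all wrdmd errors."""


class InvalidInputError(WRDMDError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(WRDMDError, ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero frames)."""


class InvalidConfigError(WRDMDError, ValueError):
    """A configuration object is internally inconsistent."""


class FormatError(WRDMDError, IOError):
    """A file could not be read or does not match the declared format."""
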