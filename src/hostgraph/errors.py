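"""Exception types shared across the package."""


class HostGraphError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HostGraphError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(HostGraphError, ValueError):
    """An input file does not conform to its declared format."""
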