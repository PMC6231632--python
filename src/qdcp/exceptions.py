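"""Exception types raised by the qdcp package."""


class QDCPError(Exception):
    """Base class for qdcp errors."""


class InvalidInputError(QDCPError, ValueError):
    """An argument violates an operation's preconditions."""


class EmptyValidRegionError(QDCPError, ValueError):
    """No pixel has a complete neighborhood inside the image."""


class OutOfBoundsError(QDCPError, ValueError):
    """A sample point lies outside the grid of pixel centers."""


class FormatError(QDCPError, ValueError):
    """A serialized file does not match the expected layout."""
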