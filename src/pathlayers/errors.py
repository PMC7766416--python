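"""Exception hierarchy.

Every error raised by the package derives from :class:`PathlayersError`,
so callers (and the CLI) can catch one base class.
"""


class PathlayersError(Exception):
    """Base class for all pathlayers errors."""


class InputError(PathlayersError):
    """A required input file is missing or unreadable."""


class FormatError(PathlayersError):
    """A file exists but does not conform to the expected dialect."""


class UnsupportedLevelError(FormatError):
    """An OWL file whose namespace is neither BioPAX Level 2 nor Level 3."""


class UnknownPathwayError(PathlayersError):
    """A pathway id that does not name a pathway instance."""


class ArgumentError(PathlayersError):
    """An invalid argument value (bad level, bad relation type, bad undo count...)."""


class DuplicateLayerError(PathlayersError):
    """Layer name already present (case-insensitive)."""


class UnknownLayerError(PathlayersError):
    """Layer name not present in the graph."""


class DuplicateNodeError(PathlayersError):
    """Node name already present in the graph."""


class UnknownNodeError(PathlayersError):
    """Node name not present in the graph."""


class UnknownEdgeError(PathlayersError):
    """No edge matches the requested endpoints/key."""


class NetworkDisabledError(PathlayersError):
    """A network operation was requested without the explicit opt-in flag."""
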