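"""Exception hierarchy shared across the package."""


class ChromatrackError(Exception):
    """Base class for all package errors."""


class InputError(ChromatrackError):
    """Unreadable, empty or otherwise unusable input."""


class FormatError(ChromatrackError):
    """Input exists but violates a format contract (e.g. unequal frame sizes)."""


class ConfigError(ChromatrackError):
    """Invalid configuration values."""


class LookupError_(ChromatrackError):
    """Unknown track id or (track, frame) cell."""


class SpotOccludedError(ChromatrackError):
    """Ground-truth query for a frame in which the spot is not drawn."""
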