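"""Exception hierarchy for gigaslide.

All errors raised deliberately by the toolkit derive from :class:`GigaslideError`
so callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class GigaslideError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GigaslideError):
    """The input file is not a readable TIFF/BigTIFF container."""


class UnsupportedCodecError(GigaslideError):
    """A plane uses a compression scheme the toolkit cannot decode."""


class BoundsError(GigaslideError):
    """A tile index or pixel region lies outside the plane."""


class NotTiledError(GigaslideError):
    """A tile-level operation was requested on a stripped plane."""


class ConfigurationError(GigaslideError):
    """A parameter combination is invalid (bad overlap, threshold, format token...)."""


class BudgetError(GigaslideError):
    """The RAM budget cannot be satisfied by any mosaic grid."""


class SelectionError(GigaslideError):
    """A plane filter selected no planes."""


class MetadataAbsent:
    """Sentinel: a plane description carries no magnification/focus keys.

    Deliberately not an exception — unlabeled planes are legal, callers
    treat them as such.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "METADATA_ABSENT"

    def __bool__(self) -> bool:
        return False


METADATA_ABSENT = MetadataAbsent()
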