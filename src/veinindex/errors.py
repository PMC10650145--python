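"""Exception hierarchy for veinindex."""


class VeinIndexError(Exception):
    """Base class for all veinindex errors."""


class FormatError(VeinIndexError):
    """A file or in-memory container violates the expected format."""


class WavelengthRangeError(VeinIndexError):
    """A requested wavelength falls outside the cube's (extended) axis."""


class MaskError(VeinIndexError):
    """A vessel mask is unusable (empty, mismatched, or ambiguous)."""


class ContrastError(VeinIndexError):
    """Contrast is undefined or no stripes were detected."""


class SearchError(VeinIndexError):
    """The candidate search cannot proceed (empty stream, bad config)."""


class ConfigError(VeinIndexError):
    """A run configuration is invalid or incomplete."""
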