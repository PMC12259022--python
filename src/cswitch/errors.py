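"""Exception types shared across the package."""


class CswitchError(Exception):
    """Base class for all package-specific errors."""


class BedFormatError(CswitchError):
    """A BED/bedGraph line failed to parse or violated an invariant."""


class SizingError(CswitchError):
    """A synthetic layout does not fit the requested genome."""


class TrackStateError(CswitchError):
    """A coverage-track operation was applied in an invalid state
    (e.g. double RPM normalization, mismatched assemblies)."""
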