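"""Exception types shared across the package."""


class DFCError(Exception):
    """Base class for all package errors."""


class ParcellationError(DFCError):
    """Invalid parcellation definition (duplicate names, bad region count)."""


class DimensionError(DFCError):
    """Array shape or length does not match the expected index space."""


class BandError(DFCError):
    """Frequency band invalid for the recording's sampling rate."""


class WindowError(DFCError):
    """Analysis window or epoch length incompatible with the recording."""


class MontageError(DFCError):
    """Electrode-to-region assignment missing, duplicated, or inconsistent."""


class AlignmentError(DFCError):
    """Subject sets or feature spaces of two collections do not match."""


class InsufficientDataError(DFCError):
    """Too few epochs, samples, or subjects for the requested computation."""
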