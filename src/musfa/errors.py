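"""Exception hierarchy shared across the package."""


class MusfaError(Exception):
    """Base class for all package errors."""


class InputError(MusfaError):
    """An input file is missing or unreadable."""


class UnsupportedFormatError(InputError):
    """The file format is recognised but not supported (e.g. multi-frame DICOM)."""


class ValidationError(MusfaError, ValueError):
    """An input value violates a documented invariant."""


class ConfigurationError(MusfaError, ValueError):
    """A configuration value is inconsistent (e.g. kernel larger than FFT pad)."""


class ROITooSmallError(MusfaError):
    """No analysis kernel fits fully inside the region of interest."""


class CalibrationError(MusfaError):
    """Requested synthetic cohort targets are infeasible for the generator."""


class InsufficientSampleError(MusfaError, ValueError):
    """Too few observations for the requested statistical procedure."""
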