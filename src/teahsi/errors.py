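"""Exception hierarchy shared across the pipeline."""


class TeaHsiError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(TeaHsiError, ValueError):
    """A configuration value is outside its admissible range."""


class DimensionError(TeaHsiError, ValueError):
    """Array shapes or variable counts do not agree."""


class DegenerateReferenceError(TeaHsiError, ValueError):
    """White and dark reference coincide at some band; reflectance undefined."""


class EmptyRoiError(TeaHsiError, ValueError):
    """Threshold masking left no foreground pixel."""


class FormatError(TeaHsiError, ValueError):
    """A cube file is malformed (header field, interleave, or binary size)."""


class InvalidLVError(TeaHsiError, ValueError):
    """Requested latent-variable count outside [1, min(n-1, p)]."""


class DegenerateTargetError(TeaHsiError, ValueError):
    """Target vector has zero variance; centering/correlation undefined."""


class WavelengthAlignmentError(TeaHsiError, ValueError):
    """Cube wavelength axis does not cover the model's training wavelengths."""


class TooFewSamplesError(TeaHsiError, ValueError):
    """Not enough samples to form a calibration/prediction split."""
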