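"""Exception hierarchy for filmdose.

Readers and fitters reject rather than coerce: every contract violation maps
to a distinct exception type so callers (and the CLI) can report precisely.
"""


class FilmdoseError(Exception):
    """Base class for all filmdose errors."""


class DomainError(FilmdoseError):
    """A dose lies outside the curve's validity domain."""


class SingularityError(FilmdoseError):
    """A dose coincides with the pole of the rational response function."""


class ResponseRangeError(FilmdoseError):
    """A response lies outside the interval achievable on the dose domain."""


class InsufficientDataError(FilmdoseError):
    """Too few distinct calibration doses to determine the curve."""


class FitRejectedError(FilmdoseError):
    """The fitted curve violates a curve invariant (pole in domain, non-monotone)."""


class DegenerateReferencesError(FilmdoseError):
    """The two reference readings cannot determine the rescaling (N1 == N2)."""


class RescaleRejectedError(FilmdoseError):
    """The rescaled curve violates a curve invariant."""


class TimingValidationError(FilmdoseError):
    """Invalid exposure-window or delay input to the timing check."""


class InvalidPixelError(FilmdoseError):
    """A pixel triplet cannot be solved (e.g. all channels zero)."""


class GeometryError(FilmdoseError):
    """ROI or dose-map geometry violation (out of bounds, empty overlap...)."""


class FormatError(FilmdoseError):
    """Malformed external file (TIFF depth, dose-plane header, config...)."""


class MetadataError(FormatError):
    """Required file metadata (e.g. TIFF resolution) absent with no fallback."""


class NormalizationError(FilmdoseError):
    """Gamma normalization dose is zero or undefined."""


class EmptyEvaluationError(FilmdoseError):
    """No pixels above the low-dose threshold to evaluate."""
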