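"""Exception hierarchy shared across the package."""


class MammoError(Exception):
    """Base class for all package-specific errors."""


class InfoParseError(MammoError):
    """Malformed annotation file line (carries the 1-based line number)."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class PgmFormatError(MammoError):
    """File is not a supported PGM (P2/P5, maxval <= 255)."""


class ParameterError(MammoError):
    """Invalid parameter value passed to an operation."""


class EmptyMaskError(MammoError):
    """No pixel above the breast-mask threshold."""


class DegenerateRoiError(MammoError):
    """A window is entirely dark after non-breast cropping."""


class SizeError(MammoError):
    """Image too small for the requested window."""


class SamplingError(MammoError):
    """No admissible random center found within the retry budget."""


class SpecError(MammoError):
    """Invalid or inconsistent model specification."""


class DependencyError(MammoError):
    """A required external resource (e.g. pretrained weights) is unavailable."""


class DataError(MammoError):
    """Invalid or inconsistent data passed to training/evaluation."""


class TrainingError(MammoError):
    """Training diverged (non-finite loss)."""


class UndefinedCurveError(MammoError):
    """ROC/PR curves are undefined for single-class truth."""
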