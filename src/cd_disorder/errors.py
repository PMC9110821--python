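"""Exception hierarchy.

Every error raised by the package derives from :class:`CDDisorderError`, so
callers can catch one base class. The subclasses separate the failure modes the
API contracts distinguish: malformed files, invalid spectrum content, wavelength
coverage gaps, bad manifests, degenerate numerical input, unusable training
sets, and queries no recommended wavelength triplet can serve.
"""


class CDDisorderError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(CDDisorderError):
    """A spectrum file row could not be parsed; carries the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where += f" in {path}"
        if line is not None:
            where += f" at line {line}"
        super().__init__(message + where)


class SpectrumContentError(CDDisorderError):
    """Parsed data violate a spectrum invariant (duplicates, too few points...)."""


class CoverageError(CDDisorderError):
    """A wavelength was requested outside a spectrum's measured range."""


class ManifestError(CDDisorderError):
    """A reference-set manifest is malformed (bad label, duplicate id...)."""


class DegenerateInputError(CDDisorderError):
    """Numerically degenerate input, e.g. a zero vector under the cosine metric."""


class TrainingError(CDDisorderError):
    """The training set cannot support fitting (single class, too small)."""


class InsufficientDataError(CDDisorderError):
    """A coverage-filtered subset is too small for cross-validation."""


class UncoverableSpectrumError(CDDisorderError):
    """The query spectrum covers neither recommended wavelength triplet."""
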