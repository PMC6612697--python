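"""Exception hierarchy for gammaqa."""


class GammaQAError(Exception):
    """Base class for all gammaqa errors."""


class GridValidationError(GammaQAError):
    """A dose grid violates a structural invariant (spacing, finiteness, sign)."""


class PairValidationError(GammaQAError):
    """A reference/evaluated grid pair cannot be compared (e.g. no spatial overlap)."""


class NormalizationError(GammaQAError):
    """The normalization dose is degenerate (all-zero reference)."""


class EmptyMaskError(GammaQAError):
    """No reference points survive the lower dose threshold."""


class GridFormatError(GammaQAError):
    """A dose-grid TSV file is malformed."""


class DicomImportError(GammaQAError):
    """A DICOM object cannot be interpreted as a planar RT Dose grid."""


class SearchError(GammaQAError):
    """Invalid inverse-search parameters."""
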