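"""Exception hierarchy.

Every error raised by the package derives from :class:`CytoharmError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class CytoharmError(Exception):
    """Base class for all package errors."""


# --- FCS / LMD I/O -----------------------------------------------------------

class FCSError(CytoharmError):
    """Base class for FCS file problems."""


class FCSFormatError(FCSError):
    """The file does not start with a valid FCS header or is structurally broken."""


class FCSMetadataError(FCSError):
    """A required keyword ($PAR, $TOT, $PnN, ...) is missing or unparseable."""


class EmptyFCSError(FCSError):
    """The file parsed but contains zero events."""


class ChannelMappingError(CytoharmError):
    """One or more detector names could not be mapped to canonical marker names."""


class AmbiguousDateError(FCSError):
    """$DATE cannot be parsed unambiguously; dates are never guessed."""


# --- bead QC / normalization -------------------------------------------------

class PeakDetectionError(CytoharmError):
    """Fewer than the expected number of bead peaks could be resolved."""


class AffineFitError(CytoharmError):
    """The per-channel affine fit is invalid (alpha <= 0 or poor R^2)."""


# --- compensation ------------------------------------------------------------

class CompensationError(CytoharmError):
    """Spillover matrix invalid, singular or ill-conditioned."""


# --- gating ------------------------------------------------------------------

class GatingError(CytoharmError):
    """Gating could not be performed (missing marker, missing threshold, ...)."""


class ThresholdError(GatingError):
    """A marker used in a population definition has no configured threshold."""


# --- corrections -------------------------------------------------------------

class BatchAssignmentError(CytoharmError):
    """An acquisition date falls outside every configured lot period."""


class CorrectionError(CytoharmError):
    """MFI correction failed (empty batch, non-positive median, unmapped row)."""


class PipelineOrderError(CytoharmError):
    """A pipeline stage was invoked out of its fixed order."""
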