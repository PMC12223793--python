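"""Exception hierarchy.

``ScanRejectedError`` marks data-quality conditions (catheter contact,
unusable segmentation, too few breath cycles, no pressure modulation) that
map to CLI exit code 2; everything else is a plain error (exit code 1).
"""


class AoctelError(Exception):
    """Base class for package errors."""


class ScanRejectedError(AoctelError):
    """A scan is unusable for compliance analysis (not a programming error)."""


class SheathNotDetectedError(AoctelError):
    """No bright near-axis sheath band found above threshold."""


class FoldRegionError(AoctelError):
    """A flagged fold-over run is not bounded by bottom-touching columns."""
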