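"""Exception hierarchy for masscnv.

All package-specific failures derive from :class:`MasscnvError` so callers
(and the CLI) can distinguish validation problems from genuine I/O errors.
"""


class MasscnvError(Exception):
    """Base class for all masscnv errors."""


class PanelError(MasscnvError):
    """Panel definition violates the assay schema (duplicate ids, wells
    without reference fragments, non-monotone fragment order, ...)."""


class IntensityParseError(MasscnvError):
    """An intensity table row is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UncallableSampleError(MasscnvError):
    """A sample has zero QC-passing reference fragments in every well and
    therefore cannot be normalized."""


class CalibrationError(MasscnvError):
    """Cutoff calibration failed: degenerate controls or inseparable
    control/standard TR distributions."""


class ConfigError(MasscnvError):
    """Simulation or run configuration is inconsistent with the panel."""


class BreakpointError(MasscnvError):
    """Malformed coordinate string, BED line, or insufficient reference span."""
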