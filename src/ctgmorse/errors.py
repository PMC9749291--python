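"""Exception hierarchy for the CTG pipeline."""


class CTGError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CTGError):
    """A record file is missing, garbled, or violates the expected dialect."""


class StructuralError(CTGError):
    """A record lacks a required channel or field (e.g. no FHR channel)."""


class LabelingError(CTGError):
    """A record cannot be labeled (missing or non-positive pH)."""


class EmptySignalError(CTGError):
    """A signal is empty, all-missing, or became empty during cleaning."""


class SegmentTooShortError(CTGError):
    """A cleaned signal is shorter than the requested labor-stage window."""


class ConvergenceError(CTGError):
    """Iterative spike removal failed to reach a spike-free signal."""


class SplitError(CTGError):
    """A dataset cannot be split as requested (e.g. a class with < 2 items)."""


class DatasetError(CTGError):
    """A dataset is degenerate (empty, or a class with zero members)."""


class ConfigError(CTGError):
    """A simulation or pipeline configuration is invalid or infeasible."""
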