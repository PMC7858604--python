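"""Exception hierarchy for shiftmethyl."""


class ShiftMethylError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ShiftMethylError):
    """Invalid simulation or pipeline configuration."""


class ContractError(ShiftMethylError):
    """A documented precondition of an operation was violated."""


class DesignError(ShiftMethylError):
    """The sample sheet cannot support the requested design matrix."""


class FitError(ShiftMethylError):
    """A per-probe least-squares fit is impossible (e.g. no residual df)."""


class AlignmentError(ShiftMethylError):
    """Matrix columns and sample-sheet rows do not match one-to-one."""


class FormatError(ShiftMethylError):
    """A file is syntactically invalid for its declared format."""


class SchemaError(ShiftMethylError):
    """A table is missing a required column or carries invalid values."""


class PipelineError(ShiftMethylError):
    """A pipeline stage failed; the message names the stage."""
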