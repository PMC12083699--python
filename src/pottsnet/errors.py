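"""Exception types shared across the package."""


class PottsNetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PottsNetError, ValueError):
    """An argument or configuration value is outside its valid range."""


class ContractViolation(PottsNetError, ValueError):
    """A caller broke an operation precondition (shape mismatch, non-neighbor pair, ...)."""


class CorruptStateError(PottsNetError):
    """A simulation state failed an internal consistency audit."""


class PackingError(PottsNetError):
    """Random cell placement could not find a non-overlapping configuration."""


class TrajectoryGapError(PottsNetError):
    """A trajectory is missing frames required by an operation.

    Carries the list of absent MCS values in ``missing``.
    """

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(str(m) for m in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"trajectory is missing MCS frames: {preview}{more}")


class CoverageError(PottsNetError):
    """A ground-truth trajectory does not cover the requested evaluation horizon."""


class TrainingDivergedError(PottsNetError):
    """Optimization produced a non-finite loss; carries the epoch index."""

    def __init__(self, epoch, message="non-finite loss"):
        self.epoch = epoch
        super().__init__(f"training diverged at epoch {epoch}: {message}")
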