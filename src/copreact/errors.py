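"""Exception hierarchy for the COP analysis pipeline.

Every failure mode the pipeline distinguishes gets its own class so that
callers (and the CLI) can decide per-recording whether to exclude, retry
with a different schema, or abort.
"""


class CopReactError(Exception):
    """Base class for all package errors."""


class SchemaError(CopReactError):
    """Input file does not match the declared column schema."""


class SamplingError(CopReactError):
    """Time column is non-uniform beyond tolerance, or fs is invalid."""


class QCError(CopReactError):
    """Recording fails quality control (NaNs, missing events) and is excluded."""


class UnreliableCopError(CopReactError):
    """Vertical force below the floor; COP coordinates are unreliable."""

    def __init__(self, message, sample_index=None):
        super().__init__(message)
        self.sample_index = sample_index


class FilterSpecError(CopReactError):
    """Invalid filter specification (cutoff vs Nyquist, order)."""


class SeriesLengthError(CopReactError):
    """Series too short for the requested operation."""


class EpochBoundsError(CopReactError):
    """Requested epoch window extends past the recording bounds."""


class WindowError(CopReactError):
    """Analysis or baseline window falls outside the epoch."""


class EpochStateError(CopReactError):
    """Operation requires a different baseline-correction state."""


class BalanceError(CopReactError):
    """Trial table is not a balanced 2 x 2 split-plot design."""


class DegenerateDataError(CopReactError):
    """Zero variance where the statistic requires some."""


class ConstraintError(CopReactError):
    """Logical constraint over hypotheses cannot be enumerated."""


class DomainError(CopReactError, ValueError):
    """Argument outside its mathematical domain."""


class SpacingError(CopReactError):
    """Perturbation events cannot be packed into the recording."""


class ConfigError(CopReactError):
    """Unknown or invalid pipeline configuration key."""


class ParticipantExcludedError(QCError):
    """No valid epochs survive QC for a participant/session."""
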