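"""Exception hierarchy for smrbci."""


class SmrBciError(Exception):
    """Base class for all smrbci errors."""


class InvalidArgumentError(SmrBciError, ValueError):
    """A parameter is outside its documented range."""


class MontageError(SmrBciError, KeyError):
    """A channel label is missing from a montage or recording."""


class DegenerateDataError(SmrBciError):
    """Input carries no usable information (all-zero differences, zero rank
    variance, numerically singular fit)."""


class UndefinedPVCError(SmrBciError):
    """PVC is undefined: a trial set with no hits and no misses.

    Distinct from a PVC of 0 %, which requires at least one miss.
    """


class BufferingError(SmrBciError):
    """A streaming consumer ran ahead of its producer (signal-chain underrun)."""


class SimulationError(SmrBciError):
    """Closed-loop simulation received a non-finite control value."""


class InterpolationError(SmrBciError):
    """Too few good channels remain to interpolate the flagged ones."""


class EmptyEpochsError(SmrBciError):
    """Trial rejection removed every epoch."""
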