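"""Exception hierarchy for kelpcoast.

Every error raised by the library derives from :class:`KelpcoastError` so
pipeline code can distinguish analysis failures from programming errors.
"""


class KelpcoastError(Exception):
    """Base class for all kelpcoast errors."""


class AlignmentError(KelpcoastError):
    """Sequences are ragged or otherwise not a valid alignment."""


class FormatError(KelpcoastError):
    """A file or sequence contains illegal content (bad characters, columns)."""


class MappingError(KelpcoastError):
    """A sequence record has no entry in the sample table."""


class EmptyInputError(KelpcoastError):
    """An operation received an empty alignment or population."""


class UndefinedDistanceError(KelpcoastError):
    """No comparable (both-unambiguous) sites between two sequences."""


class OrderingError(KelpcoastError):
    """Coastal positions are not monotone in the stated coastal order."""


class LabelError(KelpcoastError):
    """Distance-matrix labels do not match between inputs."""


class DegenerateTestError(KelpcoastError):
    """A statistical test cannot be run (e.g. zero-variance distance matrix)."""


class ParameterError(KelpcoastError):
    """A parameter is outside its valid range."""


class CoverageError(KelpcoastError):
    """The beach table does not cover an adjacent locality pair."""


class ConfigError(KelpcoastError):
    """A simulation or run configuration is internally inconsistent."""


class RankError(KelpcoastError):
    """The regression design matrix is rank deficient."""


class PipelineStageError(KelpcoastError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
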