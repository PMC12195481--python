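"""Exception hierarchy for the smqc pipeline.

Every error raised deliberately by the library derives from :class:`SmqcError`
so the CLI can map failure classes onto exit codes (config errors vs. data
validation vs. stage computation).
"""


class SmqcError(Exception):
    """Base class for all smqc errors."""


class ConfigError(SmqcError):
    """Invalid configuration (unknown keys, infeasible parameters, bad schema)."""


class FormatError(SmqcError):
    """A file could not be parsed as the expected format."""


class ValidationError(SmqcError):
    """Parsed data violates a peak-table invariant (negative intensity,
    duplicate coordinates, duplicate m/z columns, ...)."""


class ConsistencyError(SmqcError):
    """Result tables disagree with the peak table they describe."""


class GeometryError(SmqcError):
    """Invalid polygon (too few vertices, self-intersection)."""


class EmptyRegionError(SmqcError):
    """A region definition selects no pixel of the table."""


class UndefinedCorrelationError(SmqcError):
    """Pearson correlation is undefined because a spectrum has zero variance."""


class DegenerateInputError(SmqcError):
    """Input is degenerate for the requested computation (constant vector,
    fewer than two usable quadrats, ...)."""


class EmptyResultError(SmqcError):
    """A filtering step would remove every pixel or every ion."""


class StageError(SmqcError):
    """A pipeline stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
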