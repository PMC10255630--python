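"""Exception hierarchy for the pipeline.

Exit-code mapping for the CLI: configuration errors (2), data errors (3),
chemistry errors (4), training errors (5).
"""


class BloomscanError(Exception):
    """Base class for all package errors."""


class ConfigError(BloomscanError):
    """Invalid scenario / run configuration."""


class DataError(BloomscanError):
    """Malformed or insufficient observation data."""


class MissingFactorError(DataError):
    """A required factor is absent from a series or table."""

    def __init__(self, factor: str, where: str = ""):
        self.factor = factor
        suffix = f" in {where}" if where else ""
        super().__init__(f"required factor {factor!r} is missing{suffix}")


class ChemistryInfeasibleError(BloomscanError):
    """The carbonate system has no physical solution for the given inputs."""


class TrainingDivergedError(BloomscanError):
    """Network training produced a non-finite loss."""

    def __init__(self, message: str, iteration: int | None = None):
        self.iteration = iteration
        super().__init__(message)


class FactorOrderError(DataError):
    """Window factor layout does not match the model's expected layout."""
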