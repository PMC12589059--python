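"""Exception hierarchy shared across the pipeline."""


class DDSNError(Exception):
    """Base class for all errors raised by this package."""


class TableFormatError(DDSNError):
    """A table is structurally unusable (e.g. a required column is missing)."""


class RowFormatError(DDSNError):
    """A single data row violates a field constraint.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GraphIntegrityError(DDSNError):
    """A graph invariant is violated (e.g. vertex-set disjointness)."""


class UnknownDrugError(DDSNError, KeyError):
    """A drug identifier is not present in the graph being queried."""


class CoverageError(DDSNError):
    """A partition does not cover the node set it is evaluated against."""


class ParameterError(DDSNError, ValueError):
    """An operation received an out-of-range parameter."""


class ConfigError(DDSNError):
    """A configuration object is internally inconsistent or infeasible."""


class InconsistencyError(DDSNError):
    """Reported percentages reconstruct to counts that exceed the group size."""


class StageError(DDSNError):
    """A pipeline stage failed; names the stage for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
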