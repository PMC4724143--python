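"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: configuration errors -> 2,
data/IO errors -> 3, solver capacity errors -> 4.
"""


class ObsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ObsimError, ValueError):
    """Invalid configuration (infeasible tiling, bad parameter range, ...)."""


class DataError(ObsimError, ValueError):
    """Invalid data passed between stages (unknown ids, broken invariants)."""


class GeographyIOError(DataError):
    """A geography file failed validation; identifies file and row."""

    def __init__(self, filename: str, row: object, message: str):
        self.filename = filename
        self.row = row
        super().__init__(f"{filename} (row {row}): {message}")


class CapacityError(ObsimError, RuntimeError):
    """Instance too large for the requested exact solver mode."""


class UndefinedMetricError(ObsimError, ValueError):
    """A metric is undefined for the given input (zero denominator)."""
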