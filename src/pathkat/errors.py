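"""Exception hierarchy for pathkat."""


class PathkatError(Exception):
    """Base class for all pathkat errors."""


class VcfParseError(PathkatError):
    """A VCF record could not be parsed."""


class SchemaError(PathkatError):
    """A tabular input is missing required columns or has malformed rows."""


class ConfigError(PathkatError):
    """An invalid configuration value or inconsistent option combination."""


class CollinearityError(PathkatError):
    """The covariate design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class DegenerateFitError(PathkatError):
    """The null regression has (numerically) zero residual variance."""


class DegenerateSetError(PathkatError):
    """A variant set carries no testable genetic variation."""


class ResourceError(PathkatError):
    """A requested computation exceeds a configured resource ceiling."""
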