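"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`aircausal.cli`).
"""


class AircausalError(Exception):
    """Base class for all package errors."""


class ConfigError(AircausalError):
    """Invalid generator or run configuration."""


class SchemaError(AircausalError):
    """A cohort table violates the variable schema (names row/column)."""


class DegenerateDataError(AircausalError):
    """Data are numerically unusable for the requested statistic
    (zero variance, collinear conditioning set, too few rows)."""


class IdentifiabilityError(AircausalError):
    """No admissible adjustment set exists for the requested effect."""


class OrientationError(IdentifiabilityError):
    """An edge relevant to effect estimation is undirected in the PDAG."""


class ConstraintConflictError(AircausalError):
    """Whitelist/blacklist constraints conflict with each other or with
    orientations forced by the data."""
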