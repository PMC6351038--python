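"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: config errors 2, data errors 3,
degenerate-statistics errors 4.
"""


class MitosynError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(MitosynError):
    """Invalid configuration or arguments."""

    exit_code = 2


class DataError(MitosynError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class FormatError(DataError):
    """Missing mandatory columns or an unrecognisable table layout."""


class IntegrityError(DataError):
    """Duplicate subject identifiers or other cross-record inconsistencies."""


class ParseError(DataError):
    """A token could not be parsed in strict mode; names line and column."""


class FeatureError(DataError):
    """A feature references a locus absent from the cohort registry."""


class DegenerateTableError(MitosynError):
    """A contingency table has an empty margin or stratum."""

    exit_code = 4


class InconsistentMarginalsError(DataError):
    """Marginal counts violate inclusion-exclusion constraints."""
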