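"""Exception hierarchy shared across the package."""


class MgmtPerfError(Exception):
    """Base class for all package errors."""


class ConfigError(MgmtPerfError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ParseError(MgmtPerfError):
    """Malformed tabular input; carries row/column location where known."""

    def __init__(self, message: str, row=None, column=None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)


class ReferentialIntegrityError(MgmtPerfError):
    """A table row references an identifier absent from its parent table."""


class DomainUnscorableError(MgmtPerfError):
    """Every item in a management domain was degenerate; no score exists."""


class CollinearityError(MgmtPerfError):
    """Design matrix is rank deficient; lists the dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent columns: "
            + ", ".join(map(str, self.columns))
        )


class NumericalError(MgmtPerfError):
    """A linear-algebra step failed (e.g. singular covariance)."""


class InsufficientDataError(MgmtPerfError):
    """Too few observations for the requested computation."""


class JoinError(MgmtPerfError):
    """Identifier mismatch when joining score and panel tables."""


class BootstrapError(MgmtPerfError):
    """Bootstrap replication failed too often to report valid inference."""
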