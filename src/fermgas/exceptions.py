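"""Error types shared across fermgas modules."""


class FermgasError(Exception):
    """Base class for all fermgas errors."""


class InvalidInputError(FermgasError, ValueError):
    """A scalar or array argument violates a precondition (sign, range, shape)."""


class InvalidConfigError(FermgasError, ValueError):
    """A configuration object violates its invariants."""


class SchemaError(FermgasError, ValueError):
    """A file does not conform to the expected CSV/YAML schema.

    Carries an optional row/column locator so validation failures can be
    reported precisely.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column
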