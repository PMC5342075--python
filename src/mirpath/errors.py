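"""Exception hierarchy shared across the pipeline."""


class MirpathError(Exception):
    """Base class for all package errors."""


class ConfigError(MirpathError, ValueError):
    """Invalid generator or pipeline configuration."""


class ContractError(MirpathError, ValueError):
    """An operation was called with arguments violating its contract."""


class SchemaError(MirpathError, ValueError):
    """A file does not conform to its declared tabular dialect.

    Carries enough context (file, line, column where known) to locate
    the offending record.
    """

    def __init__(self, message, path=None, line=None, column=None):
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.path = path
        self.line = line
        self.column = column


class EstimationError(MirpathError, RuntimeError):
    """A statistical estimation step could not be completed."""
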