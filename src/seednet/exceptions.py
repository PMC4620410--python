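"""Exception hierarchy shared across the package."""


class SeedNetError(Exception):
    """Base class for all seednet errors."""


class ConfigurationError(SeedNetError, ValueError):
    """A configuration value violates an invariant; the message names the field."""


class ParseError(SeedNetError, ValueError):
    """A file could not be parsed; carries path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class ValidationError(SeedNetError, ValueError):
    """In-memory data violates a precondition or invariant."""


class DisconnectedGraphError(SeedNetError, ValueError):
    """Path-based metrics were requested on a disconnected graph."""
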