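"""Exception hierarchy shared across the package."""


class Net3dError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Net3dError):
    """Malformed input file; carries a line/row locator when available."""

    def __init__(self, message: str, line: int | None = None, locator: str | None = None):
        where = ""
        if line is not None:
            where = f" (line {line})"
        elif locator is not None:
            where = f" ({locator})"
        super().__init__(message + where)
        self.line = line
        self.locator = locator


class GraphLookupError(Net3dError, KeyError):
    """Unknown node or edge identifier."""

    def __init__(self, element_id: str):
        super().__init__(f"unknown element: {element_id!r}")
        self.element_id = element_id


class ParameterError(Net3dError, ValueError):
    """A parameter violates its documented constraint."""


class ConfigError(Net3dError):
    """Invalid run configuration (unknown scheme, duplicate labels, ...)."""


class NumericError(Net3dError):
    """Non-finite value encountered where a finite number is required."""


class SyncError(Net3dError):
    """Scene synchronization conflict; carries the offending sequence number."""

    def __init__(self, message: str, seq: int | None = None):
        if seq is not None:
            message = f"{message} (seq {seq})"
        super().__init__(message)
        self.seq = seq
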