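"""Typed exception hierarchy shared across the package."""


class DtifuseError(Exception):
    """Base class for all package errors."""


class ParseError(DtifuseError):
    """Malformed input row or file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GraphError(DtifuseError):
    """Graph-structure violations (self-loops when disallowed, invalid paths)."""


class ContractError(DtifuseError):
    """A precondition of an operation was violated by the caller."""


class FormatError(DtifuseError):
    """An agent payload deviates from its declared format contract.

    ``position`` is the 1-based index of the offending element, or None for
    arity errors.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class ConfigError(DtifuseError):
    """Invalid or inconsistent run configuration."""


class BackendError(DtifuseError):
    """A pluggable backend failed or is unavailable."""


class RetrievalError(BackendError):
    """Live search retrieval failed (network, auth, quota)."""


class InputError(DtifuseError):
    """Required input fields missing for the selected backend."""


class JoinError(DtifuseError):
    """Predictions and labels could not be matched one-to-one."""

    def __init__(self, message: str, offenders: list | None = None):
        self.offenders = offenders or []
        super().__init__(message)


class SpecError(DtifuseError):
    """A fixture specification is infeasible or self-contradictory."""


class PairError(DtifuseError):
    """A single query pair could not produce any evidence."""
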