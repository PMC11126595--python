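"""Exception hierarchy shared across the package."""


class BilinkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BilinkError):
    """An input edge list could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PartConflictError(BilinkError):
    """The same identifier appeared in both parts of a two-mode input."""


class UnknownNodeError(BilinkError, KeyError):
    """A node identifier is not present in the network."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep the message readable
        return Exception.__str__(self)


class PartError(BilinkError):
    """A node pair violates the cross-part requirement (both endpoints in one part)."""


class EmptyPartError(BilinkError):
    """A statistic is undefined because one part of the network is empty."""


class InvalidCandidateError(BilinkError):
    """A candidate pair offered for prediction is already an edge."""


class InfeasibleSplitError(BilinkError):
    """The edge set is too small to split into the requested number of folds."""


class SamplingError(BilinkError):
    """Comparison-pair sampling is impossible (e.g. no true non-edge exists)."""


class ConfigError(BilinkError):
    """A generator or run configuration is invalid."""
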