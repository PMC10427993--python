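"""Exception taxonomy shared across the pipeline.

Exit codes mirror the CLI contract: 2 config, 3 data/format, 4 inference
diagnostics. Library callers catch the classes; the CLI maps them to codes.
"""


class NeohybridError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NeohybridError):
    """Invalid or infeasible run/generator configuration."""

    exit_code = 2


class FormatError(NeohybridError):
    """A file could not be parsed as the expected format."""

    exit_code = 3


class ValidationError(NeohybridError):
    """Parsed content violates a declared invariant."""

    exit_code = 3


class DataError(NeohybridError):
    """Well-formed input that the requested analysis cannot use."""

    exit_code = 3


class DomainError(NeohybridError, ValueError):
    """Scalar argument outside the mathematical domain of an estimator."""

    exit_code = 3


class DiagnosticsError(NeohybridError):
    """MCMC convergence diagnostics failed the post-hoc thresholds."""

    exit_code = 4
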