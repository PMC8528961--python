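"""Typed exceptions raised across the package.

Every validation failure raises one of these instead of silently coercing,
so callers can distinguish malformed files from genuinely degenerate data.
"""


class GraftageError(Exception):
    """Base class for all package errors."""


class BetaRangeError(GraftageError, ValueError):
    """A methylation value lies outside [0, 1]."""


class FormatError(GraftageError, ValueError):
    """A file violates its format contract (duplicates, bad field counts...)."""


class SchemaError(GraftageError, ValueError):
    """A table or JSON document is missing required columns/keys."""


class ValidationError(GraftageError, ValueError):
    """Values parsed fine but violate a domain invariant."""


class CoordinateError(GraftageError, ValueError):
    """Genomic interval with start >= end or negative coordinates."""


class ConfigError(GraftageError, ValueError):
    """Inconsistent simulation configuration."""


class DegenerateDataError(GraftageError, ValueError):
    """Input with no usable variation (constant response, zero variance...)."""


class CoverageError(GraftageError, ValueError):
    """Too few clock CpGs present in a beta matrix to predict age."""

    def __init__(self, msg: str, missing: list[str] | None = None):
        super().__init__(msg)
        self.missing = missing or []


class CollinearityError(GraftageError, ValueError):
    """Rank-deficient design matrix; names the aliased columns."""

    def __init__(self, msg: str, aliased: list[str] | None = None):
        super().__init__(msg)
        self.aliased = aliased or []


class PairingError(GraftageError, ValueError):
    """Paired test requested but pair identifiers do not match up."""


class ConvergenceError(GraftageError, RuntimeError):
    """Likelihood maximization failed (e.g. monotone Cox likelihood)."""

    def __init__(self, msg: str, direction: float | None = None):
        super().__init__(msg)
        #: sign of the diverging coefficient, when known
        self.direction = direction
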