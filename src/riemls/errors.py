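"""Typed exceptions raised across the package."""


class RiemlsError(Exception):
    """Base class for all package errors."""


class StructuralError(RiemlsError):
    """Malformed L-string or rule output (unbalanced brackets, bad fragment)."""


class DepthError(RiemlsError):
    """Interpretation-rule recursion exceeded the configured depth limit."""


class QueryError(RiemlsError):
    """A query module was evaluated outside an active space context."""


class SpaceError(RiemlsError):
    """Invalid space construction parameters or unknown space kind."""


class MetricError(SpaceError):
    """A user metric failed validation (non-symmetric or not positive definite)."""


class DegeneratePointError(SpaceError):
    """Evaluation requested at (or within eps of) a degenerate coordinate locus."""


class BoundaryError(RiemlsError):
    """A trajectory left a non-periodic parameter domain.

    Carries ``last_valid`` — the last in-domain sample as (u, v) arrays.
    """

    def __init__(self, msg, last_valid=None):
        super().__init__(msg)
        self.last_valid = last_valid


class ConvergenceError(RiemlsError):
    """A boundary-value solver failed to reach its tolerance.

    Carries ``best_mismatch`` (smallest endpoint mismatch seen) and optionally
    ``history`` (residual norms per iteration).
    """

    def __init__(self, msg, best_mismatch=None, history=None):
        super().__init__(msg)
        self.best_mismatch = best_mismatch
        self.history = history or []


class ModeError(RiemlsError):
    """A turtle command was used in an incompatible mode (direct/indirect/euclidean)."""


class StackError(RiemlsError):
    """Pop on an empty turtle stack."""


class CacheError(RiemlsError):
    """A static-segment cache key was reused with inconsistent arguments."""


class ConfigError(RiemlsError):
    """A run configuration failed schema validation."""
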