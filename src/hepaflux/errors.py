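"""Exception hierarchy for hepaflux."""


class HepafluxError(Exception):
    """Base class for all package-specific errors."""


class NetworkParseError(HepafluxError, ValueError):
    """Malformed network file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AtomBalanceError(HepafluxError, ValueError):
    """A reaction violates atom conservation or leaves a product atom unmapped."""


class NetworkValidationError(HepafluxError, ValueError):
    """Network-level invariant violated (roles, connectivity, null space)."""


class InfeasibleConstraintError(HepafluxError, ValueError):
    """Fixed flux constraints are inconsistent with the steady-state balances."""


class IdentifiabilityError(HepafluxError, RuntimeError):
    """An EMU balance system is singular (flux-disconnected pool)."""


class CorrectionError(HepafluxError, ValueError):
    """Natural-abundance correction produced physically impossible fractions."""


class UsageError(HepafluxError, ValueError):
    """An operation was called with arguments outside its contract."""


class OptimizationError(HepafluxError, RuntimeError):
    """No restart of the flux regression converged."""
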