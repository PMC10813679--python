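"""Exception hierarchy shared across the package."""


class AlignerSimError(Exception):
    """Base class for all package errors."""


class ValidationError(AlignerSimError, ValueError):
    """Invalid input data or configuration."""


class StagingError(AlignerSimError, ValueError):
    """Inconsistent staging plan request."""


class FitError(AlignerSimError, ValueError):
    """Curve or frame fitting failed (degenerate geometry)."""


class ExtrapolationError(AlignerSimError, ValueError):
    """Query point outside the fitted curve domain."""


class DegenerateRegionError(AlignerSimError, ValueError):
    """Interdental deformation region collapsed (overlapping crowns)."""


class RegistrationError(AlignerSimError, ValueError):
    """Rigid best-fit registration not possible."""


class DomainError(AlignerSimError, ValueError):
    """Argument outside a formula's valid domain."""


class SolverError(AlignerSimError, RuntimeError):
    """Equilibrium solve failed to converge."""


class DiagnosticsUnavailableError(AlignerSimError, RuntimeError):
    """A diagnostic quantity was requested but its computation is disabled."""


class ReportMismatchError(AlignerSimError, ValueError):
    """Trace and configuration do not belong together (hash mismatch)."""
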