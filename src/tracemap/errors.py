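"""Exception types raised across the pipeline."""


class TracemapError(Exception):
    """Base class for all package errors."""


class ConfigError(TracemapError):
    """Invalid or degenerate configuration."""


class ContractViolation(TracemapError):
    """An operation was called in a way its contract forbids."""


class MissingTransform(TracemapError):
    """A transform chain has no entry for the requested section."""


class MappingDiverged(TracemapError):
    """Point mapping produced non-finite coordinates."""


class InversionFailed(TracemapError):
    """Displacement-field inversion did not converge."""

    def __init__(self, residual: float, tol: float, iterations: int):
        self.residual = residual
        self.tol = tol
        self.iterations = iterations
        super().__init__(
            f"field inversion residual {residual:.3g} above tolerance {tol:.3g} "
            f"after {iterations} iterations"
        )


class MetricUndefined(TracemapError):
    """A similarity metric has no valid support (e.g. no non-constant windows)."""


class LandmarkMismatch(TracemapError):
    """Landmark label inventories differ between the two point sets."""


class SolverFailed(TracemapError):
    """An iterative solver failed to reach its residual tolerance."""


class InsufficientData(TracemapError):
    """Not enough paired observations for the requested statistic."""
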