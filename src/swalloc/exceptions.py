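"""Exception hierarchy for design, feasibility and numerical failures."""


class SwallocError(Exception):
    """Base class for all package-specific errors."""


class DesignError(SwallocError, ValueError):
    """Invalid design parameters (J, rho, r, sigma2, indexing)."""


class InfeasibleBoundsError(SwallocError, ValueError):
    """Allocation box bounds incompatible with the simplex constraint."""


class SingularInformationError(SwallocError, ValueError):
    """The total information matrix is singular (treatment effect inestimable)."""


class EstimabilityError(SwallocError, ValueError):
    """Observed data cannot identify all fixed-effect parameters."""


class OptimizationError(SwallocError, RuntimeError):
    """No optimization start converged to a feasible solution."""
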