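"""Attrition-weighted information matrices and the GLS treatment-effect variance.

With known residual covariance ``V``, the generalized-least-squares
estimator of the fixed effects has covariance

    cov(theta_hat) = ( sum_j sum_t  n_jt  X_jt' V_t^-1 X_jt )^-1,

where ``X_jt`` and ``V_t`` are the leading-``t`` truncations of the
sequence-``j`` design matrix and of ``V``, and ``n_jt`` is the number of
sequence-``j`` individuals whose last observation is at period ``t``.
Working per unit total sample size (``n_jt = p_j * w_t`` with attrition
weights ``w``), the per-sequence information

    A_j = sum_t  w_t  X_jt' V_t^-1 X_jt

is precomputed once, and an allocation ``p`` yields
``var(gamma_hat) = [ (sum_j p_j A_j)^-1 ]`` at the treatment (last)
diagonal entry.  Variance at total sample size ``n`` is this divided by
``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .covariance import attrition_weights, exp_decay_covariance, truncate_covariance
from .design import DesignSpec, build_design_matrix, truncate_design
from .exceptions import DesignError, InfeasibleBoundsError, SingularInformationError

__all__ = [
    "Allocation",
    "sequence_information",
    "information_matrices",
    "total_information",
    "treatment_variance",
]

#: condition number above which the information solve is flagged as ill-conditioned
_COND_WARN = 1e12
#: condition number at which the information matrix is treated as numerically singular
_COND_SINGULAR = 1e15


def _as_bound(value, J: int, default: float) -> np.ndarray:
    if value is None:
        return np.full(J, default)
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(J, arr[0])
    if arr.size != J:
        raise InfeasibleBoundsError(f"bounds must be scalar or length {J}, got length {arr.size}")
    return arr


def check_bounds(lower, upper, J: int) -> tuple[np.ndarray, np.ndarray]:
    """Validate per-sequence box bounds; returns (lower, upper) arrays.

    Feasibility requires elementwise lower <= upper, sum(lower) <= 1 and
    sum(upper) >= 1 so the simplex constraint can still be met.
    """
    lo = _as_bound(lower, J, 0.0)
    hi = _as_bound(upper, J, 1.0)
    if np.any(lo < 0) or np.any(hi > 1) or np.any(lo > hi):
        raise InfeasibleBoundsError(f"bounds must satisfy 0 <= lower <= upper <= 1, got {lo}, {hi}")
    if lo.sum() > 1.0 + 1e-12 or hi.sum() < 1.0 - 1e-12:
        raise InfeasibleBoundsError(
            f"infeasible bounds: sum(lower)={lo.sum():.4f} must be <= 1 <= sum(upper)={hi.sum():.4f}"
        )
    return lo, hi


@dataclass(frozen=True)
class Allocation:
    """A proportion vector over the J sequences, optionally box-bounded.

    ``proportions`` must lie on the simplex (non-negative, summing to 1);
    when bounds are given they must be feasible and contain ``proportions``.
    """

    proportions: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        object.__setattr__(self, "proportions", p)
        if p.ndim != 1 or p.size < 2:
            raise DesignError("allocation must be a vector of at least 2 proportions")
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise DesignError(f"proportions must be non-negative and sum to 1, got {p}")
        if self.lower is not None or self.upper is not None:
            lo, hi = check_bounds(self.lower, self.upper, p.size)
            object.__setattr__(self, "lower", lo)
            object.__setattr__(self, "upper", hi)
            if np.any(p < lo - 1e-8) or np.any(p > hi + 1e-8):
                raise InfeasibleBoundsError(f"proportions {p} violate bounds [{lo}, {hi}]")

    @property
    def J(self) -> int:
        return self.proportions.size

    @classmethod
    def uniform(cls, J: int) -> "Allocation":
        return cls(np.full(J, 1.0 / J))


def sequence_information(j: int, spec: DesignSpec) -> np.ndarray:
    """Per-individual expected information A_j of one sequence-``j`` member,

    A_j = sum_{t=1}^{T} w_t X_jt' V_t^-1 X_jt,

    with w the attrition-weight distribution.  For r = 0 this is exactly
    X_j' V^-1 X_j.  Symmetric positive semidefinite, (T+1) x (T+1).
    """
    V = exp_decay_covariance(spec)
    X = build_design_matrix(j, spec)
    w = attrition_weights(spec)
    K = spec.n_params
    A = np.zeros((K, K))
    for t in range(1, spec.T + 1):
        if w[t - 1] == 0.0:
            continue
        Xt = truncate_design(X, t)
        Vt = truncate_covariance(V, t)
        A += w[t - 1] * (Xt.T @ np.linalg.solve(Vt, Xt))
    return 0.5 * (A + A.T)  # symmetrize against round-off


def information_matrices(spec: DesignSpec) -> np.ndarray:
    """Stacked per-sequence information matrices, shape (J, T+1, T+1)."""
    return np.stack([sequence_information(j, spec) for j in range(1, spec.J + 1)])


def total_information(p, spec: DesignSpec, A: np.ndarray | None = None) -> np.ndarray:
    """Per-unit-sample-size information sum_j p_j A_j for allocation p."""
    p = p.proportions if isinstance(p, Allocation) else np.asarray(p, dtype=float)
    if p.size != spec.J:
        raise DesignError(f"allocation has {p.size} entries, design has J={spec.J}")
    if A is None:
        A = information_matrices(spec)
    return np.tensordot(p, A, axes=1)


def treatment_variance(
    p, spec: DesignSpec, n_total: float | None = None, A: np.ndarray | None = None
) -> float:
    """var(gamma_hat) for allocation ``p``, per unit total sample size.

    The treatment effect is the last fixed-effect parameter; its variance
    is the corresponding diagonal entry of the inverse total information.
    Pass ``n_total`` to get the variance at an absolute sample size
    (information is additive in individuals, so the variance scales as
    1/n).  ``A`` may carry precomputed per-sequence information matrices
    to avoid rebuilding them in inner loops.
    """
    M = total_information(p, spec, A=A)
    K = M.shape[0]
    e = np.zeros(K)
    e[-1] = 1.0
    try:
        cond = np.linalg.cond(M)
        if not np.isfinite(cond) or cond > _COND_SINGULAR:
            raise SingularInformationError(
                "total information matrix is singular for this allocation"
            )
        if cond > _COND_WARN:
            warnings.warn(
                f"information matrix ill-conditioned (cond={cond:.2e}); "
                "variance may be inaccurate",
                RuntimeWarning,
                stacklevel=2,
            )
        x = np.linalg.solve(M, e)
    except np.linalg.LinAlgError as exc:
        raise SingularInformationError(
            "total information matrix is singular for this allocation"
        ) from exc
    var = float(x[-1])
    if var <= 0:
        raise SingularInformationError(
            "non-positive variance: information matrix numerically indefinite"
        )
    if n_total is not None:
        var /= float(n_total)
    return var
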