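"""Variance-minimizing allocation over the simplex, with optional box bounds.

No closed form for the map from allocation to ``var(gamma_hat)`` exists
under exponential-decay correlation and/or attrition, so the optimum is
found numerically: SLSQP over the ``J-1`` free proportions (the last one
implied by the simplex constraint) with an analytic gradient, restarted
from the uniform allocation plus randomized Dirichlet draws to guard
against local minima.  A brute-force lattice enumeration (`grid_oracle`)
is provided as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import minimize

from .design import DesignSpec
from .exceptions import OptimizationError, SingularInformationError
from .precision import check_bounds, information_matrices, treatment_variance

__all__ = ["OptimizationResult", "optimize_allocation", "grid_oracle"]

_INTERIOR_FLOOR = 1e-9  # keeps implied proportions strictly positive
_ACTIVE_TOL = 1e-6


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a multi-start allocation optimization.

    ``active_bounds`` lists (sequence, "lower"|"upper") pairs for
    user-supplied bounds within 1e-6 of being attained (1-based sequence
    labels).
    """

    optimal_proportions: np.ndarray
    optimal_variance: float
    converged: bool
    active_bounds: tuple[tuple[int, str], ...]
    starts_used: int

    def to_dict(self) -> dict:
        return {
            "p_star": [float(v) for v in self.optimal_proportions],
            "variance": self.optimal_variance,
            "converged": self.converged,
            "active_bounds": [list(ab) for ab in self.active_bounds],
            "starts_used": self.starts_used,
        }


def _project_box_simplex(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Project a simplex point into feasible box bounds by clipping and
    redistributing the excess over unsaturated coordinates."""
    p = np.clip(p, lo, hi)
    for _ in range(100):
        gap = 1.0 - p.sum()
        if abs(gap) < 1e-12:
            break
        room = (hi - p) if gap > 0 else (p - lo)
        movable = room > 1e-15
        if not movable.any():
            break
        share = room * movable / room[movable].sum()
        p = np.clip(p + gap * share, lo, hi)
    return p


def optimize_allocation(
    spec: DesignSpec,
    lower=None,
    upper=None,
    n_starts: int = 10,
    seed: int = 2023,
) -> OptimizationResult:
    """Minimize var(gamma_hat) over allocations p on the simplex.

    Parameters
    ----------
    spec : DesignSpec
        Design parameters (J, rho, r, sigma2).
    lower, upper : float or array, optional
        Per-sequence allocation bounds (scalar broadcasts to all J).
        Feasibility (sum(lower) <= 1 <= sum(upper)) is checked up front.
    n_starts : int
        Number of randomized starts in addition to the uniform start.
    seed : int
        Seed for the randomized starts; fixed seed + fixed n_starts
        reproduces the result bit for bit.

    Returns
    -------
    OptimizationResult
        Best converged solution across starts; solutions tied within
        1e-12 in variance resolve to the lexicographically smallest p.
    """
    J = spec.J
    lo, hi = check_bounds(lower, upper, J)
    lo_eff = np.maximum(lo, _INTERIOR_FLOOR)
    hi_eff = np.minimum(hi, 1.0 - _INTERIOR_FLOOR)
    A = information_matrices(spec)
    eK = np.zeros(A.shape[1])
    eK[-1] = 1.0

    def full_p(q: np.ndarray) -> np.ndarray:
        return np.append(q, 1.0 - q.sum())

    def value_and_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        p = full_p(q)
        M = np.tensordot(p, A, axes=1)
        try:
            x = np.linalg.solve(M, eK)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(J - 1)
        var = x[-1]
        # d var / d p_j = -x' A_j x ; chain through p_J = 1 - sum(q)
        g = -np.einsum("i,jik,k->j", x, A, x)
        return var, g[:-1] - g[-1]

    constraints = [
        {  # implied last proportion within its bounds
            "type": "ineq",
            "fun": lambda q: 1.0 - q.sum() - lo_eff[-1],
            "jac": lambda q: -np.ones(J - 1),
        },
        {
            "type": "ineq",
            "fun": lambda q: hi_eff[-1] - (1.0 - q.sum()),
            "jac": lambda q: np.ones(J - 1),
        },
    ]
    box = list(zip(lo_eff[:-1], hi_eff[:-1]))

    rng = np.random.default_rng(seed)
    starts = [_project_box_simplex(np.full(J, 1.0 / J), lo_eff, hi_eff)]
    for _ in range(int(n_starts)):
        starts.append(_project_box_simplex(rng.dirichlet(np.ones(J)), lo_eff, hi_eff))

    candidates: list[tuple[float, np.ndarray]] = []
    for p0 in starts:
        res = minimize(
            value_and_grad,
            p0[:-1],
            jac=True,
            method="SLSQP",
            bounds=box,
            constraints=constraints,
            options={"ftol": 1e-10, "maxiter": 500},
        )
        if not res.success:
            continue
        p = _project_box_simplex(full_p(res.x), lo_eff, hi_eff)
        try:
            var = treatment_variance(p, spec, A=A)
        except SingularInformationError:
            continue
        candidates.append((var, p))

    if not candidates:
        raise OptimizationError(
            f"no start converged for J={J}, rho={spec.rho}, r={spec.r} "
            f"({len(starts)} starts attempted)"
        )

    best_var = min(var for var, _ in candidates)
    tied = [p for var, p in candidates if var <= best_var + 1e-12]
    tied.sort(key=lambda p: tuple(p))
    p_star = tied[0]

    active = []
    for j in range(J):
        if lower is not None and abs(p_star[j] - lo[j]) <= _ACTIVE_TOL:
            active.append((j + 1, "lower"))
        if upper is not None and abs(p_star[j] - hi[j]) <= _ACTIVE_TOL:
            active.append((j + 1, "upper"))

    return OptimizationResult(
        optimal_proportions=p_star,
        optimal_variance=treatment_variance(p_star, spec, A=A),
        converged=True,
        active_bounds=tuple(active),
        starts_used=len(starts),
    )


def _compositions(total: int, parts: int):
    """Yield all tuples of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def grid_oracle(
    spec: DesignSpec,
    lower=None,
    upper=None,
    resolution: float = 0.01,
    max_points: int = 5_000_000,
) -> tuple[np.ndarray, float]:
    """Exhaustive search over the lattice of allocations with step ``resolution``.

    Enumerates every allocation whose proportions are multiples of
    ``resolution`` (interior: every proportion strictly positive unless a
    zero lower bound is explicitly lifted by the lattice), filters by the
    box bounds, and returns the variance minimizer ``(p, var)``.  Intended
    for small J as an independent check on `optimize_allocation`; lattice
    sizes above ``max_points`` are refused.
    """
    J = spec.J
    lo, hi = check_bounds(lower, upper, J)
    N = round(1.0 / resolution)
    if abs(N * resolution - 1.0) > 1e-9:
        raise ValueError(f"resolution {resolution} must divide 1 into an integer lattice")
    n_lattice = comb(N + J - 1, J - 1)
    if n_lattice > max_points:
        raise ValueError(
            f"lattice of {n_lattice} points exceeds cap {max_points}; "
            "coarsen the resolution or reduce J"
        )

    pts = np.array(list(_compositions(N, J)), dtype=float) / N
    keep = (pts > 0).all(axis=1) & (pts >= lo - 1e-12).all(axis=1) & (pts <= hi + 1e-12).all(axis=1)
    pts = pts[keep]
    if pts.shape[0] == 0:
        raise ValueError("no lattice point satisfies the bounds; refine the resolution")

    A = information_matrices(spec)
    K = A.shape[1]
    M = np.tensordot(pts, A, axes=1)  # (m, K, K)
    e = np.zeros(K)
    e[-1] = 1.0
    x = np.linalg.solve(M, e.reshape(1, K, 1))  # batched over the lattice
    variances = x[:, -1, 0]
    variances = np.where(variances > 0, variances, np.inf)
    best = np.min(variances)
    # deterministic tie-break: lexicographically smallest allocation
    tied = pts[variances <= best + 1e-15]
    order = np.lexsort(tied.T[::-1])
    p_best = tied[order[0]]
    return p_best, float(best)
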