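"""Relative efficiency of allocations and parameter-grid sweeps.

The relative efficiency (RE) of an allocation compares the variance the
optimal allocation achieves with the variance of the comparison
allocation: RE = var(gamma_hat; p*) / var(gamma_hat; p) <= 1.  An RE of
0.8 means the comparison design needs (1/0.8 - 1) * 100 = 25% more
individuals to match the optimal design's precision.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .design import DesignSpec
from .exceptions import DesignError, SwallocError
from .optimize import optimize_allocation
from .precision import Allocation, information_matrices, treatment_variance

__all__ = [
    "uniform_allocation",
    "relative_efficiency",
    "sample_size_inflation",
    "efficiency_grid",
]

DEFAULT_J_VALUES: tuple[int, ...] = (3, 4, 5, 6)
DEFAULT_RHO_VALUES: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
DEFAULT_R_VALUES: tuple[float, ...] = (0.0, 0.05, 0.2)


def uniform_allocation(J: int) -> Allocation:
    """Equal proportions 1/J per sequence — the common default design."""
    if int(J) != J or J < 2:
        raise DesignError(f"need at least 2 sequences, got J={J}")
    return Allocation.uniform(int(J))


def relative_efficiency(
    alternative,
    spec: DesignSpec,
    lower=None,
    upper=None,
    n_starts: int = 10,
    seed: int = 2023,
) -> float:
    """RE of ``alternative`` against the (constrained) optimal allocation.

    Equals 1 when the alternative is itself optimal; bounds, when given,
    constrain the optimum the alternative is compared against.
    """
    var_alt = treatment_variance(alternative, spec)
    opt = optimize_allocation(spec, lower=lower, upper=upper, n_starts=n_starts, seed=seed)
    return opt.optimal_variance / var_alt


def sample_size_inflation(re: float) -> float:
    """Percent extra sample the comparison allocation needs: (1/RE - 1) * 100."""
    if not 0.0 < re <= 1.0:
        raise ValueError(f"relative efficiency must be in (0, 1], got {re}")
    return (1.0 / re - 1.0) * 100.0


def efficiency_grid(
    J_values: Iterable[int] = DEFAULT_J_VALUES,
    rho_values: Iterable[float] = DEFAULT_RHO_VALUES,
    r_values: Iterable[float] = DEFAULT_R_VALUES,
    lower=None,
    upper=None,
    sigma2: float = 1.0,
    n_starts: int = 10,
    seed: int = 2023,
) -> pd.DataFrame:
    """Optimal allocation and uniform-allocation RE for every (J, rho, r) cell.

    Returns one row per cell with columns ``J, rho, r, p_1..p_Jmax,
    var_star, var_uniform, relative_efficiency, inflation_percent`` (p
    columns beyond a row's J are NaN).  Failures in individual cells are
    recorded as NaN rows rather than aborting the sweep.
    """
    J_values = list(J_values)
    rho_values = list(rho_values)
    r_values = list(r_values)
    if not J_values or not rho_values or not r_values:
        raise ValueError("empty parameter range")
    J_max = max(J_values)
    rows = []
    for J in J_values:
        for r in r_values:
            for rho in rho_values:
                row: dict = {"J": J, "rho": rho, "r": r}
                try:
                    spec = DesignSpec(J=J, rho=rho, r=r, sigma2=sigma2)
                    A = information_matrices(spec)
                    opt = optimize_allocation(
                        spec, lower=lower, upper=upper, n_starts=n_starts, seed=seed
                    )
                    var_u = treatment_variance(uniform_allocation(J), spec, A=A)
                    re = opt.optimal_variance / var_u
                    for j in range(J):
                        row[f"p_{j + 1}"] = opt.optimal_proportions[j]
                    row.update(
                        var_star=opt.optimal_variance,
                        var_uniform=var_u,
                        relative_efficiency=re,
                        inflation_percent=sample_size_inflation(re),
                    )
                except SwallocError as exc:
                    row.update(
                        var_star=np.nan,
                        var_uniform=np.nan,
                        relative_efficiency=np.nan,
                        inflation_percent=np.nan,
                        error=str(exc),
                    )
                rows.append(row)
    cols = (
        ["J", "rho", "r"]
        + [f"p_{j + 1}" for j in range(J_max)]
        + ["var_star", "var_uniform", "relative_efficiency", "inflation_percent"]
    )
    frame = pd.DataFrame(rows)
    for c in cols:
        if c not in frame.columns:
            frame[c] = np.nan
    extra = [c for c in frame.columns if c not in cols]
    return frame[cols + extra]
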