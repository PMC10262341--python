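"""Stepped-wedge treatment layouts and fixed-effects design matrices.

An individually randomized stepped-wedge design with ``J`` treatment
sequences has ``T = J + 1`` measurement periods.  Every sequence starts in
the control condition; at the beginning of each period one sequence crosses
over to the intervention, so sequence ``j`` is on intervention from period
``j + 1`` onward and all sequences end on intervention.

The outcome model for individual ``i`` in sequence ``j`` at period ``t`` is

    Y_ijt = beta + tau_t + x_jt * gamma + eps_ijt,

with ``tau_1 = 0`` for identifiability.  The fixed-effects design matrix
for one individual therefore has ``T + 1`` columns ordered as
``[intercept, period-2 dummy, ..., period-T dummy, treatment]``; the
treatment effect ``gamma`` is the last coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DesignError

__all__ = [
    "DesignSpec",
    "build_sequence_layout",
    "build_design_matrix",
    "truncate_design",
    "layout_to_frame",
]


@dataclass(frozen=True)
class DesignSpec:
    """One stepped-wedge design problem.

    Parameters
    ----------
    J : int
        Number of treatment sequences (>= 2).  The number of measurement
        periods is ``T = J + 1``.
    rho : float
        Within-person correlation between measurements one period apart,
        in ``[0, 1)``.  Correlation at lag ``|t - t'|`` decays as
        ``rho ** |t - t'|`` (exponential decay / AR(1)-type).
    r : float, default 0.0
        Per-period attrition rate in ``[0, 1)``: the probability an
        individual observed at one period is lost before the next.
        Dropout is monotone — once gone, gone.
    sigma2 : float, default 1.0
        Residual variance ``sigma_eps^2``.  A pure scale factor of
        ``var(gamma_hat)``; it cancels in the optimal allocation and in
        relative efficiencies.
    """

    J: int
    rho: float
    r: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if int(self.J) != self.J or self.J < 2:
            raise DesignError(
                f"need at least 2 sequences for a between-sequence contrast, got J={self.J}"
            )
        object.__setattr__(self, "J", int(self.J))
        if not 0.0 <= self.rho < 1.0:
            raise DesignError(f"rho must be in [0, 1), got {self.rho}")
        if not 0.0 <= self.r < 1.0:
            raise DesignError(f"attrition rate r must be in [0, 1), got {self.r}")
        if not self.sigma2 > 0.0:
            raise DesignError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def T(self) -> int:
        """Number of measurement periods, J + 1."""
        return self.J + 1

    @property
    def n_params(self) -> int:
        """Number of fixed-effect parameters: intercept + (T-1) period dummies + treatment."""
        return self.T + 1


def build_sequence_layout(J: int) -> np.ndarray:
    """Return the J x (J+1) binary treatment-indicator matrix.

    Entry ``(j, t)`` (1-based) is 1 iff sequence ``j`` is on the
    intervention in period ``t``, i.e. iff ``t >= j + 1``.  Row ``j``
    crosses over at the start of period ``j + 1``; column 1 is all zeros
    and column T all ones.
    """
    if int(J) != J or J < 2:
        raise DesignError(f"need at least 2 sequences, got J={J}")
    J = int(J)
    T = J + 1
    t = np.arange(1, T + 1)
    j = np.arange(1, J + 1)
    return (t[None, :] >= j[:, None] + 1).astype(np.int64)


def build_design_matrix(j: int, spec: DesignSpec) -> np.ndarray:
    """Fixed-effects matrix X_j (T rows, T+1 columns) for sequence ``j`` (1-based).

    Columns: intercept, period dummies for periods 2..T, treatment
    indicator (row ``j`` of the sequence layout).
    """
    if int(j) != j or not 1 <= j <= spec.J:
        raise DesignError(f"sequence index must be in 1..{spec.J}, got {j}")
    T = spec.T
    X = np.zeros((T, T + 1))
    X[:, 0] = 1.0
    for t in range(2, T + 1):  # dummy for period t sits in column t-1
        X[t - 1, t - 1] = 1.0
    X[:, T] = build_sequence_layout(spec.J)[int(j) - 1]
    return X


def truncate_design(X: np.ndarray, t: int) -> np.ndarray:
    """First ``t`` rows of a design matrix (the records of an individual
    whose last observation is at the end of period ``t``)."""
    T = X.shape[0]
    if int(t) != t or not 1 <= t <= T:
        raise DesignError(f"truncation period must be in 1..{T}, got {t}")
    return X[: int(t), :]


def layout_to_frame(J: int) -> pd.DataFrame:
    """Sequence layout as a DataFrame (rows = sequences, columns period_1..period_T),
    ready for CSV export."""
    layout = build_sequence_layout(J)
    T = J + 1
    return pd.DataFrame(
        layout,
        index=pd.Index(range(1, J + 1), name="sequence"),
        columns=[f"period_{t}" for t in range(1, T + 1)],
    )
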