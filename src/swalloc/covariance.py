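"""Exponential-decay residual covariance and attrition weights.

The residuals of one individual's repeated measurements have covariance
``V[t, t'] = sigma2 * rho ** |t - t'|`` — a symmetric Toeplitz matrix,
positive definite for any ``rho`` in ``[0, 1)``.

Under a constant per-period attrition rate ``r``, the expected fraction of
a sequence's individuals whose *last* observation falls at the end of
period ``t`` is ``(1-r)**(t-1) - (1-r)**t`` for ``t < T``; individuals
still present at period ``T`` are completers with mass ``(1-r)**(T-1)``,
so the weights form a proper probability distribution over last-observation
times.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import toeplitz

from .design import DesignSpec
from .exceptions import DesignError

__all__ = ["exp_decay_covariance", "truncate_covariance", "attrition_weights"]


def exp_decay_covariance(spec: DesignSpec) -> np.ndarray:
    """T x T residual covariance matrix sigma2 * rho^|t-t'|."""
    lags = np.arange(spec.T)
    return spec.sigma2 * toeplitz(spec.rho ** lags)


def truncate_covariance(V: np.ndarray, t: int) -> np.ndarray:
    """Leading t x t principal submatrix of V (covariance of the first t
    measurements); remains positive definite."""
    T = V.shape[0]
    if int(t) != t or not 1 <= t <= T:
        raise DesignError(f"truncation period must be in 1..{T}, got {t}")
    t = int(t)
    return V[:t, :t]


def attrition_weights(spec: DesignSpec) -> np.ndarray:
    """Length-T distribution of last-observation periods.

    ``w[t-1] = (1-r)**(t-1) - (1-r)**t`` for ``t = 1..T-1`` and
    ``w[T-1] = (1-r)**(T-1)`` (completer mass).  Sums to 1 for any
    ``r`` in ``[0, 1)``; for ``r = 0`` it is ``(0, ..., 0, 1)``.
    """
    T = spec.T
    s = (1.0 - spec.r) ** np.arange(T + 1)  # survival at period boundaries
    w = s[:-1] - s[1:]
    w[T - 1] = s[T - 1]
    return w
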