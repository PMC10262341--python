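"""Monte Carlo validation: simulate stepped-wedge trial data and fit GLS.

Data are generated from the outcome model
``Y_ijt = beta + tau_t + x_jt * gamma + eps_ijt`` with multivariate-normal
residuals under the exponential-decay covariance, and monotone dropout:
each individual's last-observation period is drawn from the attrition-weight
distribution, independently of the outcomes (missing completely at
random).  Fitting uses the known residual covariance — the design-stage
assumption under which the analytic variance formula holds — so the
empirical variance of ``gamma_hat`` across replicates can be checked
against the analytic ``var(gamma_hat)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import attrition_weights, exp_decay_covariance
from .design import DesignSpec, build_design_matrix, build_sequence_layout
from .exceptions import DesignError, EstimabilityError
from .precision import Allocation, treatment_variance

__all__ = [
    "TrialEffects",
    "TrialData",
    "GlsFit",
    "MonteCarloResult",
    "apportion",
    "simulate_trial",
    "fit_gls",
    "monte_carlo_variance",
]


@dataclass(frozen=True)
class TrialEffects:
    """Fixed effects of the generating model.

    ``tau`` holds the period effects for periods 2..T (period 1 is the
    reference, tau_1 = 0).
    """

    beta: float = 0.0
    tau: tuple[float, ...] = ()
    gamma: float = 0.0

    def mean_vector(self, j: int, spec: DesignSpec) -> np.ndarray:
        tau = np.asarray(self.tau, dtype=float)
        if tau.size == 0:
            tau = np.zeros(spec.T - 1)
        if tau.size != spec.T - 1:
            raise DesignError(f"tau must have T-1={spec.T - 1} entries, got {tau.size}")
        theta = np.concatenate([[self.beta], tau, [self.gamma]])
        return build_design_matrix(j, spec) @ theta


@dataclass
class TrialData:
    """Long-format simulated trial records plus the generating configuration.

    ``data`` columns: individual_id, sequence, period, treatment, outcome,
    observed.  Outcomes after an individual's dropout are missing
    (observed = 0, outcome empty); the observation pattern is monotone and
    everyone is observed at period 1.
    """

    data: pd.DataFrame
    spec: DesignSpec | None = None
    effects: TrialEffects | None = None
    proportions: np.ndarray | None = None
    seed: int | None = None

    def to_csv(self, path) -> None:
        """Write the records in long CSV form (missing outcomes as empty fields)."""
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, spec: DesignSpec | None = None) -> "TrialData":
        df = pd.read_csv(path)
        required = ["individual_id", "sequence", "period", "treatment", "outcome", "observed"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DesignError(f"trial CSV is missing columns {missing}")
        return cls(data=df, spec=spec)


@dataclass(frozen=True)
class GlsFit:
    """GLS solution with known residual covariance."""

    theta: np.ndarray
    cov_theta: np.ndarray
    n_used: int

    @property
    def gamma_hat(self) -> float:
        return float(self.theta[-1])

    @property
    def gamma_var(self) -> float:
        return float(self.cov_theta[-1, -1])


@dataclass(frozen=True)
class MonteCarloResult:
    """Empirical vs analytic variance of the treatment-effect estimator."""

    empirical_variance: float
    std_error: float
    analytic_variance: float
    mean_gamma_hat: float
    mean_model_variance: float
    true_gamma: float
    n_reps: int
    n_total: int

    @property
    def z_score(self) -> float:
        """(empirical - analytic) / SE(empirical)."""
        return (self.empirical_variance - self.analytic_variance) / self.std_error

    def agrees(self, k: float = 3.0) -> bool:
        """Whether the analytic variance lies within k standard errors."""
        return abs(self.z_score) <= k


def apportion(p, n_total: int) -> np.ndarray:
    """Largest-remainder rounding of proportions to integer headcounts.

    Deterministic (no randomness): quotas floor(p_j * n) plus the largest
    fractional remainders until the total is met; ties resolve to the
    earlier sequence.
    """
    p = p.proportions if isinstance(p, Allocation) else np.asarray(p, dtype=float)
    quota = p * n_total
    counts = np.floor(quota).astype(int)
    short = int(n_total - counts.sum())
    if short > 0:
        remainders = quota - counts
        order = np.lexsort((np.arange(p.size), -remainders))
        counts[order[:short]] += 1
    return counts


def _simulate_arrays(spec, counts, effects, rng):
    """Outcome matrix (n, T), sequence index (0-based) and last period per individual."""
    T = spec.T
    V = exp_decay_covariance(spec)
    L = np.linalg.cholesky(V)
    w = attrition_weights(spec)
    seq_idx = np.repeat(np.arange(spec.J), counts)
    n = seq_idx.size
    Y = rng.standard_normal((n, T)) @ L.T
    offset = 0
    for j in range(1, spec.J + 1):
        nj = counts[j - 1]
        Y[offset : offset + nj] += effects.mean_vector(j, spec)
        offset += nj
    t_last = rng.choice(np.arange(1, T + 1), size=n, p=w)
    return seq_idx, t_last, Y


def simulate_trial(
    spec: DesignSpec,
    p,
    n_total: int,
    effects: TrialEffects | None = None,
    seed: int = 0,
) -> TrialData:
    """Simulate one individually randomized stepped-wedge trial.

    Per-sequence headcounts are the largest-remainder apportionment of
    ``p * n_total``; residual vectors are multivariate normal with the
    exponential-decay covariance; each individual's last-observation
    period is drawn from the attrition weights independently of outcomes.
    Deterministic given ``seed``.
    """
    if n_total < spec.J:
        raise DesignError(f"n_total={n_total} below the number of sequences J={spec.J}")
    effects = effects or TrialEffects(tau=tuple(np.zeros(spec.T - 1)))
    p_arr = p.proportions if isinstance(p, Allocation) else np.asarray(p, dtype=float)
    counts = apportion(p_arr, n_total)
    if (counts == 0).any():
        warnings.warn(
            f"degenerate design: sequences {np.where(counts == 0)[0] + 1} received no individuals",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    seq_idx, t_last, Y = _simulate_arrays(spec, counts, effects, rng)

    T = spec.T
    layout = build_sequence_layout(spec.J)
    n = seq_idx.size
    periods = np.tile(np.arange(1, T + 1), n)
    ind = np.repeat(np.arange(1, n + 1), T)
    seq_long = np.repeat(seq_idx + 1, T)
    observed = (periods <= np.repeat(t_last, T)).astype(int)
    outcome = Y.ravel().astype(float)
    outcome[observed == 0] = np.nan
    df = pd.DataFrame(
        {
            "individual_id": ind,
            "sequence": seq_long,
            "period": periods,
            "treatment": layout[seq_idx][:, :].ravel(),
            "outcome": outcome,
            "observed": observed,
        }
    )
    return TrialData(
        data=df, spec=spec, effects=effects, proportions=p_arr, seed=seed
    )


def _group_terms(spec: DesignSpec):
    """Per-(sequence, last-period) GLS building blocks.

    Returns dict (j, t) -> (X_jt' V_t^-1, X_jt' V_t^-1 X_jt), with j
    1-based.
    """
    V = exp_decay_covariance(spec)
    terms = {}
    for j in range(1, spec.J + 1):
        X = build_design_matrix(j, spec)
        for t in range(1, spec.T + 1):
            Xt = X[:t]
            W = np.linalg.solve(V[:t, :t], Xt).T  # X' V^-1, shape (K, t)
            terms[(j, t)] = (W, W @ Xt)
    return terms


def _fit_arrays(seq_idx, t_last, Y, spec, terms=None):
    if terms is None:
        terms = _group_terms(spec)
    K = spec.n_params
    info = np.zeros((K, K))
    rhs = np.zeros(K)
    for j in range(1, spec.J + 1):
        in_seq = seq_idx == j - 1
        for t in range(1, spec.T + 1):
            sel = in_seq & (t_last == t)
            m = int(sel.sum())
            if m == 0:
                continue
            W, XtVX = terms[(j, t)]
            info += m * XtVX
            rhs += W @ Y[sel, :t].sum(axis=0)
    if np.linalg.matrix_rank(info) < K:
        raise EstimabilityError(
            "observed data do not identify all fixed effects "
            "(e.g. a period or treatment cell with no observations)"
        )
    cov = np.linalg.inv(info)
    theta = cov @ rhs
    return GlsFit(theta=theta, cov_theta=0.5 * (cov + cov.T), n_used=int(seq_idx.size))


def fit_gls(data: TrialData, spec: DesignSpec | None = None) -> GlsFit:
    """Fit the GLS estimator with the residual covariance treated as known.

    Each individual contributes through the truncated design ``X_jt`` and
    truncated covariance ``V_t`` for their last observed period ``t``.
    The observation pattern must be monotone (dropout, not intermittent
    missingness) with everyone observed at period 1.
    """
    spec = spec or data.spec
    if spec is None:
        raise DesignError("a DesignSpec is required to fit (covariance is taken as known)")
    df = data.data.sort_values(["individual_id", "period"])
    T = spec.T
    obs = df.pivot(index="individual_id", columns="period", values="observed").to_numpy()
    if obs.shape[1] != T:
        raise DesignError(f"expected {T} periods per individual, found {obs.shape[1]}")
    if not (obs[:, 0] == 1).all():
        raise DesignError("every individual must be observed at period 1")
    if (np.diff(obs, axis=1) > 0).any():
        raise DesignError("non-monotone observation pattern: dropout cannot be intermittent")
    t_last = obs.sum(axis=1).astype(int)
    Y = df.pivot(index="individual_id", columns="period", values="outcome").to_numpy()
    Y = np.nan_to_num(Y)  # unobserved cells never enter the truncated sums
    seq = df.groupby("individual_id")["sequence"].first().to_numpy()
    return _fit_arrays(seq - 1, t_last, Y, spec)


def monte_carlo_variance(
    spec: DesignSpec,
    p,
    n_total: int,
    effects: TrialEffects | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> MonteCarloResult:
    """Empirical variance of gamma_hat over replicates vs the analytic value.

    The analytic benchmark is the expected-information variance
    ``treatment_variance(p, spec) / n_total`` (expected dropout counts);
    the mean of the per-replicate model-based variances (realized dropout
    counts) is reported as a diagnostic.  The standard error of the
    empirical variance uses the normal-theory form s^2 * sqrt(2/(m-1)),
    exact here because gamma_hat is Gaussian.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be at least 100, got {n_reps}")
    effects = effects or TrialEffects(tau=tuple(np.zeros(spec.T - 1)))
    p_arr = p.proportions if isinstance(p, Allocation) else np.asarray(p, dtype=float)
    counts = apportion(p_arr, n_total)
    rng = np.random.default_rng(seed)
    terms = _group_terms(spec)
    gammas = np.empty(n_reps)
    model_vars = np.empty(n_reps)
    for rep in range(n_reps):
        seq_idx, t_last, Y = _simulate_arrays(spec, counts, effects, rng)
        fit = _fit_arrays(seq_idx, t_last, Y, spec, terms=terms)
        gammas[rep] = fit.gamma_hat
        model_vars[rep] = fit.gamma_var
    emp_var = float(np.var(gammas, ddof=1))
    se = emp_var * np.sqrt(2.0 / (n_reps - 1))
    analytic = treatment_variance(p_arr, spec, n_total=n_total)
    return MonteCarloResult(
        empirical_variance=emp_var,
        std_error=float(se),
        analytic_variance=analytic,
        mean_gamma_hat=float(gammas.mean()),
        mean_model_variance=float(model_vars.mean()),
        true_gamma=effects.gamma,
        n_reps=n_reps,
        n_total=n_total,
    )
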