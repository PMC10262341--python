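"""Trial simulation and GLS fitting with known covariance."""

import numpy as np
import pandas as pd
import pytest

from swalloc import (
    DesignSpec,
    TrialEffects,
    apportion,
    attrition_weights,
    build_design_matrix,
    exp_decay_covariance,
    fit_gls,
    monte_carlo_variance,
    simulate_trial,
    treatment_variance,
    uniform_allocation,
)
from swalloc.exceptions import DesignError

EFFECTS3 = TrialEffects(beta=2.0, tau=(0.3, -0.2, 0.5), gamma=1.0)


class TestApportionment:
    def test_largest_remainder_conserves_total(self):
        counts = apportion(np.array([0.33, 0.17, 0.17, 0.33]), 100)
        assert counts.sum() == 100
        np.testing.assert_array_equal(counts, [33, 17, 17, 33])

    def test_remainder_ties_resolve_to_earlier_sequence(self):
        counts = apportion(np.array([0.25, 0.25, 0.25, 0.25]), 102)
        np.testing.assert_array_equal(counts, [26, 26, 25, 25])

    def test_deterministic(self):
        p = np.array([0.4, 0.35, 0.25])
        np.testing.assert_array_equal(apportion(p, 97), apportion(p, 97))


class TestSimulateTrial:
    def test_no_attrition_gives_complete_records(self):
        spec = DesignSpec(J=3, rho=0.5, r=0.0)
        trial = simulate_trial(spec, uniform_allocation(3), 60, EFFECTS3, seed=1)
        assert (trial.data.groupby("individual_id")["observed"].sum() == spec.T).all()
        assert trial.data["outcome"].notna().all()

    def test_deterministic_given_seed(self):
        spec = DesignSpec(J=3, rho=0.5, r=0.2)
        a = simulate_trial(spec, uniform_allocation(3), 500, EFFECTS3, seed=42)
        b = simulate_trial(spec, uniform_allocation(3), 500, EFFECTS3, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_monotone_dropout_pattern(self):
        spec = DesignSpec(J=3, rho=0.5, r=0.3)
        trial = simulate_trial(spec, uniform_allocation(3), 400, EFFECTS3, seed=3)
        wide = trial.data.pivot(index="individual_id", columns="period", values="observed")
        assert (wide[1] == 1).all()  # everyone observed at baseline
        assert (wide.to_numpy()[:, 1:] - wide.to_numpy()[:, :-1] <= 0).all()
        # unobserved cells carry no outcome
        assert trial.data.loc[trial.data.observed == 0, "outcome"].isna().all()

    def test_treatment_column_follows_layout(self):
        spec = DesignSpec(J=4, rho=0.3, r=0.0)
        trial = simulate_trial(spec, uniform_allocation(4), 40, seed=5)
        for (j, t), grp in trial.data.groupby(["sequence", "period"]):
            assert (grp.treatment == int(t >= j + 1)).all()

    def test_null_model_has_no_treatment_signal(self):
        spec = DesignSpec(J=3, rho=0.4, r=0.0)
        effects = TrialEffects(beta=1.0, tau=(0.0, 0.0, 0.0), gamma=0.0)
        trial = simulate_trial(spec, uniform_allocation(3), 3000, effects, seed=11)
        df = trial.data
        diff = df[df.treatment == 1].outcome.mean() - df[df.treatment == 0].outcome.mean()
        assert abs(diff) < 0.1  # well within Monte Carlo error at this n

    def test_dropout_fractions_converge_to_attrition_weights(self):
        spec = DesignSpec(J=3, rho=0.4, r=0.15)
        trial = simulate_trial(spec, uniform_allocation(3), 100_000, EFFECTS3, seed=13)
        t_last = trial.data.groupby("individual_id")["observed"].sum()
        observed = t_last.value_counts(normalize=True).reindex(
            range(1, spec.T + 1), fill_value=0.0
        )
        np.testing.assert_allclose(observed.to_numpy(), attrition_weights(spec), atol=0.01)

    def test_rejects_tiny_samples_and_warns_on_empty_sequences(self):
        spec = DesignSpec(J=4, rho=0.3)
        with pytest.raises(DesignError):
            simulate_trial(spec, uniform_allocation(4), 3, seed=1)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            simulate_trial(spec, np.array([0.9, 0.05, 0.04, 0.01]), 20, seed=1)

    def test_csv_round_trip(self, tmp_path):
        spec = DesignSpec(J=3, rho=0.5, r=0.2)
        trial = simulate_trial(spec, uniform_allocation(3), 50, EFFECTS3, seed=21)
        path = tmp_path / "trial.csv"
        trial.to_csv(path)
        from swalloc import TrialData

        back = TrialData.from_csv(path, spec=spec)
        pd.testing.assert_frame_equal(back.data, trial.data, check_dtype=False)
        # fits agree on the round-tripped data
        assert fit_gls(back).gamma_hat == pytest.approx(fit_gls(trial).gamma_hat)


class TestFitGls:
    def test_noiseless_data_recovers_generating_effects(self):
        spec = DesignSpec(J=3, rho=0.5, r=0.0, sigma2=1e-12)
        trial = simulate_trial(spec, uniform_allocation(3), 30, EFFECTS3, seed=2)
        fit = fit_gls(trial)
        expected = np.array([2.0, 0.3, -0.2, 0.5, 1.0])
        np.testing.assert_allclose(fit.theta, expected, atol=1e-6)

    def test_matches_statsmodels_gls_without_attrition(self):
        """Independent textbook-GLS oracle on the stacked complete data."""
        import statsmodels.api as sm

        spec = DesignSpec(J=3, rho=0.6, r=0.0, sigma2=1.4)
        trial = simulate_trial(spec, uniform_allocation(3), 24, EFFECTS3, seed=8)
        fit = fit_gls(trial)

        df = trial.data.sort_values(["individual_id", "period"])
        seq = df.groupby("individual_id")["sequence"].first()
        X = np.vstack([build_design_matrix(int(j), spec) for j in seq])
        y = df["outcome"].to_numpy()
        V = exp_decay_covariance(spec)
        sigma = np.kron(np.eye(len(seq)), V)
        oracle = sm.GLS(y, X, sigma=sigma).fit()
        np.testing.assert_allclose(fit.theta, oracle.params, rtol=1e-8)

    def test_covariance_matches_information_at_realized_counts(self):
        """cov(theta_hat) from the fit equals the inverse attrition-truncated
        information accumulated over the realized dropout counts."""
        spec = DesignSpec(J=3, rho=0.4, r=0.25)
        trial = simulate_trial(spec, uniform_allocation(3), 200, EFFECTS3, seed=17)
        fit = fit_gls(trial)

        df = trial.data
        t_last = df.groupby("individual_id")["observed"].sum()
        seq = df.groupby("individual_id")["sequence"].first()
        V = exp_decay_covariance(spec)
        K = spec.n_params
        info = np.zeros((K, K))
        for (j, t), count in pd.crosstab(seq, t_last).stack().items():
            if count:
                Xt = build_design_matrix(int(j), spec)[: int(t)]
                info += count * Xt.T @ np.linalg.inv(V[: int(t), : int(t)]) @ Xt
        np.testing.assert_allclose(fit.cov_theta, np.linalg.inv(info), rtol=1e-8, atol=1e-12)

    def test_intermittent_missingness_rejected(self):
        spec = DesignSpec(J=3, rho=0.5, r=0.0)
        trial = simulate_trial(spec, uniform_allocation(3), 30, EFFECTS3, seed=4)
        df = trial.data.copy()
        df.loc[(df.individual_id == 1) & (df.period == 2), "observed"] = 0
        from swalloc import TrialData

        with pytest.raises(DesignError, match="monotone"):
            fit_gls(TrialData(data=df, spec=spec))


class TestMonteCarlo:
    def test_unbiased_and_agrees_with_analytic_variance(self):
        spec = DesignSpec(J=3, rho=0.4, r=0.0)
        p = uniform_allocation(3)
        mc = monte_carlo_variance(spec, p, 300, EFFECTS3, n_reps=400, seed=31)
        assert mc.agrees(3.0)
        se_mean = np.sqrt(mc.empirical_variance / mc.n_reps)
        assert abs(mc.mean_gamma_hat - EFFECTS3.gamma) < 3 * se_mean

    def test_attrition_inflates_empirical_variance(self):
        spec0 = DesignSpec(J=3, rho=0.4, r=0.0)
        spec2 = DesignSpec(J=3, rho=0.4, r=0.2)
        p = uniform_allocation(3)
        v0 = monte_carlo_variance(spec0, p, 300, EFFECTS3, n_reps=300, seed=7).empirical_variance
        v2 = monte_carlo_variance(spec2, p, 300, EFFECTS3, n_reps=300, seed=7).empirical_variance
        assert v2 > v0

    def test_refuses_too_few_replicates(self):
        with pytest.raises(ValueError):
            monte_carlo_variance(
                DesignSpec(J=3, rho=0.4), uniform_allocation(3), 300, n_reps=10, seed=1
            )
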