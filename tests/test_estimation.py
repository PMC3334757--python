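"""Mixed-effects estimation: likelihood oracle, recovery, model comparison."""

import numpy as np
import pytest
from scipy.integrate import simpson
from scipy.stats import norm

from acetapop import (
    DoseEvent,
    EffectParameters,
    FitResult,
    FitSettings,
    PKConstants,
    PopulationParameters,
    StudyDesign,
    TurnoverState,
    fit_nlme,
    generate_study,
    information_criteria,
    likelihood_ratio_test,
    log_marginal_likelihood,
    oracle_bicarbonate,
    shrinkage,
    typical_bicar0,
    typical_kout,
)


def brute_force_loglik(ds, theta, npts=201, span=6.0):
    """Independent marginal log-likelihood: Simpson grid over the two etas.

    Trajectories come from the quadrature-based integrating-factor oracle
    (not the production engine); bicarbonate is linear in the baseline, so
    the normalized trajectory is computed once per eta_kout grid value.
    """
    pk = PKConstants(k_elim=theta.k_elim)
    eff = EffectParameters(e_max=theta.e_max, a50=theta.a50)
    total = 0.0
    for s in ds.subjects():
        tb = typical_bicar0(theta, s.covariates)
        tk = typical_kout(theta, s.covariates)
        e1 = np.linspace(-span * theta.omega_bicar0, span * theta.omega_bicar0, npts)
        e2 = np.linspace(-span * theta.omega_kout, span * theta.omega_kout, npts)
        reg = [DoseEvent(t, a) for t, a in zip(s.dose_times, s.dose_amounts)]
        G = np.array([
            oracle_bicarbonate(TurnoverState(1.0, tk * np.exp(x2)), eff, reg,
                               pk, s.obs_times)
            for x2 in e2
        ])
        F = (tb * np.exp(e1))[:, None, None] * G[None, :, :]
        var = (theta.sigma_prop * F) ** 2
        y = s.obs_values[None, None, :]
        ll = -0.5 * ((y - F) ** 2 / var + np.log(2 * np.pi * var)).sum(-1)
        h = (ll + norm.logpdf(e1[:, None], 0, theta.omega_bicar0)
             + norm.logpdf(e2[None, :], 0, theta.omega_kout))
        hmax = h.max()
        total += hmax + np.log(simpson(simpson(np.exp(h - hmax), x=e2, axis=1),
                                       x=e1))
    return total


def _sparse_design(n, **kw):
    return StudyDesign(n_subjects=n, **kw)


class TestMarginalLikelihood:
    def test_single_observation_subjects_match_brute_force(self, theta):
        ds = generate_study(_sparse_design(2, obs_count_probs=(1.0, 0, 0, 0, 0, 0)),
                            theta, np.random.default_rng(17))
        agh = log_marginal_likelihood(ds, theta)
        brute = brute_force_loglik(ds, theta)
        assert agh == pytest.approx(brute, abs=1e-4)

    def test_three_subject_instance_matches_brute_force(self, theta):
        ds = generate_study(_sparse_design(3), theta, np.random.default_rng(11))
        agh = log_marginal_likelihood(ds, theta)
        brute = brute_force_loglik(ds, theta)
        assert agh == pytest.approx(brute, abs=1e-4)

    def test_degenerate_omegas_reduce_to_conditional_density(self, theta):
        """With omega -> 0 the marginal is the plain product of proportional-
        error Normal densities at the typical predictions."""
        th = theta.replace(omega_bicar0=0.0, omega_kout=0.0)
        ds = generate_study(_sparse_design(4), th, np.random.default_rng(23))
        ll = log_marginal_likelihood(ds, th)
        expected = 0.0
        pk = PKConstants(k_elim=th.k_elim)
        eff = EffectParameters(e_max=th.e_max, a50=th.a50)
        for s in ds.subjects():
            state = TurnoverState(typical_bicar0(th, s.covariates),
                                  typical_kout(th, s.covariates))
            reg = [DoseEvent(t, a) for t, a in zip(s.dose_times, s.dose_amounts)]
            f = oracle_bicarbonate(state, eff, reg, pk, s.obs_times)
            expected += norm.logpdf(s.obs_values, f, th.sigma_prop * f).sum()
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_subject_relabeling(self, theta, small_dataset):
        from acetapop.datasets import StudyDataset
        ll = log_marginal_likelihood(small_dataset, theta,
                                     FitSettings(n_agh=5))
        df = small_dataset.df.copy()
        # reverse subject order and relabel contiguously
        order = df["ID"].unique()[::-1]
        parts = [df[df["ID"] == sid].assign(ID=i + 1)
                 for i, sid in enumerate(order)]
        import pandas as pd
        shuffled = StudyDataset(pd.concat(parts, ignore_index=True))
        ll2 = log_marginal_likelihood(shuffled, theta, FitSettings(n_agh=5))
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_invariant_to_joint_time_shift(self, theta, small_dataset):
        """Shifting a subject's doses and observations together leaves the
        likelihood unchanged (the subject starts at equilibrium)."""
        from acetapop.datasets import StudyDataset
        ll = log_marginal_likelihood(small_dataset, theta, FitSettings(n_agh=5))
        df = small_dataset.df.copy()
        df.loc[df["ID"] == 1, "TIME"] += 1.5
        ll2 = log_marginal_likelihood(StudyDataset(df), theta, FitSettings(n_agh=5))
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_zero_residual_variance_rejected(self, theta, small_dataset):
        with pytest.raises(ValueError):
            log_marginal_likelihood(small_dataset,
                                    theta.replace(sigma_prop=0.0))


class TestFit:
    def test_noise_free_recovery_within_one_percent(self, theta):
        """Deterministic identifiability: sigma ~ 0, omega = 0 data return
        the generating tv_bicar0, tv_kout and a50 to < 1%."""
        truth = theta.replace(omega_bicar0=0.0, omega_kout=0.0, sigma_prop=0.0)
        ds = generate_study(_sparse_design(200), truth, np.random.default_rng(2))
        init = PopulationParameters(
            tv_bicar0=33.0, tv_kout=0.6, a50=200.0,
            beta_saps=truth.beta_saps, beta_chloride=truth.beta_chloride,
            theta_cort=truth.theta_cort, fur50=truth.fur50,
            omega_bicar0=0.0, omega_kout=0.0, sigma_prop=0.01)
        fit = fit_nlme(ds, FitSettings(
            free=("tv_bicar0", "tv_kout", "a50"), initial=init,
            compute_se=False))
        assert fit.params.tv_bicar0 == pytest.approx(35.5, rel=0.01)
        assert fit.params.tv_kout == pytest.approx(0.395, rel=0.01)
        assert fit.params.a50 == pytest.approx(117.0, rel=0.01)
        # self-consistency: the optimum is at least as likely as the truth
        ll_truth = log_marginal_likelihood(
            ds, truth.replace(sigma_prop=0.01), FitSettings(n_agh=1))
        assert fit.llf >= ll_truth - 1e-6

    def test_optimizer_never_worse_than_start(self, theta):
        ds = generate_study(_sparse_design(15), theta, np.random.default_rng(44))
        st = FitSettings(free=("tv_bicar0", "sigma_prop"), initial=theta,
                         compute_se=False)
        fit = fit_nlme(ds, st)
        ll0 = log_marginal_likelihood(ds, theta, FitSettings(n_agh=st.n_agh))
        assert fit.llf >= ll0 - 1e-8

    def test_single_subject_rejected(self, theta):
        design = _sparse_design(1)
        with pytest.raises(ValueError):
            ds = generate_study(design, theta, np.random.default_rng(0))
            fit_nlme(ds)

    def test_unavailable_algorithm_raises(self):
        with pytest.raises(NotImplementedError):
            FitSettings(algorithm="stochastic-EM")

    def test_fixed_parameters_cannot_be_freed(self):
        with pytest.raises(ValueError):
            FitSettings(free=("tv_bicar0", "e_max"))


class TestModelComparison:
    @staticmethod
    def _dummy_fit(llf, free, etas=None, n_obs=100):
        return FitResult(
            params=PopulationParameters(), free=tuple(free),
            se={}, llf=llf, n_obs=n_obs, n_subjects=10,
            etas=etas if etas is not None else np.zeros((10, 2)),
            converged=True, message="")

    def test_information_criteria_formulas(self):
        fit = self._dummy_fit(-100.0, ("tv_bicar0", "tv_kout", "a50",
                                       "omega_bicar0", "sigma_prop"), n_obs=100)
        aic, bic = information_criteria(fit)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + 5 * np.log(100))
        assert aic < bic  # n_obs > e^2 and p >= 1

    def test_zero_loglik_difference_gives_p_one(self):
        full = self._dummy_fit(-50.0, ("tv_bicar0", "beta_chloride"))
        red = self._dummy_fit(-50.0, ("tv_bicar0",))
        assert likelihood_ratio_test(full, red).p_value == pytest.approx(1.0)

    def test_chi2_quantile_reference_point(self):
        full = self._dummy_fit(-50.0 + 3.841 / 2, ("tv_bicar0", "beta_chloride"))
        red = self._dummy_fit(-50.0, ("tv_bicar0",))
        assert likelihood_ratio_test(full, red).p_value == pytest.approx(0.05, abs=1e-3)

    def test_non_nested_models_rejected(self):
        a = self._dummy_fit(-50.0, ("tv_bicar0",))
        b = self._dummy_fit(-50.0, ("tv_kout",))
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    @pytest.mark.parametrize("etas_scale, expected", [
        (1.0, 0.0),    # sd(eta) = omega -> no shrinkage
        (0.5, 0.5),    # sd(eta) = omega/2
        (0.0, 1.0),    # all etas zero -> full shrinkage
    ])
    def test_shrinkage_formula(self, theta, etas_scale, expected):
        rng = np.random.default_rng(0)
        z = rng.normal(size=10_000)
        z = (z - z.mean()) / z.std(ddof=1)  # exact unit sample SD
        etas = np.stack([z * theta.omega_bicar0 * etas_scale,
                         z * theta.omega_kout * etas_scale], axis=1)
        fit = FitResult(params=theta, free=(), se={}, llf=0.0, n_obs=1,
                        n_subjects=len(z), etas=etas, converged=True, message="")
        s = shrinkage(fit)
        assert s["omega_bicar0"] == pytest.approx(expected, abs=1e-9)
        assert s["omega_kout"] == pytest.approx(expected, abs=1e-9)

    def test_shrinkage_undefined_for_zero_omega(self):
        fit = self._dummy_fit(-1.0, ())
        fit.params = PopulationParameters(omega_bicar0=0.0)
        assert np.isnan(shrinkage(fit)["omega_bicar0"])


class TestCovariateRetention:
    def test_chloride_effect_retained_by_lrt(self, theta):
        """Data simulated WITH the chloride effect keep it at alpha = 0.05
        in at least 90% of replicates (scaled-down power check)."""
        kept = 0
        n_rep = 20
        for rep in range(n_rep):
            ds = generate_study(_sparse_design(60), theta,
                                np.random.default_rng(1000 + rep))
            init = theta.replace(beta_chloride=0.0)
            st = dict(initial=init, compute_se=False)
            red = fit_nlme(ds, FitSettings(
                free=("tv_bicar0", "sigma_prop"), **st))
            full = fit_nlme(ds, FitSettings(
                free=("tv_bicar0", "sigma_prop", "beta_chloride"), **st))
            if likelihood_ratio_test(full, red).p_value < 0.05:
                kept += 1
        assert kept >= 0.9 * n_rep
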