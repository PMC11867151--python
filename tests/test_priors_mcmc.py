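"""Priors, MCMC sampler behaviour and convergence diagnostics."""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.stats as st

import fossilbisse as fb
from fossilbisse.infer.priors import Prior, default_priors, log_prior


class TestPriors:
    def test_exponential_density_closed_form(self):
        # exp(mean 0.01) at q = 0.01: log(100) - 1
        pr = Prior("exponential", 0.01)
        assert pr.logpdf(0.01) == pytest.approx(math.log(100) - 1)

    def test_lognormal_density_at_location(self):
        pr = Prior("lognormal", math.log(0.1), 1.0)
        assert pr.logpdf(0.1) == pytest.approx(
            -math.log(0.1) - math.log(math.sqrt(2 * math.pi))
        )

    def test_out_of_support_gives_neg_inf_not_exception(self):
        priors = default_priors()
        assert log_prior({"lambda0": -0.5}, priors) == -np.inf
        assert log_prior({"pi0": 1.5}, priors) == -np.inf

    def test_total_log_prior_matches_scipy_oracle(self):
        priors = default_priors()
        rng = np.random.default_rng(0)
        names = ["lambda0", "lambda1", "mu0", "mu1", "q01", "q10", "psi", "pi0"]
        for _ in range(100):
            vals = {n: priors[n].sample(rng) for n in names}
            expected = (
                sum(
                    st.lognorm.logpdf(vals[n], s=2.0, scale=0.01)
                    for n in ("lambda0", "lambda1", "mu0", "mu1")
                )
                + st.lognorm.logpdf(vals["psi"], s=1.0, scale=0.05)
                + sum(st.expon.logpdf(vals[n], scale=0.01) for n in ("q01", "q10"))
                + st.uniform.logpdf(vals["pi0"])
            )
            assert log_prior(vals, priors) == pytest.approx(expected, abs=1e-10)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            Prior("lognormal", 0.0, -1.0)
        with pytest.raises(ValueError):
            Prior("exponential", 0.0)
        with pytest.raises(ValueError):
            Prior("cauchy", 0.0, 1.0)


class TestMcmcSampler:
    def test_constant_likelihood_recovers_priors(self):
        # with the likelihood forced to a constant the sampler must
        # reproduce the prior marginals (KS check per parameter)
        priors = default_priors()
        settings = fb.MCMCSettings(
            iterations=9000, moves_per_iteration=29, burnin_fraction=0.2,
            target_samples=2000,
        )
        trace = fb.run_mcmc(
            None, "bisse", priors=priors, settings=settings, seed=123,
            loglikelihood_fn=lambda v: 0.0,
        )
        cdfs = {
            "lambda0": st.lognorm(s=2.0, scale=0.01).cdf,
            "mu1": st.lognorm(s=2.0, scale=0.01).cdf,
            "q01": st.expon(scale=0.01).cdf,
            "pi0": st.uniform().cdf,
        }
        x = trace.df
        assert len(x) >= 2000
        for name, cdf in cdfs.items():
            sub = x[name].to_numpy()[:: max(1, len(x) // 2000)][:2000]
            p = st.kstest(sub, cdf).pvalue
            assert p > 0.01, f"{name}: KS p={p}"

    def test_same_seed_gives_identical_trace_bytes(self, tmp_path, small_replicate):
        settings = fb.MCMCSettings(iterations=120, target_samples=50)
        paths = []
        for i in (0, 1):
            tr = fb.run_mcmc(
                small_replicate.extant, "bisse", settings=settings, seed=77
            )
            p = tmp_path / f"t{i}.csv"
            tr.to_csv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_trace_round_trip_preserves_meta_and_samples(self, tmp_path, small_replicate):
        settings = fb.MCMCSettings(iterations=80, target_samples=20)
        tr = fb.run_mcmc(small_replicate.extant, "bisse", settings=settings, seed=5)
        p = tmp_path / "t.csv"
        tr.to_csv(p)
        back = fb.PosteriorTrace.from_csv(p)
        assert back.meta == tr.meta
        assert np.allclose(back.df.to_numpy(), tr.df.to_numpy())
        assert back.parameters == tr.parameters

    def test_view_model_mismatch_rejected(self, small_replicate):
        with pytest.raises(ValueError):
            fb.run_mcmc(small_replicate.fbd, "bisse", settings=fb.MCMCSettings(iterations=10))
        with pytest.raises(ValueError):
            fb.run_mcmc(small_replicate.extant, "bisse_fbd", settings=fb.MCMCSettings(iterations=10))

    def test_toy_posterior_moments_match_quadrature(self):
        # 1-D informative toy likelihood on lambda0: posterior moments by
        # quadrature vs MCMC; checks detailed balance empirically
        priors = default_priors()
        settings = fb.MCMCSettings(iterations=12000, moves_per_iteration=8,
                                   burnin_fraction=0.25, target_samples=3000)

        def loglik(v):
            return -50.0 * (v["lambda0"] - 0.2) ** 2 - 20.0 * (v["mu0"] - 0.1) ** 2

        trace = fb.run_mcmc(None, "bisse", priors=priors, settings=settings,
                            seed=42, loglikelihood_fn=loglik)
        from scipy.integrate import quad

        def post_mean(name, center, w):
            pr = priors[name]
            f = lambda x: math.exp(pr.logpdf(x) - w * (x - center) ** 2)
            z = quad(f, 1e-9, 10, limit=200)[0]
            m = quad(lambda x: x * f(x), 1e-9, 10, limit=200)[0]
            return m / z

        for name, center, w in [("lambda0", 0.2, 50.0), ("mu0", 0.1, 20.0)]:
            x = trace.df[name].to_numpy()
            ess = fb.effective_sample_size(x)
            se = x.std() / math.sqrt(max(ess, 10))
            assert abs(x.mean() - post_mean(name, center, w)) < 4 * se + 1e-4

    def test_two_psi_model_exposes_state_specific_rates(self, small_replicate):
        settings = fb.MCMCSettings(iterations=60, target_samples=20)
        tr = fb.run_mcmc(small_replicate.fbd, "bisse_fbd_2psi", settings=settings, seed=3)
        assert {"psi0", "psi1"} <= set(tr.parameters)
        assert "psi" not in tr.parameters


class TestEffectiveSampleSize:
    def test_white_noise_ess_near_n(self):
        x = np.random.default_rng(0).normal(size=4000)
        assert fb.effective_sample_size(x) == pytest.approx(4000, rel=0.2)

    def test_ar1_ess_matches_autocorrelation_time(self):
        rng = np.random.default_rng(1)
        n, phi = 10_000, 0.9
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal() * math.sqrt(1 - phi**2)
        expected = n * (1 - phi) / (1 + phi)
        assert fb.effective_sample_size(x) == pytest.approx(expected, rel=0.3)

    def test_constant_series_reports_length_with_warning(self):
        with pytest.warns(UserWarning):
            assert fb.effective_sample_size(np.ones(100)) == 100

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fb.effective_sample_size(np.arange(5))

    def test_convergence_report_flags_low_ess(self, small_replicate):
        settings = fb.MCMCSettings(iterations=60, target_samples=30)
        tr = fb.run_mcmc(small_replicate.extant, "bisse", settings=settings, seed=1)
        report = fb.convergence_report(tr, threshold=200.0)
        assert report["threshold"] == 200.0
        assert set(report["ess"]) == set(tr.parameters)
        assert report["flagged"], "a 60-iteration chain cannot reach ESS 200"
        assert not report["converged"]
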