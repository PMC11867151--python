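"""Summary statistics: intervals, coverage, errors, inequalities, ROC."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import fossilbisse.summarize as sz
from fossilbisse.infer.mcmc import PosteriorTrace

probs = hst.floats(0.0, 1.0).map(lambda x: round(x, 2))


def make_trace(**cols) -> PosteriorTrace:
    return PosteriorTrace(df=pd.DataFrame(cols), meta={})


class TestSummarizeTrace:
    def test_constant_trace_degenerate_interval(self):
        tr = make_trace(lambda0=[0.25] * 50)
        s = sz.summarize_trace(tr).set_index("parameter")
        assert s.loc["lambda0", "mean"] == 0.25
        assert s.loc["lambda0", "lower95"] == s.loc["lambda0", "upper95"] == 0.25

    def test_quantile_rule_on_known_sequence(self):
        tr = make_trace(mu0=np.arange(1, 1001, dtype=float))
        s = sz.summarize_trace(tr).set_index("parameter")
        assert s.loc["mu0", "mean"] == pytest.approx(500.5)
        assert s.loc["mu0", "lower95"] == pytest.approx(25.975)
        assert s.loc["mu0", "upper95"] == pytest.approx(975.025)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=500)
        a = sz.summarize_trace(make_trace(q01=x))
        b = sz.summarize_trace(make_trace(q01=rng.permutation(x)))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            sz.summarize_trace(make_trace(lambda0=[]))


class TestCoverageAndError:
    def test_full_coverage(self):
        assert sz.coverage_proportion([(0, 1)] * 10, 0.5) == 1.0

    def test_truth_on_endpoint_counts_as_covered(self):
        assert sz.coverage_proportion([(0.5, 1.0), (0.0, 0.5)], 0.5) == 1.0

    def test_mixed_coverage_fraction(self):
        ints = [(0, 1), (2, 3), (0.4, 0.6), (0.7, 0.9)]
        assert sz.coverage_proportion(ints, 0.5) == 0.5

    def test_relative_error_arithmetic(self):
        assert sz.relative_error(0.1, 0.1) == (0.0, 0.0)
        abs_e, signed_e = sz.relative_error(0.05, 0.1)
        assert abs_e == pytest.approx(0.5)
        assert signed_e == pytest.approx(-0.5)
        with pytest.raises(ValueError):
            sz.relative_error(0.1, 0.0)


class TestProbGreater:
    def test_strict_dominance(self):
        tr = make_trace(lambda1=[2.0, 3.0], lambda0=[1.0, 1.5])
        assert sz.prob_greater(tr, "lambda1", "lambda0") == 1.0

    def test_symmetric_independent_traces_near_half(self):
        rng = np.random.default_rng(2)
        tr = make_trace(mu0=rng.normal(size=4000), mu1=rng.normal(size=4000))
        assert sz.prob_greater(tr, "mu0", "mu1") == pytest.approx(0.5, abs=0.03)

    def test_tie_rule_makes_complements_sum_to_one(self):
        tr = make_trace(a=[1.0, 2.0, 3.0], b=[1.0, 5.0, 1.0])
        assert sz.prob_greater(tr, "a", "b") + sz.prob_greater(tr, "b", "a") == 1.0

    def test_missing_parameter_rejected(self):
        with pytest.raises(KeyError):
            sz.prob_greater(make_trace(a=[1.0]), "a", "zz")


class TestDerivedTransforms:
    def test_turnover_and_extinction_fraction_values(self):
        tr = make_trace(lambda0=[0.1], mu0=[0.03], lambda1=[0.2], mu1=[0.03])
        out = sz.derived_transforms(tr)
        assert out["tau0"].iloc[0] == pytest.approx(0.13)
        assert out["eps0"].iloc[0] == pytest.approx(0.3)
        assert out["tau1"].iloc[0] == pytest.approx(0.23)
        assert out["eps1"].iloc[0] == pytest.approx(0.15)

    def test_time_rescaling(self):
        tr = make_trace(lambda0=[0.1], mu0=[0.03], lambda1=[0.1], mu1=[0.03])
        tr2 = make_trace(lambda0=[0.2], mu0=[0.06], lambda1=[0.2], mu1=[0.06])
        a, b = sz.derived_transforms(tr), sz.derived_transforms(tr2)
        assert b["tau0"].iloc[0] == pytest.approx(2 * a["tau0"].iloc[0])
        assert b["eps0"].iloc[0] == pytest.approx(a["eps0"].iloc[0])

    def test_zero_speciation_samples_dropped_with_count(self):
        tr = make_trace(lambda0=[0.0, 0.1], mu0=[0.03, 0.03],
                        lambda1=[0.1, 0.1], mu1=[0.03, 0.03])
        out = sz.derived_transforms(tr)
        assert np.isnan(out["eps0"].iloc[0])
        assert out.attrs["eps_dropped"] == 1

    def test_jensen_gap_between_samplewise_and_mean_transform(self):
        rng = np.random.default_rng(3)
        lam = rng.lognormal(mean=np.log(0.1), sigma=0.8, size=5000)
        mu = rng.lognormal(mean=np.log(0.03), sigma=0.8, size=5000)
        tr = make_trace(lambda0=lam, mu0=mu, lambda1=lam, mu1=mu)
        samplewise = np.nanmean(sz.derived_transforms(tr)["eps0"])
        of_means = mu.mean() / lam.mean()
        assert samplewise > of_means  # E[mu/lam] > E[mu]/E[lam] for independent draws


class TestRoc:
    def test_perfect_separation_auc_one(self):
        roc = sz.roc_points([0.9, 0.95, 1.0], [0.1, 0.2, 0.3])
        assert roc.attrs["auc"] == pytest.approx(1.0)
        assert (roc["fpr"].iloc[0], roc["tpr"].iloc[0]) == (0.0, 0.0)
        assert (roc["fpr"].iloc[-1], roc["tpr"].iloc[-1]) == (1.0, 1.0)

    def test_identical_sets_auc_half(self):
        vals = [0.2, 0.4, 0.6, 0.8]
        assert sz.roc_points(vals, vals).attrs["auc"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_mann_whitney_u_statistic(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.round(rng.uniform(size=37), 2)  # rounding forces ties
        neg = np.round(rng.uniform(size=23) * 0.8, 2)
        roc = sz.roc_points(pos, neg)
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ) / (len(pos) * len(neg))
        assert roc.attrs["auc"] == pytest.approx(u, abs=1e-12)

    def test_curve_monotone_in_unit_square(self):
        rng = np.random.default_rng(9)
        roc = sz.roc_points(rng.uniform(size=30), rng.uniform(size=30))
        assert ((roc[["fpr", "tpr"]] >= 0) & (roc[["fpr", "tpr"]] <= 1)).all().all()
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()


class TestSummaryProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        hst.lists(probs, min_size=1, max_size=25),
        hst.lists(probs, min_size=1, max_size=25),
    )
    def test_roc_auc_equals_pairwise_comparison_count(self, pos, neg):
        roc = sz.roc_points(pos, neg)
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ) / (len(pos) * len(neg))
        assert roc.attrs["auc"] == pytest.approx(u, abs=1e-12)
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(hst.lists(hst.tuples(probs, probs), min_size=1, max_size=40))
    def test_prob_greater_complements_sum_to_one(self, pairs):
        tr = make_trace(a=[p[0] for p in pairs], b=[p[1] for p in pairs])
        assert sz.prob_greater(tr, "a", "b") + sz.prob_greater(tr, "b", "a") == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        hst.floats(-10, 10),
        hst.floats(1e-6, 10),
    )
    def test_relative_error_sign_and_magnitude(self, mean, truth):
        abs_e, signed = sz.relative_error(mean, truth)
        assert abs_e == pytest.approx(abs(signed))
        assert (signed >= 0) == (mean >= truth)


class TestAnalysisSetSummary:
    def test_rollup_reports_coverage_and_median_errors(self):
        rng = np.random.default_rng(4)
        traces = [
            make_trace(lambda0=rng.normal(0.1, 0.01, 400).clip(1e-4),
                       lambda1=rng.normal(0.2, 0.02, 400).clip(1e-4))
            for _ in range(10)
        ]
        truth = {"lambda0": 0.1, "lambda1": 0.2}
        summary = sz.summarize_analysis_set(traces, truth, inequality=("lambda1", "lambda0"))
        roll = summary.rollup().set_index("parameter")
        assert roll.loc["lambda0", "coverage"] >= 0.8
        assert abs(roll.loc["lambda0", "median_rel_error_signed"]) < 0.1
        assert len(summary.inequality_probs) == 10
        assert all(p == 1.0 for p in summary.inequality_probs)
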