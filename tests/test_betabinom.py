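"""Unit and property tests for the beta-binomial occult-disease model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from occultln import (
    BetaBinomialParams,
    ModelError,
    NodalCohort,
    NodalSimConfig,
    bb_pmf,
    bootstrap_ci,
    corrected_prevalence,
    detection_prob,
    estimate_fn_counts,
    fit_mle,
    goodness_of_fit,
    log_likelihood,
    min_nodes_for_confidence,
    occult_probability,
    prob_all_negative,
    simulate_nodal_cohort,
)

from conftest import ALPHA, BETA, PREVALENCE

shape_st = st.floats(min_value=0.1, max_value=50.0, allow_nan=False)


# ---------------------------------------------------------------------------
# probability kernels


class TestProbabilityKernels:
    def test_p0_closed_form_single_node(self, params):
        # with one node examined, P0 = beta / (alpha + beta)
        assert prob_all_negative(1, params) == pytest.approx(BETA / (ALPHA + BETA), abs=1e-12)

    def test_p0_no_nodes_is_one(self, params):
        assert prob_all_negative(0, params) == 1.0

    def test_pmf_zero_case_equals_p0(self, params):
        assert bb_pmf(0, 1, params) == pytest.approx(BETA / (ALPHA + BETA), rel=1e-12)

    def test_pmf_matches_scipy(self, params):
        # independent oracle: scipy's beta-binomial distribution
        for m in (1, 5, 12, 30):
            xs = np.arange(m + 1)
            expected = stats.betabinom(m, params.alpha, params.beta).pmf(xs)
            np.testing.assert_allclose(bb_pmf(xs, np.full_like(xs, m), params), expected, rtol=1e-10)

    @given(m=st.integers(1, 50), alpha=shape_st, beta=shape_st)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pmf_normalises(self, m, alpha, beta):
        p = BetaBinomialParams(alpha, beta)
        xs = np.arange(m + 1)
        assert bb_pmf(xs, np.full_like(xs, m), p).sum() == pytest.approx(1.0, abs=1e-10)

    @given(m=st.integers(1, 50), alpha=shape_st, beta=shape_st)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_p0_telescoping_product(self, m, alpha, beta):
        p = BetaBinomialParams(alpha, beta)
        k = np.arange(m)
        product = np.prod((beta + k) / (alpha + beta + k))
        assert prob_all_negative(m, p) == pytest.approx(product, rel=1e-12)

    def test_p0_strictly_decreasing(self, params):
        p0 = prob_all_negative(np.arange(1, 51), params)
        assert np.all(np.diff(p0) < 0)
        assert np.all(np.diff(detection_prob(np.arange(1, 51), params)) > 0)

    def test_domain_errors(self, params):
        with pytest.raises(ModelError):
            bb_pmf(3, 2, params)
        with pytest.raises(ModelError):
            prob_all_negative(-1, params)
        with pytest.raises(ModelError):
            BetaBinomialParams(-1.0, 2.0)


class TestOccultProbability:
    def test_printed_sequence(self, params):
        """The seven per-yield miss probabilities match the reported table."""
        printed = [31.3, 25.3, 20.6, 16.9, 14.1, 11.8, 10.0]
        for m, expected in zip(range(1, 8), printed):
            got = 100 * occult_probability(m, params, PREVALENCE)
            assert got == pytest.approx(expected, abs=0.15)

    def test_no_information_returns_prior(self, params):
        assert occult_probability(0, params, PREVALENCE) == PREVALENCE

    def test_strictly_decreasing_and_vanishing(self, params):
        occ = occult_probability(np.arange(0, 200), params, PREVALENCE)
        assert np.all(np.diff(occ) < 0)
        assert occ[-1] < 1e-3
        assert np.all(occ <= PREVALENCE)

    def test_prevalence_domain(self, params):
        with pytest.raises(ModelError):
            occult_probability(3, params, 1.2)

    def test_min_nodes_reported_cutoff(self, params):
        assert min_nodes_for_confidence(params, PREVALENCE, 0.10) == 7

    def test_min_nodes_threshold_above_prior(self, params):
        assert min_nodes_for_confidence(params, PREVALENCE, 0.50) == 0

    def test_min_nodes_brute_force_scan(self):
        # exhaustive-scan oracle over random parameter sets
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = BetaBinomialParams(rng.uniform(0.5, 8), rng.uniform(0.5, 12))
            prev = rng.uniform(0.15, 0.8)
            thresh = rng.uniform(0.02, prev * 0.9)
            got = min_nodes_for_confidence(p, prev, thresh, m_max=2000)
            scan = [m for m in range(1, 2001)
                    if occult_probability(m, p, prev) <= thresh]
            assert got == scan[0]


# ---------------------------------------------------------------------------
# likelihood and fitting


class TestLikelihood:
    def test_single_record_untruncated(self, params):
        cohort = NodalCohort(pd.DataFrame({"nodes_examined": [1], "nodes_positive": [0]}))
        expected = np.log(BETA / (ALPHA + BETA))
        assert log_likelihood(cohort, params) == pytest.approx(expected, rel=1e-12)

    def test_truncated_single_outcome_is_certain(self, params):
        # with m=1 and conditioning on x >= 1, only x=1 is possible
        cohort = NodalCohort(pd.DataFrame({"nodes_examined": [1], "nodes_positive": [1]}))
        assert log_likelihood(cohort, params, truncated=True) == pytest.approx(0.0, abs=1e-12)

    def test_truncated_rejects_zero_records(self, params):
        cohort = NodalCohort(pd.DataFrame({"nodes_examined": [2], "nodes_positive": [0]}))
        with pytest.raises(ModelError):
            log_likelihood(cohort, params, truncated=True)

    def test_finite_for_positive_params(self, toy_nodal_table):
        cohort = NodalCohort(toy_nodal_table)
        for a, b in [(0.1, 0.1), (50, 3), (1e-3, 1e3)]:
            assert np.isfinite(log_likelihood(cohort, BetaBinomialParams(a, b)))


class TestFit:
    @pytest.mark.parametrize("truncated", [False, True])
    def test_grid_search_oracle(self, truncated):
        """Optimiser optimum agrees with a dense log-grid search."""
        rng = np.random.default_rng(5)
        table = pd.DataFrame({
            "nodes_examined": rng.integers(2, 12, size=40),
        })
        p_i = rng.beta(2.0, 5.0, size=40)
        table["nodes_positive"] = rng.binomial(table["nodes_examined"], p_i)
        cohort = NodalCohort(table).fitting_subset()
        fit = fit_mle(cohort, truncated=truncated)

        grid = np.exp(np.linspace(np.log(0.2), np.log(30), 200))
        best_ll, best_ab = -np.inf, None
        for a in grid:
            lls = [log_likelihood(cohort, BetaBinomialParams(a, b), truncated) for b in grid]
            j = int(np.argmax(lls))
            if lls[j] > best_ll:
                best_ll, best_ab = lls[j], (a, grid[j])
        step = np.log(30 / 0.2) / 199
        assert fit.log_likelihood >= best_ll - 1e-9
        assert abs(np.log(fit.params.alpha) - np.log(best_ab[0])) <= step
        assert abs(np.log(fit.params.beta) - np.log(best_ab[1])) <= step

    def test_truncated_parameter_recovery(self):
        cfg = NodalSimConfig(
            n_patients=60000, true_prevalence=1.0, alpha=ALPHA, beta=BETA,
            yield_distribution="uniform", yield_params={"lo": 2, "hi": 15}, seed=30)
        fit = fit_mle(simulate_nodal_cohort(cfg), truncated=True)
        assert fit.params.alpha == pytest.approx(ALPHA, rel=0.05)
        assert fit.params.beta == pytest.approx(BETA, rel=0.05)

    def test_degenerate_point_mass_diverges(self):
        # every positivity fraction identical: the Beta law degenerates and
        # the likelihood pushes (alpha, beta) to infinity at fixed ratio
        table = pd.DataFrame({"nodes_examined": [4] * 200, "nodes_positive": [2] * 200})
        with pytest.raises(ModelError):
            fit_mle(NodalCohort(table))

    def test_empty_subset_errors(self):
        table = pd.DataFrame({"nodes_examined": [1, 1], "nodes_positive": [1, 0]})
        with pytest.raises(ModelError):
            fit_mle(NodalCohort(table))  # min_nodes=2 leaves nothing


# ---------------------------------------------------------------------------
# false-negative correction


class TestCorrection:
    def test_fn_count_closed_form(self, params):
        # m=1 stratum with 10 detected positives: FN = P0/(1-P0) * 10
        table = pd.DataFrame({"nodes_examined": [1] * 10, "nodes_positive": [1] * 10})
        profile = estimate_fn_counts(NodalCohort(table), params, prevalence=PREVALENCE)
        row = profile.table.set_index("m").loc[1]
        p0 = BETA / (ALPHA + BETA)
        assert row["fn_count"] == pytest.approx(p0 / (1 - p0) * 10, rel=1e-9)
        assert row["fn_count"] == pytest.approx(24.84, abs=0.01)

    def test_fn_zero_without_detections(self, params):
        table = pd.DataFrame({"nodes_examined": [5] * 4, "nodes_positive": [0] * 4})
        profile = estimate_fn_counts(NodalCohort(table), params, prevalence=PREVALENCE)
        assert (profile.table["fn_count"] == 0).all()

    def test_fn_decreases_with_yield(self, params):
        # same #TP at every yield: the miss-odds factor shrinks with m
        table = pd.DataFrame({
            "nodes_examined": np.repeat(np.arange(1, 11), 5),
            "nodes_positive": 1,
        })
        profile = estimate_fn_counts(NodalCohort(table), params, prevalence=PREVALENCE)
        fn = profile.table.set_index("m").loc[1:10, "fn_count"]
        assert np.all(np.diff(fn) < 0)

    def test_observed_prevalence_is_count_ratio(self, params):
        # 1,664 node-positive of 5,399 gives the familiar 30.8%
        n, k = 5399, 1664
        table = pd.DataFrame({
            "nodes_examined": [5] * n,
            "nodes_positive": [1] * k + [0] * (n - k),
        })
        est = corrected_prevalence(NodalCohort(table), params)
        assert est.observed_prevalence == pytest.approx(k / n, abs=1e-12)
        assert est.observed_prevalence == pytest.approx(0.308, abs=5e-4)
        assert est.corrected_prevalence >= est.observed_prevalence

    def test_all_positive_cohort_saturates(self, params):
        table = pd.DataFrame({"nodes_examined": [6] * 50, "nodes_positive": [2] * 50})
        est = corrected_prevalence(NodalCohort(table), params)
        assert est.observed_prevalence == 1.0
        assert est.corrected_prevalence == 1.0  # capped

    def test_generative_recovery(self, mixed_cohort, params):
        est = corrected_prevalence(mixed_cohort, params)
        assert est.corrected_prevalence == pytest.approx(PREVALENCE, abs=0.02)
        assert est.observed_prevalence < PREVALENCE - 0.05


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_matches_independent_loop(self, positive_cohort):
        """Same seed, same resampling scheme, computed by hand."""
        stat = lambda c: float(np.mean(c.nodes_examined))
        res = bootstrap_ci(positive_cohort, stat, n_replicates=100, seed=42)

        rng = np.random.default_rng(42)
        m = positive_cohort.nodes_examined
        vals = []
        for _ in range(100):
            idx = rng.integers(0, len(m), size=len(m))
            vals.append(float(np.mean(m[idx])))
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert res.ci_lower == pytest.approx(lo, rel=1e-12)
        assert res.ci_upper == pytest.approx(hi, rel=1e-12)
        assert res.ci_lower <= res.point_estimate <= res.ci_upper

    def test_single_replicate_degenerate_ci(self, positive_cohort):
        stat = lambda c: float(np.mean(c.nodes_positive))
        res = bootstrap_ci(positive_cohort, stat, n_replicates=1, seed=1)
        assert res.ci_lower == res.ci_upper == res.replicate_values[0]

    def test_named_alpha_statistic(self, positive_cohort):
        res = bootstrap_ci(positive_cohort, "alpha", n_replicates=30, seed=2, truncated=True)
        assert res.ci_lower <= res.ci_upper
        assert res.ci_lower < ALPHA < res.ci_upper  # wide CI at 30 reps


# ---------------------------------------------------------------------------
# goodness of fit


class TestGoodnessOfFit:
    def test_model_consistent_data_not_rejected(self, positive_cohort):
        fit = fit_mle(positive_cohort, truncated=True)
        gof = goodness_of_fit(positive_cohort, fit.params)
        assert gof.p_value > 0.01
        assert gof.df == len(gof.cells) - 3

    def test_gross_misfit_rejected(self, params):
        # every node positive in every patient: nothing like a Beta(2.5, 6.2) law
        table = pd.DataFrame({"nodes_examined": [6] * 300, "nodes_positive": [6] * 300})
        gof = goodness_of_fit(NodalCohort(table), params)
        assert gof.p_value < 1e-3

    def test_pooling_against_hand_computation(self, params):
        # two yield strata; expected counts per x computed independently and
        # pooled by the same left-to-right rule, coded separately here
        obs_by_m = {
            4: [14, 9, 5, 2],          # x = 1..4, 30 patients
            5: [15, 13, 8, 3, 1],      # x = 1..5, 40 patients
        }
        rows = {"nodes_examined": [], "nodes_positive": []}
        for m, counts in obs_by_m.items():
            for x, c in enumerate(counts, start=1):
                rows["nodes_examined"] += [m] * c
                rows["nodes_positive"] += [x] * c
        gof = goodness_of_fit(NodalCohort(pd.DataFrame(rows)), params)

        chi2, n_cells = 0.0, 0
        for m, counts in obs_by_m.items():
            pmf = np.array([bb_pmf(x, m, params) for x in range(1, m + 1)])
            exp = sum(counts) * pmf / (1 - prob_all_negative(m, params))
            pooled = []
            acc = np.zeros(2)
            for o, e in zip(counts, exp):
                acc += (o, e)
                if acc[1] >= 5:
                    pooled.append(acc.copy())
                    acc = np.zeros(2)
            if acc[1] > 0:
                pooled[-1] += acc
            for o, e in pooled:
                chi2 += (o - e) ** 2 / e
                n_cells += 1
        assert gof.statistic == pytest.approx(chi2, rel=1e-10)
        assert len(gof.cells) == n_cells
        assert gof.df == n_cells - 3

    def test_too_few_cells_errors(self, params):
        table = pd.DataFrame({"nodes_examined": [2] * 6, "nodes_positive": [1] * 6})
        with pytest.raises(ModelError):
            goodness_of_fit(NodalCohort(table), params)
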