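"""Cohort summaries, Poisson goodness of fit, cohort rate comparisons, and
per-gene over-representation tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dnmseek.enrichment_stats import (ReferenceCohort, classwise_summary,
                                      cohort_rate_test, gene_enrichment_test,
                                      poisson_gof, summarize_cohort,
                                      trios_with_class)
from dnmseek.variant_io import GeneRateTable

from conftest import make_obs, make_site
from dnmseek.dnm_detection import DnmCall

# the reference cohort's per-trio DNM counts (14 carriers + 10 zeros)
REFERENCE_COUNTS = [2, 2, 1, 7, 2, 2, 1, 1, 1, 1, 3, 2, 1, 2] + [0] * 10


def _call(trio_id="T1", cls="missense", gene="G1"):
    site = make_site(trio_id=trio_id, gene=gene,
                     consequence_raw={"LOF": "stopgain",
                                      "missense": "nonsynonymous SNV",
                                      "synonymous": "synonymous SNV",
                                      "inframe_indel": "nonframeshift"}[cls])
    return DnmCall(site=site, consequence_class=cls, passed_filters=True,
                   filter_failures=frozenset(), confidence_rank=1)


class TestSummarizeCohort:
    def test_zero_count_trios_included(self):
        calls = [_call("A"), _call("A"), _call("B")]
        s = summarize_cohort(calls, ["A", "B", "C"])
        assert s.per_trio_counts == {"A": 2, "B": 1, "C": 0}
        assert s.lambda_hat == pytest.approx(1.0)

    def test_single_trio_rate(self):
        calls = [_call("A")] * 3
        s = summarize_cohort(calls, ["A"])
        assert s.lambda_hat == 3.0

    def test_no_calls_gives_zero_rate(self):
        s = summarize_cohort([], ["A", "B"])
        assert s.lambda_hat == 0.0 and s.total == 0

    def test_unknown_trio_is_fatal(self):
        with pytest.raises(ValueError, match="unknown trio"):
            summarize_cohort([_call("X")], ["A"])

    def test_reference_cohort_rate(self, reference_calls):
        s = summarize_cohort(reference_calls, [str(t) for t in range(1, 25)])
        assert s.total == 28 and s.n_trios == 24
        assert s.lambda_hat == pytest.approx(28 / 24)
        assert s.lambda_reported == 1.2
        assert sorted(s.per_trio_counts.values()) == sorted(REFERENCE_COUNTS)

    def test_class_totals_match_per_trio_totals(self, reference_calls):
        s = summarize_cohort(reference_calls, [str(t) for t in range(1, 25)])
        assert sum(s.class_counts.values()) == sum(s.per_trio_counts.values())


class TestPoissonGof:
    def test_reference_counts_reproduce_published_fit(self):
        """p ≈ 0.89 for the cohort counts under the fitted Poisson."""
        res = poisson_gof(REFERENCE_COUNTS)
        assert res.lambda_hat == pytest.approx(28 / 24)
        assert res.p_value == pytest.approx(0.893, abs=0.05)
        res_rounded = poisson_gof(REFERENCE_COUNTS, lam=1.2)
        assert res_rounded.p_value == pytest.approx(0.893, abs=0.05)

    def test_statistic_is_discrete_support_supremum(self):
        """Oracle: brute-force max |ECDF - F| over the integer support."""
        counts = np.array(REFERENCE_COUNTS)
        lam = counts.mean()
        d_oracle = max(
            abs((counts <= k).mean() - stats.poisson.cdf(k, lam))
            for k in range(counts.max() + 1)
        )
        assert poisson_gof(counts.tolist()).ks_statistic == pytest.approx(
            d_oracle, abs=1e-12)

    def test_perfect_quantile_data_large_n_high_p(self):
        # counts drawn exactly at Poisson(2) expected frequencies
        n = 1000
        lam = 2.0
        counts = []
        for k in range(10):
            counts += [k] * round(n * stats.poisson.pmf(k, lam))
        res = poisson_gof(counts, lam=lam)
        assert res.p_value > 0.99

    def test_degenerate_all_zero_counts(self):
        res = poisson_gof([0, 0, 0, 0], lam=0.0)
        assert res.ks_statistic == 0.0 and res.p_value == 1.0

    def test_chi2_crosscheck_agrees_in_direction(self):
        good = poisson_gof(REFERENCE_COUNTS)
        bad = poisson_gof([0] * 20 + [9] * 4)
        assert good.chi2_p_value > bad.chi2_p_value
        assert good.p_value > bad.p_value

    def test_requires_two_trios(self):
        with pytest.raises(ValueError):
            poisson_gof([3])


class TestCohortRateTest:
    def test_published_lof_comparisons(self):
        p1 = cohort_rate_test(8, 24, ReferenceCohort("healthy", 54, 4))
        assert p1 == pytest.approx(0.011, abs=1e-3)
        p2 = cohort_rate_test(8, 24, ReferenceCohort("siblings", 677, 54))
        assert p2 == pytest.approx(0.001, abs=5e-4)

    def test_small_case_by_direct_enumeration(self):
        # m=2, pi0=0.5: P(X>=1) = 1 - 0.25
        assert cohort_rate_test(1, 10, ReferenceCohort("r", 10, 1)) == \
            pytest.approx(0.75)

    def test_no_events_gives_p_one(self):
        assert cohort_rate_test(0, 24, ReferenceCohort("r", 54, 0)) == 1.0

    @given(k_case=st.integers(0, 40), k_ref=st.integers(0, 160),
           n_case=st.integers(1, 50), n_ref=st.integers(1, 150))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force_pmf_sum(self, k_case, k_ref, n_case, n_ref):
        """Oracle: direct sum of binomial pmf terms over the upper tail."""
        m = k_case + k_ref
        pi0 = n_case / (n_case + n_ref)
        expected = sum(
            math.comb(m, j) * pi0 ** j * (1 - pi0) ** (m - j)
            for j in range(k_case, m + 1)
        ) if m else 1.0
        got = cohort_rate_test(k_case, n_case,
                               ReferenceCohort("r", n_ref, k_ref))
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_conservative_type_I_error_under_null(self, rng):
        """Exact-test rejection rate stays at or below nominal α."""
        alpha = 0.05
        n_case, n_ref, lam = 24, 54, 0.2
        reps = 2000
        k_case = rng.poisson(lam * n_case, size=reps)
        k_ref = rng.poisson(lam * n_ref, size=reps)
        rej = sum(
            cohort_rate_test(int(kc), n_case,
                             ReferenceCohort("r", n_ref, int(kr))) < alpha
            for kc, kr in zip(k_case, k_ref)
        )
        # binomial noise allowance on 2000 replicates
        assert rej / reps <= alpha + 2 * math.sqrt(alpha * (1 - alpha) / reps)


class TestGeneEnrichment:
    RATES = GeneRateTable({"RET": 1.33e-4, "UNIT": 1 / 24})

    def test_published_ret_over_representation(self):
        res = gene_enrichment_test("RET", 8, 24, self.RATES)
        assert res.rate_per_trio == pytest.approx(1 / 3)
        assert res.p_value < 2e-16

    def test_closed_form_poisson_tail(self):
        # n*mu = 1, observed 1 -> 1 - e^-1
        res = gene_enrichment_test("UNIT", 1, 24, self.RATES)
        assert res.p_value == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_zero_observed_gives_p_one(self):
        assert gene_enrichment_test("RET", 0, 24, self.RATES).p_value == 1.0

    def test_matches_survival_function_identity(self):
        for obs in (1, 2, 5):
            res = gene_enrichment_test("UNIT", obs, 24, self.RATES)
            assert res.p_value == pytest.approx(
                1 - stats.poisson.cdf(obs - 1, 1.0), rel=1e-12)

    def test_monotone_decreasing_in_observed(self):
        ps = [gene_enrichment_test("UNIT", k, 24, self.RATES).p_value
              for k in range(6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_absent_gene_yields_explicit_absent_result(self):
        res = gene_enrichment_test("NOSUCH", 3, 24, self.RATES)
        assert res.p_value is None and res.mu is None

    def test_fisher_mode_flags_strong_enrichment(self):
        res = gene_enrichment_test("RET", 8, 24, self.RATES, method="fisher")
        assert res.p_value < 1e-2


class TestClasswiseSummary:
    def test_reference_partition(self, reference_calls):
        counts = classwise_summary(reference_calls)
        assert counts["LOF"] == 8
        assert counts["missense"] == 12
        assert counts["inframe_indel"] == 1
        assert counts["synonymous"] == 7
        assert counts["LOF_nonsense"] == 2
        assert counts["LOF_frameshift"] == 5
        assert counts["LOF_splicing"] == 1

    def test_empty_input_all_zero(self):
        counts = classwise_summary([])
        assert all(v == 0 for v in counts.values())

    def test_single_nonsense_counted_as_lof(self):
        counts = classwise_summary([_call(cls="LOF")])
        assert counts["LOF"] == 1 and counts["LOF_nonsense"] == 1

    def test_trios_with_class_restricted_by_gene(self, reference_calls):
        assert len(trios_with_class(reference_calls, "LOF")) == 8
        ret_lof = trios_with_class(reference_calls, "LOF", gene="RET")
        non_ret = trios_with_class(reference_calls, "LOF") - ret_lof
        assert len(non_ret) == 3


class TestCalibration:
    def test_lambda_estimator_and_gof_calibrated_under_the_model(self, rng):
        """Poisson cohorts at λ=1.2: the mean of λ̂ is unbiased and the KS
        GOF rejects at α=0.05 at (or conservatively below) the nominal
        rate."""
        lam, n_trios, reps = 1.2, 24, 1200
        counts = rng.poisson(lam, size=(reps, n_trios))
        lam_hats = counts.mean(axis=1)
        se = lam_hats.std(ddof=1) / math.sqrt(reps)
        assert abs(lam_hats.mean() - lam) < 2 * se
        rej = sum(poisson_gof(row.tolist()).p_value < 0.05 for row in counts)
        # discrete-null KS is conservative: reject at or below ~5%
        assert rej / reps <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / reps)
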