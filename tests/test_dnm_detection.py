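"""Candidate selection, the four read-level criteria, ranking, mosaic
flagging, consequence classification, and the rare-variant filter."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dnmseek.dnm_detection import (DnmFilterConfig, RankModel,
                                   apply_dnm_filters, assign_confidence_rank,
                                   candidate_dnms, classify_consequence,
                                   filter_rare, flag_mosaic,
                                   is_denovo_configuration, strand_bias_phred,
                                   F_DEPTH, F_GQ, F_PARENT_FRAC,
                                   F_PROBAND_FRAC)
from dnmseek.variant_io import VariantRecord

from conftest import make_obs, make_site

GENOTYPES = [None, (0, 0), (0, 1), (1, 0), (1, 1)]


class TestCandidateSelection:
    def test_exhaustive_genotype_configuration_oracle(self):
        """Agreement with a brute-force truth table over all genotype trios.

        The oracle re-states the definition independently: proband carries
        >= 1 alt allele, both parents are called and carry 0 alt alleles.
        """
        def oracle(p, f, m):
            if p is None or f is None or m is None:
                return False
            return sum(p) >= 1 and sum(f) == 0 and sum(m) == 0

        for p, f, m in itertools.product(GENOTYPES, repeat=3):
            site = make_site(
                proband=make_obs(gt=p), father=make_obs(gt=f, alt=0),
                mother=make_obs(gt=m, alt=0))
            got = list(candidate_dnms([site]))
            assert bool(got) == oracle(p, f, m), (p, f, m)

    def test_inherited_het_excluded(self):
        site = make_site(father=make_obs(gt=(0, 1)))
        assert list(candidate_dnms([site])) == []

    def test_hom_alt_proband_retained_but_demoted_in_rank(self):
        site = make_site(proband=make_obs(gt=(1, 1), depth=40, alt=40))
        assert is_denovo_configuration((1, 1), (0, 0), (0, 0))
        call = apply_dnm_filters(site)
        assert call.passed_filters
        ranked = assign_confidence_rank(call)
        assert ranked.confidence_rank >= 3  # implausible double-de-novo


class TestFilterCriteria:
    def test_all_boundaries_inclusive(self):
        """A site exactly at every printed threshold passes all criteria."""
        site = make_site(
            proband=make_obs(depth=10, alt=1, gq=10.0),
            father=make_obs(gt=(0, 0), depth=10, alt=1, gq=10.0),
            mother=make_obs(gt=(0, 0), depth=10, alt=1, gq=10.0))
        call = apply_dnm_filters(site)
        assert call.passed_filters, call.filter_failures

    def test_depth_five_exactly_passes(self):
        site = make_site(
            proband=make_obs(depth=5, alt=3, gq=10.0),
            father=make_obs(gt=(0, 0), depth=5, alt=0, gq=10.0),
            mother=make_obs(gt=(0, 0), depth=5, alt=0, gq=10.0))
        assert apply_dnm_filters(site).passed_filters

    def test_depth_four_fails_regardless_of_other_fields(self):
        site = make_site(proband=make_obs(depth=4, alt=2, gq=99.0))
        call = apply_dnm_filters(site)
        assert F_DEPTH in call.filter_failures

    def test_parent_fraction_just_above_threshold_fails_only_that(self):
        site = make_site(
            father=make_obs(gt=(0, 0), depth=100, alt=11, gq=99.0))
        call = apply_dnm_filters(site)
        assert call.filter_failures == {F_PARENT_FRAC}

    def test_missing_gq_fails_quality_criterion(self):
        site = make_site(proband=make_obs(gq=None))
        assert F_GQ in apply_dnm_filters(site).filter_failures

    def test_zero_depth_parent_fails_depth_not_fraction(self):
        site = make_site(father=make_obs(gt=(0, 0), depth=0, alt=0, gq=99.0))
        call = apply_dnm_filters(site)
        assert F_DEPTH in call.filter_failures
        assert F_PARENT_FRAC not in call.filter_failures

    def test_zero_depth_proband_fails_depth_and_fraction(self):
        site = make_site(proband=make_obs(depth=0, alt=0))
        failures = apply_dnm_filters(site).filter_failures
        assert {F_DEPTH, F_PROBAND_FRAC} <= failures

    @given(
        depth=st.integers(1, 200), frac_pct=st.integers(0, 100),
        gq=st.floats(0, 99), parent_alt=st.integers(0, 30),
        relax=st.sampled_from(["min_depth", "min_gq",
                               "min_proband_alt_fraction",
                               "max_parent_alt_fraction"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_relaxing_any_threshold_is_monotone(self, depth, frac_pct, gq,
                                                parent_alt, relax):
        """A call passing at the defaults still passes after relaxing any
        single threshold."""
        alt = min(depth, round(depth * frac_pct / 100))
        site = make_site(
            proband=make_obs(depth=depth, alt=alt, gq=gq),
            father=make_obs(gt=(0, 0), depth=30, alt=parent_alt, gq=gq),
            mother=make_obs(gt=(0, 0), depth=30, alt=0, gq=gq))
        strict = apply_dnm_filters(site, DnmFilterConfig())
        relaxed_cfg = {
            "min_depth": DnmFilterConfig(min_depth=1),
            "min_gq": DnmFilterConfig(min_gq=0),
            "min_proband_alt_fraction": DnmFilterConfig(min_proband_alt_fraction=0.0),
            "max_parent_alt_fraction": DnmFilterConfig(max_parent_alt_fraction=1.0),
        }[relax]
        relaxed = apply_dnm_filters(site, relaxed_cfg)
        if strict.passed_filters:
            assert relaxed.passed_filters


class TestConfidenceRank:
    def test_clean_high_quality_call_is_rank_one(self):
        site = make_site(proband=make_obs(depth=50, alt=24, gq=99.0,
                                          strand=(13, 13, 12, 12)))
        call = assign_confidence_rank(apply_dnm_filters(site))
        assert call.confidence_rank == 1

    def test_extreme_strand_bias_forces_rank_at_least_four(self):
        """All alt reads on one strand with balanced ref reads."""
        site = make_site(proband=make_obs(depth=40, alt=20, gq=99.0,
                                          strand=(10, 10, 20, 0)))
        call = assign_confidence_rank(apply_dnm_filters(site))
        assert call.confidence_rank >= 4

    def test_strand_bias_phred_matches_hypergeometric_tail_enumeration(self):
        """Independent oracle: two-tailed exact p by direct enumeration of
        the hypergeometric over all tables with the observed margins."""
        strand = (10, 10, 20, 0)  # rf, rr, af, ar
        rf, rr, af, ar = strand
        n = rf + rr + af + ar
        row1 = rf + rr
        col1 = rf + af
        obs_p = stats.hypergeom.pmf(rf, n, row1, col1)
        total = sum(
            p for k in range(max(0, col1 - (af + ar)), min(row1, col1) + 1)
            if (p := stats.hypergeom.pmf(k, n, row1, col1)) <= obs_p * (1 + 1e-9)
        )
        expected_phred = -10 * math.log10(total)
        assert strand_bias_phred(strand) == pytest.approx(expected_phred,
                                                          rel=1e-6)

    def test_missing_strand_counts_leave_axis_neutral(self):
        site = make_site(proband=make_obs(depth=50, alt=24, gq=99.0))
        call = assign_confidence_rank(apply_dnm_filters(site))
        assert call.confidence_rank == 2

    def test_model_probability_promotes_low_rank_to_two(self):
        site = make_site(proband=make_obs(depth=40, alt=20, gq=99.0,
                                          strand=(10, 10, 20, 0)))
        call = apply_dnm_filters(site)
        assert assign_confidence_rank(call).confidence_rank >= 4
        always_yes = RankModel(coef=[0.0, 0.0, 0.0], intercept=5.0)
        assert assign_confidence_rank(call, model=always_yes).confidence_rank == 2
        always_no = RankModel(coef=[0.0, 0.0, 0.0], intercept=-5.0)
        assert assign_confidence_rank(call, model=always_no).confidence_rank >= 4

    def test_model_training_separates_labelled_outcomes(self):
        good = [apply_dnm_filters(make_site(
            proband=make_obs(depth=50, alt=25, gq=90 + i, strand=(13, 12, 13, 12))))
            for i in range(5)]
        bad = [apply_dnm_filters(make_site(
            proband=make_obs(depth=50, alt=6, gq=float(i), strand=(22, 22, 6, 0))))
            for i in range(5)]
        model = RankModel.train(good + bad, [True] * 5 + [False] * 5)
        assert model.predict_proba(good[0]) > 0.5 > model.predict_proba(bad[0])


class TestMosaicFlag:
    @pytest.mark.parametrize("frac,expected", [
        (0.15, True),   # inside the band
        (0.50, False),  # germline heterozygous
        (0.30, False),  # half-open upper boundary
        (0.10, True),   # closed lower boundary
        (0.05, False),  # below the band
    ])
    def test_band_membership(self, frac, expected):
        site = make_site(proband=make_obs(depth=100, alt=int(frac * 100),
                                          gq=99.0))
        call = flag_mosaic(apply_dnm_filters(site))
        assert call.mosaic_flag is expected


class TestConsequenceClassification:
    @pytest.mark.parametrize("raw,expected", [
        ("Nonsense", "LOF"),
        ("stopgain", "LOF"),
        ("Frameshift", "LOF"),
        ("frameshift deletion", "LOF"),
        ("Splicing", "LOF"),
        ("Missense", "missense"),
        ("nonsynonymous SNV", "missense"),
        ("Non-frameshift", "inframe_indel"),
        ("nonframeshift deletion", "inframe_indel"),
        ("Synonymous", "synonymous"),
        ("synonymous SNV", "synonymous"),
        ("ncRNA_exonic", "other"),
        ("", "other"),
    ])
    def test_annotation_string_mapping(self, raw, expected):
        v = VariantRecord(chrom="1", pos=1, ref="A", alt="G",
                          consequence_raw=raw)
        assert classify_consequence(v) == expected

    def test_reference_table_partitions_into_exactly_one_class(
            self, reference_calls):
        for call in reference_calls:
            assert call.consequence_class in {"LOF", "missense",
                                              "inframe_indel", "synonymous"}


class TestRareFilter:
    def test_low_frequency_retained(self):
        v = VariantRecord(chrom="1", pos=1, ref="A", alt="G",
                          pop_afs={"ExAC": 2.8e-3})
        assert filter_rare(v)

    def test_common_in_one_database_excluded(self):
        v = VariantRecord(chrom="1", pos=1, ref="A", alt="G",
                          pop_afs={"db": 0.02})
        assert not filter_rare(v)

    def test_no_database_entries_retained(self):
        v = VariantRecord(chrom="1", pos=1, ref="A", alt="G", pop_afs={})
        assert filter_rare(v)

    def test_threshold_is_exclusive_above(self):
        v = VariantRecord(chrom="1", pos=1, ref="A", alt="G",
                          pop_afs={"db": 0.01})
        assert filter_rare(v)  # exactly 0.01 is not "> 0.01"
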