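"""Region extraction, dN/dS estimation, filters and paired comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from domainage.evolrates import (
    CodonAlignmentPair,
    FilterThresholds,
    RateEstimate,
    apply_filters,
    compare_age_groups,
    estimate_dnds,
    extract_domain_region,
    paired_binomial_test,
    relative_difference,
)
from domainage.synthetic import simulate_codon_pair

from oracles import dnds_oracle, extract_region_oracle, two_sided_binom_p_oracle


def pair(ref, oth):
    return CodonAlignmentPair("ref", "oth", ref, oth)


class TestCodonAlignmentPair:
    def test_validation(self):
        with pytest.raises(ValueError):
            pair("ATGAAA", "ATG")  # length mismatch
        with pytest.raises(ValueError):
            pair("ATGA", "ATGC")  # not codon multiple
        with pytest.raises(ValueError):
            pair("AT-GAA", "ATGGAA")  # gap not codon-aligned

    def test_ref_length_skips_gap_codons(self):
        p = pair("ATG---AAA", "ATGCCCAAA")
        assert p.ref_length_aa == 2


class TestExtractRegion:
    def test_full_length_is_identity(self):
        p = pair("ATGAAACCC", "ATGAAGCCC")
        sub = extract_domain_region(p, 1, 3)
        assert (sub.ref_seq, sub.oth_seq) == (p.ref_seq, p.oth_seq)

    def test_first_codon(self):
        p = pair("ATGAAACCC", "ATGAAGCCC")
        sub = extract_domain_region(p, 1, 1)
        assert sub.ref_seq == "ATG" and sub.oth_seq == "ATG"

    def test_coordinates_beyond_reference_raise(self):
        p = pair("ATGAAA", "ATGAAA")
        with pytest.raises(ValueError):
            extract_domain_region(p, 1, 3)

    def test_interior_gap_columns_are_retained(self):
        ref = "ATG---AAACCC"
        oth = "ATGGGGAAACCC"
        sub = extract_domain_region(pair(ref, oth), 1, 2)
        assert sub.ref_seq == "ATG---AAA"
        assert sub.oth_seq == "ATGGGGAAA"

    def test_matches_column_walking_oracle_on_random_gapped_pairs(self, rng):
        codons = ["ATG", "AAA", "CCC", "GGG", "TTT", "GAA"]
        for _ in range(100):
            n = int(rng.integers(4, 12))
            ref_parts, oth_parts = [], []
            for _ in range(n):
                r = codons[int(rng.integers(len(codons)))]
                o = codons[int(rng.integers(len(codons)))]
                gap_side = rng.random()
                if gap_side < 0.15:
                    r = "---"
                elif gap_side < 0.3:
                    o = "---"
                ref_parts.append(r)
                oth_parts.append(o)
            ref, oth = "".join(ref_parts), "".join(oth_parts)
            p = pair(ref, oth)
            ref_len = p.ref_length_aa
            if ref_len < 2:
                continue
            start = int(rng.integers(1, ref_len))
            end = int(rng.integers(start, ref_len + 1))
            sub = extract_domain_region(p, start, end)
            exp_ref, exp_oth = extract_region_oracle(ref, oth, start, end)
            assert (sub.ref_seq, sub.oth_seq) == (exp_ref, exp_oth)


class TestEstimateDnds:
    def test_identical_sequences(self):
        est = estimate_dnds(pair("TTTAAACCC", "TTTAAACCC"))
        assert est.nd == est.sd == 0.0
        assert est.dn == est.ds == 0.0
        assert not est.omega_defined

    def test_single_nonsynonymous_difference(self):
        est = estimate_dnds(pair("TTTTTT", "TTATTT"))
        assert est.nd == 1.0 and est.sd == 0.0
        assert est.dn > 0 and est.ds == 0.0

    def test_matches_pathway_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            ref, oth = simulate_codon_pair(int(rng.integers(5, 30)), 0.5, 0.4, rng)
            est = estimate_dnds(pair(ref, oth))
            exp = dnds_oracle(ref, oth)
            for field in ("n_sites", "s_sites", "nd", "sd", "dn", "ds"):
                assert getattr(est, field) == pytest.approx(exp[field]), field

    def test_swapping_sequences_leaves_rates_unchanged(self, rng):
        ref, oth = simulate_codon_pair(100, 0.3, 0.5, rng)
        a = estimate_dnds(pair(ref, oth))
        b = estimate_dnds(pair(oth, ref))
        assert a.dn == pytest.approx(b.dn)
        assert a.ds == pytest.approx(b.ds)

    def test_gapped_columns_are_skipped(self):
        est = estimate_dnds(pair("TTT---AAA", "TTTCCCAAA"))
        assert est.n_sites + est.s_sites == pytest.approx(6.0)

    def test_no_comparable_codons_raises(self):
        with pytest.raises(ValueError):
            estimate_dnds(pair("---", "AAA"))

    def test_rates_increase_with_divergence(self, rng):
        ds_values = [0.05, 0.2, 0.6]
        estimates = []
        for ds in ds_values:
            r, o = simulate_codon_pair(800, 0.3, ds, np.random.default_rng(5))
            estimates.append(estimate_dnds(pair(r, o)))
        assert estimates[0].ds < estimates[1].ds < estimates[2].ds
        assert estimates[0].dn < estimates[1].dn < estimates[2].dn


class TestFilters:
    @pytest.mark.parametrize(
        "length,dn,ds,expected",
        [
            (59, 0.1, 0.3, False),   # too short
            (60, 0.5, 2.0, True),    # boundaries keep
            (100, 0.6, 0.3, False),  # dN too high
            (100, 0.1, 2.1, False),  # dS too high
            (100, 0.1, 0.3, True),
        ],
    )
    def test_boundaries_inclusive_on_keep_side(self, length, dn, ds, expected):
        est = RateEstimate("x", length, 100, 50, 1, 1, 0.01, 0.02, dn, ds, dn / ds)
        assert apply_filters(est).pass_filter is expected

    def test_filtered_estimates_are_retained_not_deleted(self):
        est = RateEstimate("x", 10, 100, 50, 1, 1, 0.01, 0.02, 0.9, 0.3, 3.0)
        out = apply_filters(est)
        assert out.occurrence_id == "x" and not out.pass_filter


class TestRelativeDifference:
    def test_closed_form(self):
        assert relative_difference(0.4, 0.1) == pytest.approx(0.75)

    def test_identity_and_antisymmetry(self):
        assert relative_difference(0.3, 0.3) == 0.0
        assert relative_difference(0.1, 0.4) == pytest.approx(-0.75)

    def test_bounded(self, rng):
        for _ in range(200):
            y, o = rng.uniform(0, 2, size=2)
            v = relative_difference(float(y), float(o))
            assert -1.0 <= v <= 1.0
            assert v == pytest.approx(-relative_difference(float(o), float(y)))

    def test_both_zero_is_zero(self):
        assert relative_difference(0.0, 0.0) == 0.0

    def test_undefined_omega_raises(self):
        with pytest.raises(ValueError):
            relative_difference(float("nan"), 0.1)


def make_estimate(nd, sd, n_sites=300.0, s_sites=100.0):
    pn, ps = nd / n_sites, sd / s_sites
    dn = -0.75 * math.log(1 - 4 * pn / 3)
    ds = -0.75 * math.log(1 - 4 * ps / 3)
    return RateEstimate("x", 150, n_sites, s_sites, nd, sd, pn, ps, dn, ds,
                        dn / ds if ds else float("nan"))


class TestPairedBinomial:
    def test_null_exactly_met_gives_high_p(self):
        old = make_estimate(30, 30)
        young = make_estimate(30, 30)
        comp = paired_binomial_test(young, old)
        assert comp.pvalue > 0.5
        assert comp.verdict == "no_difference"

    def test_strong_excess_detected_against_tail_sum_oracle(self):
        # old rates imply p0 = 0.5 on the young domain's site composition
        old = make_estimate(30, 10, n_sites=300, s_sites=100)
        young = make_estimate(50, 5, n_sites=300, s_sites=100)
        comp = paired_binomial_test(young, old)
        p0 = (300 * (30 / 300)) / (300 * (30 / 300) + 100 * (10 / 100))
        assert p0 == pytest.approx(0.75)
        expected = two_sided_binom_p_oracle(50, 55, p0)
        assert comp.pvalue == pytest.approx(expected, rel=1e-6)
        assert comp.verdict == "young_faster"
        assert comp.pvalue < 0.01

    def test_zero_trials_degenerate(self):
        old = make_estimate(30, 10)
        young = make_estimate(0.2, 0.2)
        comp = paired_binomial_test(young, old)
        assert comp.degenerate or comp.verdict == "no_difference"

    def test_degenerate_null_flagged(self):
        old = make_estimate(30, 0.0)
        young = make_estimate(10, 10)
        comp = paired_binomial_test(young, old)
        assert comp.degenerate and comp.verdict == "no_difference"

    def test_exact_under_known_null(self, rng):
        """Drawing young counts from the null p0 itself: rejection <= alpha.

        This isolates the binomial machinery from the noise of estimating the
        null from a finite old region (see the paired-calibration notes in
        docs/methods.md)."""
        old = make_estimate(40, 40, n_sites=400, s_sites=130)
        p0 = (300 * (40 / 400)) / (300 * (40 / 400) + 100 * (40 / 130))
        rej = 0
        n = 2000
        for _ in range(n):
            trials = 60
            k = int(rng.binomial(trials, p0))
            young = make_estimate(k, trials - k, n_sites=300, s_sites=100)
            comp = paired_binomial_test(young, old, alpha=0.01)
            rej += comp.verdict != "no_difference"
        assert rej / n <= 0.02


class TestGroupComparison:
    def test_identical_samples_ks(self):
        res = compare_age_groups({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        row = res.ks_tests.iloc[0]
        assert row["statistic"] == 0.0 and row["pvalue"] == 1.0

    def test_shifted_distributions_detected(self, rng):
        a = list(rng.normal(0.1, 0.02, 200))
        b = list(rng.normal(0.5, 0.02, 200))
        res = compare_age_groups({"a": a, "b": b})
        assert res.ks_tests.iloc[0]["pvalue"] < 1e-5

    def test_small_group_skipped_with_notice(self):
        res = compare_age_groups({"a": [0.1], "b": [0.1, 0.2, 0.3]})
        assert bool(res.ks_tests.iloc[0]["skipped"])

    def test_wilcoxon_on_paired_values(self, rng):
        paired = [(y, y - 0.1) for y in rng.uniform(0.2, 0.5, 50)]
        res = compare_age_groups({"a": [0.1, 0.2]}, paired=paired)
        assert res.wilcoxon_p < 1e-5

    def test_per_type_median_aggregation(self):
        res = compare_age_groups(
            {"a": [0.1, 0.3, 0.5]},
            domain_types_by_group={"a": ["t1", "t1", "t2"]},
        )
        med = res.per_type_medians.set_index("domain_type")["omega"]
        assert med["t1"] == pytest.approx(0.2)
        assert med["t2"] == pytest.approx(0.5)
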