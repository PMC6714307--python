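"""Unit and property tests for the permutation-based somatic caller."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnpipe.somatic import (
    FAIL_FRAC,
    FAIL_P,
    GERMLINE_LIKE,
    LOW_DEPTH,
    REJECTED,
    SOMATIC,
    AlleleDepth,
    CallerParams,
    ConfigurationError,
    MissingAnnotationError,
    PairedSiteCounts,
    UndefinedVAFError,
    VariantAnnotation,
    call_somatic,
    compute_vaf,
    filter_variants,
    permutation_test,
    vaf_frac,
)

SEED = 20190828


def site(t_ref, t_alt, n_ref, n_alt):
    return PairedSiteCounts(
        "chr22", 100, "A", "G", AlleleDepth(t_ref, t_alt), AlleleDepth(n_ref, n_alt)
    )


def hypergeom_tail_oracle(t_depth, t_alt, n_depth, n_alt):
    """Independent enumeration of P(X >= t_alt) over pooled-read reassignments."""
    N = t_depth + n_depth
    K = t_alt + n_alt
    hi = min(K, t_depth)
    return sum(
        math.comb(K, x) * math.comb(N - K, t_depth - x) for x in range(t_alt, hi + 1)
    ) / math.comb(N, t_depth)


class TestVAF:
    @pytest.mark.parametrize(
        "ref,alt,expected", [(10, 10, 0.5), (10, 0, 0.0), (0, 7, 1.0)]
    )
    def test_formula(self, ref, alt, expected):
        assert compute_vaf(AlleleDepth(ref, alt)) == pytest.approx(expected)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(UndefinedVAFError):
            compute_vaf(AlleleDepth(0, 0))

    @pytest.mark.parametrize(
        "vt,vc,expected", [(0.5, 0.0, 1.0), (0.3, 0.3, 0.5), (0.3, 0.1, 0.75)]
    )
    def test_vaf_frac_examples(self, vt, vc, expected):
        assert vaf_frac(vt, vc) == pytest.approx(expected)

    def test_vaf_frac_undefined_at_double_zero(self):
        with pytest.raises(UndefinedVAFError):
            vaf_frac(0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(0.0, 1.0, allow_nan=False),
        b=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_complement_identity(self, a, b):
        """vaf_frac(a,b) + vaf_frac(b,a) == 1 whenever a + b > 0."""
        if a + b > 0:
            assert vaf_frac(a, b) + vaf_frac(b, a) == pytest.approx(1.0, abs=1e-12)


class TestPermutationTest:
    def test_exact_matches_enumeration_oracle(self):
        # tumor 5/5, normal 10/0: the one-sided hypergeometric tail
        s = site(5, 5, 10, 0)
        p = permutation_test(s, method="exact")
        assert p == pytest.approx(hypergeom_tail_oracle(10, 5, 10, 0), abs=1e-14)

    def test_reversed_direction_is_non_significant(self):
        # all alt reads in the normal sample: observed diff is minimal
        assert permutation_test(site(10, 0, 5, 5), method="exact") >= 0.95

    def test_symmetric_site_invariant_under_label_swap(self):
        p1 = permutation_test(site(5, 5, 5, 5), method="exact")
        p2 = permutation_test(site(5, 5, 5, 5), method="exact")
        assert p1 == p2

    def test_mc_agrees_with_exact_at_moderate_depth(self):
        s = site(12, 4, 14, 1)
        p_exact = permutation_test(s, method="exact")
        p_mc = permutation_test(s, n_perm=10_000, seed=SEED, method="mc")
        se = math.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(p_mc - p_exact) < 3 * se + 1e-4

    def test_mc_is_deterministic_given_seed(self):
        s = site(700, 100, 650, 2)  # beyond the default exact cap
        p1 = permutation_test(s, seed=SEED, exact_cap=500)
        p2 = permutation_test(s, seed=SEED, exact_cap=500)
        assert p1 == p2

    def test_zero_depth_propagates(self):
        with pytest.raises(UndefinedVAFError):
            permutation_test(site(0, 0, 5, 5))

    def test_bad_n_perm_rejected(self):
        with pytest.raises(ConfigurationError):
            permutation_test(site(5, 5, 5, 5), n_perm=0)


class TestCallSomatic:
    def test_germline_het_site_rejected_with_fail_p(self):
        calls = call_somatic([site(75, 75, 75, 75)], CallerParams(seed=SEED))
        (c,) = calls
        assert c.verdict == REJECTED
        assert FAIL_P in c.filters and GERMLINE_LIKE in c.filters
        assert c.vaf_frac == pytest.approx(0.5, abs=0.01)

    def test_low_depth_flag_has_precedence_over_vafs(self):
        # normal depth 3 < min_depth 8: rejected regardless of a clean VAF split
        calls = call_somatic([site(50, 50, 3, 0)], CallerParams(min_depth=8, seed=SEED))
        assert LOW_DEPTH in calls[0].filters
        assert calls[0].verdict == REJECTED

    def test_clean_somatic_site_passes(self):
        calls = call_somatic([site(90, 60, 150, 0)], CallerParams(seed=SEED))
        assert calls[0].verdict == SOMATIC
        assert calls[0].filters == frozenset()

    def test_empty_input_gives_empty_output(self):
        assert call_somatic([], CallerParams(seed=SEED)) == []

    def test_order_equivariance(self):
        sites = [site(90, 60, 150, 0), site(75, 75, 75, 75), site(50, 50, 3, 0)]
        fwd = call_somatic(sites, CallerParams(seed=SEED))
        rev = call_somatic(sites[::-1], CallerParams(seed=SEED))
        for a, b in zip(fwd, rev[::-1]):
            assert a.p_perm == b.p_perm and a.verdict == b.verdict

    def test_verdict_iff_no_filters(self):
        sites = [site(90, 60, 150, 0), site(75, 75, 75, 75), site(50, 50, 3, 0)]
        for c in call_somatic(sites, CallerParams(seed=SEED)):
            assert (c.verdict == SOMATIC) == (len(c.filters) == 0)


class TestFilterVariants:
    def _somatic_call(self, pos=100):
        s = PairedSiteCounts(
            "chr22", pos, "A", "G", AlleleDepth(90, 60), AlleleDepth(150, 0)
        )
        return call_somatic([s], CallerParams(seed=SEED))[0]

    @pytest.mark.parametrize(
        "consequence,pop_af,kept",
        [
            ("nonsynonymous", 0.02, False),  # common: fails the <1% rarity rule
            ("synonymous", 0.0, False),  # silent: fails the consequence rule
            ("stop_gain", 0.001, True),
            ("splice", 0.0, True),
            ("nonsynonymous", 0.0, True),
        ],
    )
    def test_rarity_and_consequence_rules(self, consequence, pop_af, kept):
        call = self._somatic_call()
        ann = {call.site.site_id: VariantAnnotation(call.site.site_id, consequence, pop_af)}
        out = filter_variants([call], ann, af_max=0.01)
        assert (len(out) == 1) == kept

    def test_missing_annotation_is_a_hard_error(self):
        call = self._somatic_call()
        with pytest.raises(MissingAnnotationError):
            filter_variants([call], {}, af_max=0.01)

    def test_rejected_calls_do_not_need_annotations(self):
        rejected = call_somatic([site(75, 75, 75, 75)], CallerParams(seed=SEED))
        assert filter_variants(rejected, {}) == []
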