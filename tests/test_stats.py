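"""Tests for the exact binomial test, FDR adjustment, region calling and the
validation statistics.  Oracles are independent implementations: brute-force
enumeration for the exact test, statsmodels for BH, full-permutation
enumeration for the small-sample rank-sum case."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mtrkit.core import MTRProfile, compute_profile
from mtrkit.cds_model import enumerate_possible_variants
from mtrkit.errors import InvalidParameterError
from mtrkit.stats import (
    IntolerantRegion,
    apply_fdr,
    bh_adjust,
    binom_exact_test,
    binom_pmf,
    call_regions,
    low_mtr_enrichment,
    rank_sum_compare,
    test_profile as fill_raw_p,  # alias: avoid pytest collection
)
from mtrkit.synthetic import generate_transcript


def enumeration_oracle(x, n, p):
    """Minimum-likelihood two-sided p-value by exhaustive enumeration."""
    if n == 0:
        return 1.0
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    px = pmf[x]
    return min(1.0, sum(v for v in pmf if v <= px * (1 + 1e-7)))


class TestBinomPmf:
    def test_simple_closed_form(self):
        assert binom_pmf(2, 1, 0.5) == pytest.approx(0.5)

    def test_zero_successes_power(self):
        assert binom_pmf(10, 0, 0.3) == pytest.approx(0.7**10)
        assert binom_pmf(10, 0, 0.3) == pytest.approx(0.0282475249)

    def test_normalization(self):
        total = sum(binom_pmf(25, x, 0.37) for x in range(26))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_large_n_log_space(self):
        # must not under/overflow at n = 1e4
        v = binom_pmf(10_000, 5_000, 0.5)
        assert 0 < v < 1
        assert v == pytest.approx(
            math.exp(
                math.lgamma(10_001) - 2 * math.lgamma(5_001) + 10_000 * math.log(0.5)
            )
        )

    @pytest.mark.parametrize("x,n,p", [(-1, 5, 0.5), (6, 5, 0.5), (1, 5, 1.5)])
    def test_invalid_inputs(self, x, n, p):
        with pytest.raises(InvalidParameterError):
            binom_pmf(n, x, p)


class TestBinomExactTest:
    def test_central_outcome_is_one(self):
        assert binom_exact_test(5, 10, 0.5) == pytest.approx(1.0)

    def test_no_data_convention(self):
        assert binom_exact_test(0, 0, 0.3) == 1.0

    def test_derived_example_against_oracle(self):
        assert binom_exact_test(2, 30, 0.7) == pytest.approx(
            enumeration_oracle(2, 30, 0.7), abs=1e-12
        )

    def test_spot_grid_against_oracle(self):
        # the exhaustive n <= 60 grid lives in the acceptance suite
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 200))
            x = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.05, 0.95))
            assert binom_exact_test(x, n, p) == pytest.approx(
                enumeration_oracle(x, n, p), abs=1e-9
            )

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            binom_exact_test(5, 4, 0.5)
        with pytest.raises(InvalidParameterError):
            binom_exact_test(0, 4, -0.1)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # m = 2 non-NaN tests
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_against_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = int(rng.integers(1, 500))
            p = rng.uniform(size=m)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_properties(self, pvals):
        p = np.array(pvals)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        # monotone: sorting p sorts q
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=100)
        perm = rng.permutation(100)
        q = bh_adjust(p)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-15)


def _profile_with_counts(mis_obs, syn_obs, mis_exp, syn_exp):
    L = len(mis_obs)
    mis_obs = np.asarray(mis_obs, dtype=np.int64)
    syn_obs = np.asarray(syn_obs, dtype=np.int64)
    mis_exp = np.asarray(mis_exp, dtype=np.int64)
    syn_exp = np.asarray(syn_exp, dtype=np.int64)
    n_obs = mis_obs + syn_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = (mis_obs / n_obs) / (mis_exp / (mis_exp + syn_exp))
    mtr = np.where(n_obs == 0, np.nan, mtr)
    return MTRProfile(
        transcript_id="T", window_size=31, n_codons=L,
        mis_obs=mis_obs, syn_obs=syn_obs, mis_exp=mis_exp, syn_exp=syn_exp,
        mtr=mtr,
    )


class TestTestProfile:
    def test_all_na_profile(self):
        prof = _profile_with_counts([0, 0], [0, 0], [9, 9], [3, 3])
        fill_raw_p(prof)
        assert np.all(np.isnan(prof.raw_p))

    def test_derived_window_example(self):
        # window counts (mis_obs=1, syn_obs=14) against expected 210/70:
        # n=15, p=0.75
        prof = _profile_with_counts([1], [14], [210], [70])
        fill_raw_p(prof)
        assert prof.raw_p[0] == pytest.approx(
            enumeration_oracle(1, 15, 0.75), abs=1e-12
        )

    def test_proportion_at_null_gives_large_p(self):
        prof = _profile_with_counts([150], [50], [300], [100])
        fill_raw_p(prof)
        assert prof.raw_p[0] > 0.8


class TestApplyFdrAndRegions:
    def test_joint_scope_one_family(self):
        a = _profile_with_counts([1, 1], [9, 9], [90, 90], [30, 30])
        b = _profile_with_counts([1], [9], [90], [30])
        b.transcript_id = "U"
        fill_raw_p(a)
        fill_raw_p(b)
        apply_fdr([a, b], fdr_threshold=0.1, scope="joint")
        joined = np.concatenate([a.raw_p, b.raw_p])
        expected = bh_adjust(joined)
        np.testing.assert_allclose(
            np.concatenate([a.fdr_q, b.fdr_q]), expected
        )

    def test_per_transcript_scope(self):
        a = _profile_with_counts([1, 1], [9, 9], [90, 90], [30, 30])
        fill_raw_p(a)
        apply_fdr([a], scope="per_transcript")
        np.testing.assert_allclose(a.fdr_q, bh_adjust(a.raw_p))

    def test_unknown_scope_rejected(self):
        with pytest.raises(InvalidParameterError):
            apply_fdr([], scope="banana")

    def _profile_with_q(self, q, mtr):
        L = len(q)
        prof = _profile_with_counts([1] * L, [1] * L, [9] * L, [3] * L)
        prof.fdr_q = np.asarray(q, dtype=float)
        prof.mtr = np.asarray(mtr, dtype=float)
        return prof

    def test_single_run(self):
        prof = self._profile_with_q(
            [0.5, 0.05, 0.05, 0.5], [0.9, 0.5, 0.6, 0.9]
        )
        regions = call_regions([prof], fdr_threshold=0.1)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_codon, r.end_codon) == (2, 3)
        assert r.min_mtr == pytest.approx(0.5)
        assert r.mean_mtr == pytest.approx(0.55)
        assert r.min_fdr_q == pytest.approx(0.05)

    def test_no_significant_codons(self):
        prof = self._profile_with_q([0.5, 0.9], [0.5, 0.5])
        assert call_regions([prof]) == []

    def test_tolerant_direction_excluded(self):
        prof = self._profile_with_q([0.01, 0.01], [1.3, 0.5])
        regions = call_regions([prof])
        assert len(regions) == 1
        assert (regions[0].start_codon, regions[0].end_codon) == (2, 2)

    def test_partition_property(self):
        rng = np.random.default_rng(13)
        q = rng.uniform(size=200)
        mtr = rng.uniform(0.2, 1.4, size=200)
        prof = self._profile_with_q(q, mtr)
        regions = call_regions([prof], fdr_threshold=0.3)
        covered = set()
        for r in regions:
            span = set(range(r.start_codon, r.end_codon + 1))
            assert not (span & covered), "regions overlap"
            covered |= span
            # maximality: flanking codons are not significant-and-depleted
            for edge in (r.start_codon - 1, r.end_codon + 1):
                if 1 <= edge <= 200:
                    k = edge - 1
                    assert not (q[k] < 0.3 and mtr[k] < 1.0)
        want = {i + 1 for i in range(200) if q[i] < 0.3 and mtr[i] < 1.0}
        assert covered == want


class TestRankSum:
    def test_complete_separation(self):
        res = rank_sum_compare([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0

    def test_identical_vectors(self):
        res = rank_sum_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pvalue >= 0.9

    def test_exact_small_sample_vs_enumeration(self):
        a = [0.2, 0.4, 0.6]
        b = [0.5, 0.7, 0.9]
        res = rank_sum_compare(a, b)
        # independent oracle: U statistic by pair counting, p by enumerating
        # all C(6,3)=20 assignments of ranks to group a
        u = sum(1 for x in a for y in b if x > y)
        assert res.u_statistic == u
        pooled = sorted(a + b)
        us = []
        for combo in itertools.combinations(range(6), 3):
            grp = [pooled[i] for i in combo]
            rest = [pooled[i] for i in range(6) if i not in combo]
            us.append(sum(1 for x in grp for y in rest if x > y))
        # two-sided exact p: outcomes as extreme as observed in either tail
        more_extreme = sum(1 for v in us if min(v, 9 - v) <= min(u, 9 - u))
        assert res.pvalue == pytest.approx(more_extreme / len(us))

    def test_one_sided_less(self):
        res = rank_sum_compare([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.pvalue < 0.1

    def test_empty_vector_rejected(self):
        with pytest.raises(InvalidParameterError):
            rank_sum_compare([], [1.0])


class TestLowMtrEnrichment:
    def test_hand_odds_ratio(self):
        # construct score vectors realizing table a=20,b=80,c=5,d=95 at cutoff 0.5
        case = [0.3] * 20 + [0.8] * 80
        ctrl = [0.3] * 5 + [0.8] * 95
        (res,) = low_mtr_enrichment(case, ctrl, cutoffs=(0.5,))
        assert res.table == (20, 80, 5, 95)
        assert res.odds_ratio == pytest.approx(4.75)
        assert res.case_percent == pytest.approx(20.0)
        assert res.control_percent == pytest.approx(5.0)

    def test_identical_distributions_or_near_one(self):
        rng = np.random.default_rng(21)
        scores = rng.uniform(size=2000)
        res = low_mtr_enrichment(scores, scores.copy(), cutoffs=(0.25, 0.5))
        for r in res:
            assert r.odds_ratio == pytest.approx(1.0, abs=0.01)

    def test_zero_cell_haldane_correction(self):
        case = [0.1] * 10
        ctrl = [0.9] * 10
        (res,) = low_mtr_enrichment(case, ctrl, cutoffs=(0.5,))
        assert math.isfinite(res.odds_ratio)
        assert res.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))

    def test_default_cutoffs(self):
        res = low_mtr_enrichment([0.1, 0.9], [0.2, 0.8])
        assert [r.cutoff for r in res] == [0.25, 0.5]


class TestEndToEndStats:
    def test_saturated_transcript_has_no_regions(self):
        import dataclasses as dc

        t = generate_transcript(120, 3)
        possible = enumerate_possible_variants(t)
        observed = [dc.replace(v) for v in possible]
        prof = compute_profile(t, observed, possible, w=31)
        fill_raw_p(prof)
        apply_fdr([prof])
        assert np.all(prof.mtr == 1.0)
        assert call_regions([prof]) == []
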