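import math

import numpy as np
import pytest

from tf3dnet.core_io import ContactMap
from tf3dnet.hic_ccl import (CCLConfig, ccl_heterotypic, ccl_homotypic,
                             ccl_integrated, effective_bin, expected_profile,
                             filter_low_coverage, pair_score_table,
                             rank_normalize)
from conftest import sites_at_bins, symmetric_map

BS = 5000


# ---------------------------------------------------------------------------
# Independent brute-force oracle: enumerates every site pair and recomputes
# merged windows, filters and the expected profile directly from the rules,
# sharing no code with the implementation under test.
# ---------------------------------------------------------------------------

def oracle_expected(cmap):
    n = cmap.n_bins
    vals = np.full(n, np.nan)
    for s in range(n):
        acc = [cmap.normalized[i, i + s] for i in range(n - s)
               if cmap.valid[i] and cmap.valid[i + s]]
        if acc:
            vals[s] = sum(acc) / len(acc)
    return vals


def oracle_pair(cmap, exp_vals, bi, bj, cfg):
    s = abs(bj - bi)
    if s * cmap.bin_size <= cfg.min_separation:
        return None
    sep = s * cmap.bin_size
    size = cfg.merge_rules[0][1]
    for thr, sz in cfg.merge_rules:
        if sep > thr:
            size = sz
    h = (size // cmap.bin_size - 1) // 2
    lo_i, hi_i = bi - h, bi + h
    lo_j, hi_j = bj - h, bj + h
    if lo_i < 0 or lo_j < 0 or hi_i >= cmap.n_bins or hi_j >= cmap.n_bins:
        return None
    obs = exp = raw = 0.0
    for a in range(lo_i, hi_i + 1):
        for b in range(lo_j, hi_j + 1):
            if not (cmap.valid[a] and cmap.valid[b]):
                return None
            obs += cmap.normalized[a, b]
            raw += cmap.raw[a, b]
            e = exp_vals[abs(a - b)]
            if math.isnan(e):
                return None
            exp += e
    if raw <= cfg.min_pair_raw_reads or obs <= 0 or exp <= 0:
        return None
    return math.log(obs / exp)


def oracle_ccl(cmap, query_bins, partner_bins, cfg):
    exp_vals = oracle_expected(cmap)
    out = []
    for qi in query_bins:
        total = 0.0
        for pj in partner_bins:
            if qi == pj:
                continue
            term = oracle_pair(cmap, exp_vals, qi, pj, cfg)
            if term is not None:
                total += term
        out.append(total)
    return np.array(out)


@pytest.fixture
def toy_map(rng):
    return symmetric_map(rng, 100)


class TestFilterLowCoverage:
    def _map_with_totals(self, totals):
        # diagonal-only raw counts give bin_raw_total == the diagonal
        n = len(totals)
        raw = np.diag(np.asarray(totals, dtype=np.int64))
        return ContactMap("chr1", BS, np.ones((n, n)), raw)

    def test_one_third_rule_is_strict(self):
        # median of nonzero totals = 33; 10 < 11 = masked, 11 >= 33/3 kept
        cmap = self._map_with_totals([10, 11, 33, 33, 33])
        out = filter_low_coverage(cmap, 1 / 3)
        assert list(out.valid) == [False, True, True, True, True]

    def test_uniform_map_nothing_masked(self, rng):
        out = filter_low_coverage(symmetric_map(rng, 20), 1 / 3)
        assert out.valid.all()

    def test_all_masked_raises(self):
        n = 4
        raw = np.zeros((n, n), dtype=np.int64)
        raw[0, 0] = 1000
        raw[1, 1] = 1
        cmap = ContactMap("chr1", BS, np.ones((n, n)), raw)
        # only two nonzero bins; with fraction high enough everything with
        # any reads below the cut is masked along with the zero bins
        with pytest.raises(ValueError, match="masked"):
            filter_low_coverage(cmap, 3.0)


class TestExpectedProfile:
    def test_constant_map(self):
        n = 8
        cmap = ContactMap("chr1", BS, np.full((n, n), 2.5),
                          np.full((n, n), 30))
        prof = expected_profile(cmap)
        np.testing.assert_allclose(prof.values, 2.5)

    def test_matches_brute_force(self, toy_map):
        cmap = filter_low_coverage(toy_map, 1 / 3)
        prof = expected_profile(cmap)
        np.testing.assert_allclose(prof.values, oracle_expected(cmap),
                                   rtol=1e-12)

    def test_zeros_count_toward_mean(self):
        n = 6
        norm = np.zeros((n, n))
        norm[0, 5] = norm[5, 0] = 3.0
        cmap = ContactMap("chr1", BS, norm, np.full((n, n), 5))
        prof = expected_profile(cmap)
        assert prof.at(5) == pytest.approx(3.0)  # single pair at s=5
        assert prof.at(4) == pytest.approx(0.0)  # two all-zero pairs


class TestEffectiveBin:
    @pytest.mark.parametrize("sep_bp,size", [
        (50_000, 5_000), (100_000, 5_000), (150_000, 25_000),
        (1_000_000, 25_000), (2_000_000, 55_000)])
    def test_merge_rule_selection(self, sep_bp, size):
        assert CCLConfig().merged_size(sep_bp) == size

    def test_flat_map_obs_exp_ratio_one_at_any_merge_level(self):
        n = 600
        cmap = ContactMap("chr1", BS, np.full((n, n), 1.7),
                          np.full((n, n), 40))
        prof = expected_profile(cmap)
        for sep_bins in (10, 40, 300):
            obs, exp, raw = effective_bin(cmap, prof, 100 * BS,
                                          (100 + sep_bins) * BS)
            assert obs / exp == pytest.approx(1.0, rel=1e-12)

    def test_separation_at_or_below_exclusion_band_invalid(self, toy_map):
        prof = expected_profile(toy_map)
        assert effective_bin(toy_map, prof, 0, 25_000) is None
        assert effective_bin(toy_map, prof, 0, 30_000) is not None


class TestCCLOracle:
    def test_homotypic_matches_brute_force(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 400), 1 / 3)
        prof = expected_profile(cmap)
        cfg = CCLConfig()
        bins = rng.choice(400, size=25, replace=False)
        ss = sites_at_bins(bins)
        vec = ccl_homotypic(ss, ss, cmap, prof, cfg)
        got = dict(zip(vec.sites["start"], vec.ccl))
        expected = oracle_ccl(cmap, np.sort(bins), np.sort(bins), cfg)
        for b, e in zip(np.sort(bins), expected):
            start = b * BS + BS // 2 - 100
            assert got[start] == pytest.approx(e, abs=1e-12)

    def test_heterotypic_matches_brute_force_and_is_asymmetric(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 400), 1 / 3)
        prof = expected_profile(cmap)
        cfg = CCLConfig()
        bins_a = rng.choice(400, size=1, replace=False)
        bins_b = rng.choice(400, size=3, replace=False)
        a = sites_at_bins(bins_a, "A")
        b = sites_at_bins(bins_b, "B")
        v_ab = ccl_heterotypic(a, b, cmap, prof, cfg)
        v_ba = ccl_heterotypic(b, a, cmap, prof, cfg)
        assert len(v_ab) == 1 and len(v_ba) == 3
        np.testing.assert_allclose(
            v_ab.ccl, oracle_ccl(cmap, np.sort(bins_a), np.sort(bins_b), cfg),
            atol=1e-12)
        np.testing.assert_allclose(
            v_ba.ccl, oracle_ccl(cmap, np.sort(bins_b), np.sort(bins_a), cfg),
            atol=1e-12)

    def test_heterotypic_with_self_reduces_to_homotypic(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 200), 1 / 3)
        prof = expected_profile(cmap)
        ss = sites_at_bins(rng.choice(200, size=15, replace=False))
        hom = ccl_homotypic(ss, ss, cmap, prof)
        het = ccl_heterotypic(ss, ss, cmap, prof)
        np.testing.assert_allclose(hom.ccl, het.ccl)


class TestCCLExamples:
    def _flat_map(self, n=80, value=1.0, raw=40):
        return ContactMap("chr1", BS, np.full((n, n), value),
                          np.full((n, n), raw))

    def test_obs_equals_exp_gives_zero(self):
        cmap = self._flat_map()
        prof = expected_profile(cmap)
        ss = sites_at_bins([20, 40])
        vec = ccl_homotypic(ss, ss, cmap, prof)
        np.testing.assert_allclose(vec.ccl, 0.0, atol=1e-12)
        assert list(vec.n_pairs) == [1, 1]

    def test_single_pair_with_obs_twice_exp(self):
        # one query site and one bound partner; double the contact at the
        # single consumed (merged) window -> CCL = ln 2
        n = 80
        norm = np.full((n, n), 1.0)
        norm[20, 40] = norm[40, 20] = 2 * 79 / 78  # windowed exp uses mean
        cmap = ContactMap("chr1", BS, norm, np.full((n, n), 40))
        prof = expected_profile(cmap)
        # at separation 20 bins the expected value is the row mean at s=20
        exp_s = prof.at(20)
        obs = norm[20, 40]
        query = sites_at_bins([20], "A")
        partner = sites_at_bins([40], "B")
        vec = ccl_heterotypic(query, partner, cmap, prof)
        assert vec.ccl[0] == pytest.approx(math.log(obs / exp_s), abs=1e-12)

    def test_low_raw_pair_excluded(self):
        cmap = self._flat_map(raw=15)  # 15 <= 20 at the 5-kb merge level
        prof = expected_profile(cmap)
        ss = sites_at_bins([20, 40])
        vec = ccl_homotypic(ss, ss, cmap, prof)
        assert list(vec.n_pairs) == [0, 0]
        np.testing.assert_allclose(vec.ccl, 0.0)

    def test_homotypic_query_mode_bound(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 120), 1 / 3)
        prof = expected_profile(cmap)
        putative = sites_at_bins([10, 30, 50, 70], bound=False)
        bound = sites_at_bins([30, 70])
        cfg = CCLConfig(homotypic_query="bound")
        vec = ccl_homotypic(putative, bound, cmap, prof, cfg)
        assert len(vec) == 2
        vec_put = ccl_homotypic(putative, bound, cmap, prof)
        assert len(vec_put) == 4


class TestCCLIntegrated:
    def test_single_partner_equals_heterotypic(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 150), 1 / 3)
        prof = expected_profile(cmap)
        a = sites_at_bins(rng.choice(150, 10, replace=False), "A")
        b = sites_at_bins(rng.choice(150, 10, replace=False), "B")
        np.testing.assert_allclose(
            ccl_integrated(a, [b], cmap, prof).ccl,
            ccl_heterotypic(a, b, cmap, prof).ccl)

    def test_additivity_and_order_invariance(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 150), 1 / 3)
        prof = expected_profile(cmap)
        a = sites_at_bins(rng.choice(150, 8, replace=False), "A")
        b = sites_at_bins(rng.choice(150, 8, replace=False), "B")
        c = sites_at_bins(rng.choice(150, 8, replace=False), "C")
        v_bc = ccl_integrated(a, [b, c], cmap, prof)
        v_cb = ccl_integrated(a, [c, b], cmap, prof)
        expected = (ccl_heterotypic(a, b, cmap, prof).ccl
                    + ccl_heterotypic(a, c, cmap, prof).ccl)
        np.testing.assert_allclose(v_bc.ccl, expected, atol=1e-12)
        np.testing.assert_allclose(v_bc.ccl, v_cb.ccl)

    def test_empty_group_raises(self, rng):
        cmap = symmetric_map(rng, 50)
        prof = expected_profile(cmap)
        a = sites_at_bins([5], "A")
        with pytest.raises(ValueError, match="empty"):
            ccl_integrated(a, [], cmap, prof)


class TestCCLProperties:
    def test_scaling_normalized_counts_leaves_ccl_unchanged(self, rng):
        """Obs/Exp is a ratio, so a global rescaling of the normalized map
        cancels."""
        base = symmetric_map(rng, 200)
        scaled = ContactMap("chr1", BS, base.normalized * 7.3, base.raw)
        bins = rng.choice(200, 20, replace=False)
        ss = sites_at_bins(bins)
        v1 = ccl_homotypic(ss, ss, filter_low_coverage(base),
                           expected_profile(filter_low_coverage(base)))
        f2 = filter_low_coverage(scaled)
        v2 = ccl_homotypic(ss, ss, f2, expected_profile(f2))
        np.testing.assert_allclose(v1.ccl, v2.ccl, atol=1e-10)

    def test_no_consumed_pair_within_exclusion_band(self, rng):
        cmap = filter_low_coverage(symmetric_map(rng, 60), 1 / 3)
        prof = expected_profile(cmap)
        table = pair_score_table(cmap, prof, CCLConfig())
        i, j = np.nonzero(np.isfinite(table.log_ratio))
        assert (np.abs(i - j) * BS > 25_000).all()


class TestRankNormalize:
    def test_two_groups(self):
        rank, group = rank_normalize(np.array([1.0, 2.0, 3.0, 4.0]), 2)
        assert list(group) == [0, 0, 1, 1]

    def test_all_ties_single_group(self):
        rank, group = rank_normalize(np.full(6, 3.0), 3)
        assert len(set(rank)) == 1
        assert len(set(group)) == 1

    def test_deciles_of_100_distinct_scores(self, rng):
        scores = rng.permutation(100).astype(float)
        _, group = rank_normalize(scores, 10)
        assert np.bincount(group).tolist() == [10] * 10

    def test_fewer_sites_than_groups_raises(self):
        with pytest.raises(ValueError, match="at least"):
            rank_normalize(np.array([1.0, 2.0]), 10)
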