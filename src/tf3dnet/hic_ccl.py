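"""Chromatin co-localization (CCL) scores from population Hi-C.

For a query locus i and a set of partner binding sites j on the same
chromosome, the homotypic score is

    CCL_i = sum_j ln(Obs_ij / Exp_ij)

where Obs is the normalized contact between the (possibly merged) bins of i
and j and Exp the empirical mean contact at the same separation.  The
heterotypic score HetCCL_{i,A,B} is the same sum with i a site of TF A and j
running over ChIP-seq sites of TF B; it is not symmetric in (A, B).  The
integrated score sums HetCCL over a partner group, assuming additive
effects.

Filter cascade (all configurable, defaults follow the published analysis of
GM12878 at 5-kb resolution):

* bins whose total raw reads fall below one third of the per-chromosome
  median are masked ("less than" is strict);
* the diagonal and 25 kb either side are excluded (pairs closer than five
  5-kb bins);
* bins are merged to 25 kb for loci more than 100 kb apart and to 55 kb for
  loci more than 1 Mb apart ("more than" is strict), windows centered on
  each locus's base bin;
* a pair is consumed only when its merged window holds more than 20 raw
  reads (applied to the merged window's summed raw count).

Pairs with zero observed contact (or zero expectation) contribute nothing
and are tallied in a skipped-pair diagnostic rather than producing -inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import ContactMap, ExpectedProfile, GenomicSiteSet

__all__ = [
    "CCLConfig",
    "SiteScoreVector",
    "filter_low_coverage",
    "expected_profile",
    "effective_bin",
    "PairScoreTable",
    "pair_score_table",
    "ccl_homotypic",
    "ccl_heterotypic",
    "ccl_integrated",
    "rank_normalize",
]


@dataclass(frozen=True)
class CCLConfig:
    min_separation: int = 25_000
    low_coverage_fraction: float = 1.0 / 3.0
    min_pair_raw_reads: int = 20
    # (separation threshold in bp, merged bin size in bp); a rule applies
    # when the pair separation strictly exceeds its threshold
    merge_rules: tuple[tuple[int, int], ...] = (
        (0, 5_000), (100_000, 25_000), (1_000_000, 55_000))
    # the >20-raw-reads rule is applied to the merged window's summed raw
    # count; "base" would apply it to the single base bin-pair instead
    raw_filter_scope: str = "merged_window"
    # query loci for the homotypic score: all putative sites or bound only
    homotypic_query: str = "putative"

    def __post_init__(self):
        thresholds = [t for t, _ in self.merge_rules]
        if thresholds != sorted(thresholds):
            raise ValueError("merge_rules must be sorted by separation threshold")
        base = self.merge_rules[0][1]
        for _, size in self.merge_rules:
            if size % base:
                raise ValueError("merged bin sizes must be multiples of the base bin")

    def merged_size(self, separation_bp: int) -> int:
        size = self.merge_rules[0][1]
        for threshold, s in self.merge_rules:
            if separation_bp > threshold:
                size = s
        return size


@dataclass
class SiteScoreVector:
    """Per-site CCL values for one (query TF, partner) combination."""

    tf_id: str
    partner_id: str
    sites: pd.DataFrame        # chrom, start, end columns of the query sites
    ccl: np.ndarray            # finite scores, one per query site
    n_pairs: np.ndarray        # contributing pairs per site
    n_skipped: int = 0         # zero-Obs / zero-Exp pairs dropped

    def __len__(self) -> int:
        return len(self.ccl)

    @property
    def scores(self) -> np.ndarray:
        return self.ccl


# ---------------------------------------------------------------------------
# Coverage filtering and expected profile
# ---------------------------------------------------------------------------

def filter_low_coverage(cmap: ContactMap, fraction: float | None = None) -> ContactMap:
    """Mask bins with raw coverage below ``fraction`` x chromosome median.

    The median is taken over bins with nonzero raw totals; the comparison is
    strict (< fraction * median masks the bin).
    """
    if fraction is None:
        fraction = CCLConfig().low_coverage_fraction
    totals = cmap.bin_raw_total
    nonzero = totals[totals > 0]
    if len(nonzero) == 0:
        raise ValueError(f"{cmap.chrom}: no raw reads at all")
    median = float(np.median(nonzero))
    valid = cmap.valid & ~(totals < fraction * median)
    if not valid.any():
        raise ValueError(f"{cmap.chrom}: all bins masked by coverage filter")
    return cmap.with_valid(valid)


def expected_profile(cmap: ContactMap) -> ExpectedProfile:
    """Mean normalized contact per separation over unmasked bin pairs.

    Zero entries count toward the mean; separations with no valid pair get
    NaN.  The near-diagonal band is computed like any other separation but
    is never consumed downstream (the 25-kb exclusion removes it).
    """
    n = cmap.n_bins
    valid = cmap.valid
    values = np.full(n, np.nan)
    N = cmap.normalized
    for s in range(n):
        i = np.arange(n - s)
        ok = valid[i] & valid[i + s]
        if ok.any():
            values[s] = N[i[ok], i[ok] + s].mean()
    return ExpectedProfile(cmap.chrom, cmap.bin_size, values)


# ---------------------------------------------------------------------------
# Merged-bin lookup
# ---------------------------------------------------------------------------

def _merged_exp(profile_vals: np.ndarray, s: int, h: int) -> float:
    """Sum of expected values over a (2h+1)x(2h+1) merged window at bin
    separation s: sum over offsets d in [-2h, 2h] of (2h+1-|d|) * profile[s+d]."""
    total = 0.0
    for d in range(-2 * h, 2 * h + 1):
        idx = s + d
        if idx < 0 or idx >= len(profile_vals):
            return math.nan
        total += (2 * h + 1 - abs(d)) * profile_vals[idx]
    return total


def effective_bin(cmap: ContactMap, profile: ExpectedProfile, locus_i: int,
                  locus_j: int, config: CCLConfig = CCLConfig()):
    """(obs, exp, raw) for one locus pair at the merged resolution.

    Returns None for invalid pairs: separation at or below the exclusion
    band, a merged window that runs off the chromosome, touches a masked
    bin, or has an undefined expectation.
    """
    bs = cmap.bin_size
    bi, bj = cmap.bin_of(locus_i), cmap.bin_of(locus_j)
    if bi > bj:
        bi, bj = bj, bi
    s = bj - bi
    sep_bp = s * bs
    if sep_bp <= config.min_separation:
        return None
    size = config.merged_size(sep_bp)
    h = (size // bs - 1) // 2
    n = cmap.n_bins
    if bi - h < 0 or bj + h >= n:
        return None
    wi = slice(bi - h, bi + h + 1)
    wj = slice(bj - h, bj + h + 1)
    if not (cmap.valid[wi].all() and cmap.valid[wj].all()):
        return None
    obs = float(cmap.normalized[wi, wj].sum())
    raw = int(cmap.raw[wi, wj].sum())
    exp = _merged_exp(profile.values, s, h)
    if math.isnan(exp):
        return None
    return obs, exp, raw


# ---------------------------------------------------------------------------
# Precomputed per-bin-pair log-ratio table
# ---------------------------------------------------------------------------

class PairScoreTable:
    """Dense table of ln(Obs/Exp) for every consumable bin pair of one
    chromosome, with all filters applied (NaN = pair not consumable, i.e.
    excluded band / masked window / raw-read filter / zero Obs or Exp).

    ``skipped`` counts pairs that passed the separation, mask and raw-read
    filters but had zero Obs or zero Exp.
    """

    def __init__(self, chrom: str, bin_size: int, log_ratio: np.ndarray,
                 skipped_matrix: np.ndarray):
        self.chrom = chrom
        self.bin_size = bin_size
        self.log_ratio = log_ratio
        self.skipped_matrix = skipped_matrix
        self.finite = np.isfinite(log_ratio)
        self.score_filled = np.where(self.finite, log_ratio, 0.0)

    @property
    def n_bins(self) -> int:
        return self.log_ratio.shape[0]

    def bin_of(self, pos) -> np.ndarray:
        return np.asarray(pos, dtype=np.int64) // self.bin_size

    def partner_sums(self, partner_bins: np.ndarray):
        """For every bin b: sum and count of finite scores against the given
        partner bins (bins may repeat; repeats count multiply)."""
        cnt = np.bincount(partner_bins, minlength=self.n_bins).astype(np.float64)
        sums = self.score_filled @ cnt
        npairs = self.finite @ cnt
        nskip = self.skipped_matrix @ cnt
        return sums, npairs.astype(np.int64), nskip


def pair_score_table(cmap: ContactMap, profile: ExpectedProfile,
                     config: CCLConfig = CCLConfig()) -> PairScoreTable:
    """Vectorized construction of the ln(Obs/Exp) table.

    Merged-window sums are taken from a summed-area table so the whole
    table costs O(n_bins^2) regardless of merge level.
    """
    n = cmap.n_bins
    bs = cmap.bin_size
    N, R, valid = cmap.normalized, cmap.raw, cmap.valid
    Rf = R.astype(np.float64)  # integer sums stay exact in float64

    def box_matrix(M, h):
        # separable sliding-window box sums by shifted-slice accumulation
        # (no large-sum cancellation, unlike a summed-area table):
        # out[i - h, j - h] = sum of the (2h+1) x (2h+1) block at (i, j)
        if h == 0:
            return M
        w = 2 * h + 1
        m = M.shape[1] - w + 1
        rows = M[:, :m].copy()
        for k in range(1, w):
            rows += M[:, k:k + m]
        out = rows[:m, :].copy()
        for k in range(1, w):
            out += rows[k:k + m, :]
        return out

    # valid_run[h][i] == True when bins [i-h, i+h] are all valid and in range
    half_widths = sorted({(size // bs - 1) // 2 for _, size in config.merge_rules})
    valid_run = {}
    for h in half_widths:
        ok = np.zeros(n, dtype=bool)
        if 2 * h + 1 <= n:
            window_ok = (np.convolve(valid.astype(int), np.ones(2 * h + 1,
                         dtype=int), mode="valid") == 2 * h + 1)
            ok[h:n - h] = window_ok
        valid_run[h] = ok

    log_ratio = np.full((n, n), np.nan)
    skipped = np.zeros((n, n), dtype=np.float64)
    min_sep_bins = config.min_separation // bs
    pv = profile.values

    # group separations by merge level so each box-sum matrix is built once
    seps_by_h: dict[int, list[int]] = {}
    for s in range(min_sep_bins + 1, n):
        size = config.merged_size(s * bs)
        seps_by_h.setdefault((size // bs - 1) // 2, []).append(s)

    for h, seps in seps_by_h.items():
        if 2 * h + 1 > n:
            continue
        box_n = box_matrix(N, h)
        box_r = box_matrix(Rf, h)
        # merged expectation per separation, vectorized:
        # E_h[s] = sum_{d=-2h..2h} (2h+1-|d|) * profile[s+d] (NaN off-range)
        w = 2 * h + 1
        weights = (w - np.abs(np.arange(-2 * h, 2 * h + 1))).astype(float)
        padded = np.full(n + 4 * h, np.nan)
        padded[2 * h:2 * h + n] = pv
        exp_by_sep = np.correlate(padded, weights, mode="valid")

        i = np.concatenate([np.arange(h, max(n - s - h, h)) for s in seps]) \
            if seps else np.zeros(0, dtype=np.int64)
        if len(i) == 0:
            continue
        s_rep = np.concatenate([np.full(max(n - s - 2 * h, 0), s,
                                        dtype=np.int64) for s in seps])
        j = i + s_rep
        exp = exp_by_sep[s_rep]
        ok = valid_run[h][i] & valid_run[h][j] & np.isfinite(exp)
        i, j, exp = i[ok], j[ok], exp[ok]
        if len(i) == 0:
            continue
        obs = box_n[i - h, j - h]
        if config.raw_filter_scope == "merged_window":
            raw = box_r[i - h, j - h]
        else:
            raw = Rf[i, j]
        pass_raw = raw > config.min_pair_raw_reads
        consumable = pass_raw & (obs > 0) & (exp > 0)
        skip = pass_raw & ~consumable
        ii, jj = i[consumable], j[consumable]
        vals = np.log(obs[consumable] / exp[consumable])
        log_ratio[ii, jj] = vals
        log_ratio[jj, ii] = vals
        si, sj = i[skip], j[skip]
        skipped[si, sj] = 1.0
        skipped[sj, si] = 1.0
    return PairScoreTable(cmap.chrom, bs, log_ratio, skipped)


# ---------------------------------------------------------------------------
# CCL scores
# ---------------------------------------------------------------------------

def _sites_frame(sites) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [s.chrom for s in sites],
        "start": [s.start for s in sites],
        "end": [s.end for s in sites],
    })


def _score_sites(query_sites, partner_sites, tables: dict[str, PairScoreTable],
                 tf_id: str, partner_id: str) -> SiteScoreVector:
    """Sum ln(Obs/Exp) over same-chromosome partners for each query site.

    Near-diagonal (and hence same-bin) pairs carry NaN in the table, so a
    query never pairs with itself or with partners in its own bin.
    """
    ccl = np.zeros(len(query_sites))
    n_pairs = np.zeros(len(query_sites), dtype=np.int64)
    n_skipped = 0
    by_chrom_partners: dict[str, np.ndarray] = {}
    for chrom, table in tables.items():
        centers = np.array([s.center for s in partner_sites if s.chrom == chrom],
                           dtype=np.int64)
        if len(centers):
            by_chrom_partners[chrom] = table.bin_of(centers)
    sums_cache = {}
    for chrom, pbins in by_chrom_partners.items():
        sums_cache[chrom] = tables[chrom].partner_sums(pbins)
    for k, site in enumerate(query_sites):
        cached = sums_cache.get(site.chrom)
        if cached is None:
            continue
        sums, npairs, nskip = cached
        b = site.center // tables[site.chrom].bin_size
        if b < 0 or b >= len(sums):
            continue
        ccl[k] = sums[b]
        n_pairs[k] = npairs[b]
        n_skipped += int(nskip[b])
    return SiteScoreVector(tf_id, partner_id, _sites_frame(query_sites),
                           ccl, n_pairs, n_skipped)


def _tables_for(maps, profiles, config) -> dict[str, PairScoreTable]:
    if isinstance(maps, PairScoreTable):
        return {maps.chrom: maps}
    if isinstance(maps, dict) and maps and \
            isinstance(next(iter(maps.values())), PairScoreTable):
        return maps
    if isinstance(maps, ContactMap):
        maps = {maps.chrom: maps}
        profiles = {profiles.chrom: profiles} \
            if isinstance(profiles, ExpectedProfile) else profiles
    return {chrom: pair_score_table(cmap, profiles[chrom], config)
            for chrom, cmap in maps.items()}


def ccl_homotypic(putative: GenomicSiteSet, bound: GenomicSiteSet, maps,
                  profiles=None, config: CCLConfig = CCLConfig()) -> SiteScoreVector:
    """Homotypic CCL: each query site of a TF against the ChIP-seq
    identified sites of the same TF on the same chromosome.

    Query loci default to all putative sites (config.homotypic_query =
    "bound" restricts to ChIP-identified ones).
    """
    tables = _tables_for(maps, profiles, config)
    query = list(bound if config.homotypic_query == "bound" else putative)
    return _score_sites(query, list(bound), tables, putative.tf_id,
                        putative.tf_id)


def ccl_heterotypic(sites_a: GenomicSiteSet, bound_b: GenomicSiteSet, maps,
                    profiles=None,
                    config: CCLConfig = CCLConfig()) -> SiteScoreVector:
    """HetCCL_{i,A,B} for every site i of TF A against ChIP-seq sites of B.

    Asymmetric by construction; call twice (swapping arguments) for the
    B->A direction.
    """
    tables = _tables_for(maps, profiles, config)
    return _score_sites(list(sites_a), list(bound_b), tables,
                        sites_a.tf_id, bound_b.tf_id)


def ccl_integrated(sites_a: GenomicSiteSet, bound_sets: list[GenomicSiteSet],
                   maps, profiles=None,
                   config: CCLConfig = CCLConfig()) -> SiteScoreVector:
    """SumHetCCL_{i,AG}: additive heterotypic score over a partner group G."""
    if not bound_sets:
        raise ValueError("partner group G must not be empty")
    tables = _tables_for(maps, profiles, config)
    total = None
    for bset in bound_sets:
        v = ccl_heterotypic(sites_a, bset, tables, config=config)
        if total is None:
            total = v
            total = SiteScoreVector(sites_a.tf_id,
                                    "+".join(sorted(b.tf_id for b in bound_sets)),
                                    v.sites, v.ccl.copy(), v.n_pairs.copy(),
                                    v.n_skipped)
        else:
            total.ccl += v.ccl
            total.n_pairs += v.n_pairs
            total.n_skipped += v.n_skipped
    return total


def rank_normalize(scores, n_groups: int = 10):
    """Fractional ranks in (0, 1) (mid-rank convention, average for ties)
    and quantile-group indices.

    group = floor(rank * n_groups) clipped to n_groups - 1, so 100 distinct
    scores at n_groups=10 give exactly 10 per decile.
    """
    values = scores.ccl if isinstance(scores, SiteScoreVector) \
        else np.asarray(scores, dtype=float)
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if len(values) < n_groups:
        raise ValueError(f"need at least {n_groups} sites for {n_groups} groups")
    rank = (rankdata(values, method="average") - 0.5) / len(values)
    group = np.minimum((rank * n_groups).astype(int), n_groups - 1)
    return rank, group
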