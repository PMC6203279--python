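"""Occupancy statistics and matched-site binding-strength comparisons.

Occupancy of a group of putative sites is the fraction carrying a ChIP-seq
identified peak; its error bar is the standard deviation over 1000
resamples each omitting a random third of the TF's sites.  Contrasts of
bound fractions between score terciles use a G-test with Williams'
correction or a chi-square test with Yates' continuity correction, with
Benjamini-Hochberg adjustment across TFs.  SignalValue comparisons pair
sites with identical sequence keys and identical mark/accessibility
context, difference their per-TF rank-normalized SignalValues, and assess
the paired shift with a Wilcoxon signed-rank test against a random
re-pairing control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomicSite, GenomicSiteSet
from .hic_ccl import SiteScoreVector

__all__ = [
    "OccupancyTable",
    "MatchedPair",
    "occupancy",
    "pct_change",
    "gtest_williams",
    "chisq_yates",
    "tercile_contrast",
    "tercile_contrast_table",
    "match_signal_pairs",
    "rank_sum_compare",
    "separation_profile",
]


@dataclass
class OccupancyTable:
    table: pd.DataFrame  # group, n_putative, n_bound, occupancy, sd_resample

    def occupancy_of(self, group) -> float:
        row = self.table[self.table["group"] == group]
        return float(row["occupancy"].iloc[0])


@dataclass(frozen=True)
class MatchedPair:
    site_high: GenomicSite
    site_low: GenomicSite
    matched_on: frozenset
    delta_signal: float


def _site_key(s: GenomicSite):
    return (s.chrom, s.start, s.end, s.strand)


def occupancy(putative: GenomicSiteSet, bound: GenomicSiteSet,
              grouping, n_resample: int = 1000,
              drop_fraction: float = 1.0 / 3.0, seed: int = 0) -> OccupancyTable:
    """Occupancy (bound / putative) per group with resampling SD.

    ``grouping`` assigns one group label per putative site.  Every bound
    site must be present among the putative ones.  Empty groups are
    reported with NaN occupancy.
    """
    grouping = np.asarray(grouping)
    if len(grouping) != len(putative):
        raise ValueError("grouping must label every putative site")
    bound_keys = {_site_key(s) for s in bound}
    unknown = bound_keys - {_site_key(s) for s in putative}
    if unknown:
        raise ValueError(f"{len(unknown)} bound sites are not in the putative set")
    is_bound = np.array([_site_key(s) in bound_keys for s in putative])
    rng = np.random.default_rng(seed)
    n = len(putative)
    n_drop = int(round(n * drop_fraction))
    rows = []
    groups = pd.unique(grouping)
    group_masks = {g: grouping == g for g in groups}
    resampled = np.zeros((n_resample, len(groups)))
    for t in range(n_resample):
        dropped = rng.choice(n, size=n_drop, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[dropped] = False
        for gi, g in enumerate(groups):
            m = group_masks[g] & keep
            resampled[t, gi] = (is_bound[m].mean() if m.any() else np.nan)
    for gi, g in enumerate(groups):
        m = group_masks[g]
        n_put = int(m.sum())
        n_b = int(is_bound[m].sum())
        occ = n_b / n_put if n_put else math.nan
        sd = float(np.nanstd(resampled[:, gi])) if n_put else math.nan
        rows.append({"group": g, "n_putative": n_put, "n_bound": n_b,
                     "occupancy": occ, "sd_resample": sd})
    return OccupancyTable(pd.DataFrame(rows))


def pct_change(start: float, end: float) -> float:
    """Percentage change Delta = 100 * (end - start) / start."""
    if start == 0:
        raise ValueError("start must be nonzero")
    return 100.0 * (end - start) / start


# ---------------------------------------------------------------------------
# 2x2 contrasts
# ---------------------------------------------------------------------------

def gtest_williams(table: np.ndarray):
    """G-test of independence on a 2x2 table with Williams' correction.

    q = 1 + (N/r1 + N/r2 - 1)(N/c1 + N/c2 - 1) / (6 N df); G_adj = G / q.
    Zero margins give (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    n = t.sum()
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        return 0.0, 1.0
    expected = np.outer(r, c) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * np.log(t / expected), 0.0)
    g = 2.0 * terms.sum()
    q = 1.0 + (n / r[0] + n / r[1] - 1.0) * (n / c[0] + n / c[1] - 1.0) \
        / (6.0 * n * 1.0)
    g_adj = g / q
    return float(g_adj), float(stats.chi2.sf(g_adj, df=1))


def chisq_yates(table: np.ndarray):
    """Chi-square test with Yates' continuity correction on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=True)
    return float(chi2), float(p)


def tercile_contrast(scores, bound_flags, test: str = "gtest_williams"):
    """Bound-fraction contrast between the top and bottom score terciles.

    Returns (fractional increase of the bound fraction, statistic, p).
    The fractional increase is (top - bottom) / bottom occupancy.
    """
    values = scores.ccl if isinstance(scores, SiteScoreVector) \
        else np.asarray(scores, dtype=float)
    bound_flags = np.asarray(bound_flags, dtype=bool)
    lo_cut, hi_cut = np.quantile(values, [1 / 3, 2 / 3])
    bottom = values <= lo_cut
    top = values > hi_cut
    table = np.array([
        [int((bound_flags & top).sum()), int((~bound_flags & top).sum())],
        [int((bound_flags & bottom).sum()), int((~bound_flags & bottom).sum())],
    ], dtype=float)
    if test == "gtest_williams":
        stat, p = gtest_williams(table)
    elif test == "chisq_yates":
        stat, p = chisq_yates(table)
    else:
        raise ValueError(f"unknown test {test!r}")
    occ_top = table[0, 0] / table[0].sum() if table[0].sum() else math.nan
    occ_bot = table[1, 0] / table[1].sum() if table[1].sum() else math.nan
    frac_inc = ((occ_top - occ_bot) / occ_bot
                if occ_bot and not math.isnan(occ_bot) else math.nan)
    return frac_inc, stat, p


def tercile_contrast_table(per_tf: dict, test: str = "gtest_williams",
                           min_sites_per_tercile: int = 300) -> pd.DataFrame:
    """Tercile contrasts across TFs with BH adjustment.

    ``per_tf`` maps tf_id -> (scores, bound_flags); TFs whose terciles fall
    below ``min_sites_per_tercile`` sites are skipped (the published run
    required > 300 peaks per score group).
    """
    rows = []
    for tf, (scores, flags) in per_tf.items():
        values = scores.ccl if isinstance(scores, SiteScoreVector) \
            else np.asarray(scores, dtype=float)
        tercile_n = len(values) // 3
        if tercile_n < min_sites_per_tercile:
            continue
        frac_inc, stat, p = tercile_contrast(values, flags, test)
        rows.append({"tf_id": tf, "frac_increase": frac_inc,
                     "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Sequence-matched SignalValue comparison
# ---------------------------------------------------------------------------

DEFAULT_MATCH_CRITERIA = ("sequence", "marks", "dhs", "methylation")


def match_signal_pairs(sites: GenomicSiteSet, group_flags, context: dict,
                       criteria=DEFAULT_MATCH_CRITERIA, seed: int = 0,
                       n_control: int = 1):
    """Pair high/low-group sites with identical sequence and context and
    compare their rank-normalized SignalValues.

    ``group_flags``: True = high group, False = low group, one per site.
    ``context`` maps each matching criterion (beyond "sequence") to a
    per-site value: "marks" a hashable mark combination, "dhs" and
    "methylation" booleans, "subcompartment" a label.  All qualifying
    cross-group pairings are retained.  Returns (pairs, result dict with
    the Wilcoxon signed-rank p and the re-pairing control deltas).
    """
    group_flags = np.asarray(group_flags, dtype=bool)
    site_list = list(sites)
    if len(group_flags) != len(site_list):
        raise ValueError("group_flags must label every site")
    signals = np.array([s.signal_value for s in site_list], dtype=float)
    frac = ((stats.rankdata(signals, method="average") - 0.5) / len(signals)
            if len(signals) else signals)

    def ctx_key(i):
        parts = []
        for crit in criteria:
            if crit == "sequence":
                key = site_list[i].sequence_key
                if key is None:
                    raise ValueError("sites must carry a sequence_key")
                parts.append(key)
            else:
                parts.append(context[crit][i])
        return tuple(parts)

    buckets: dict = {}
    for i in range(len(site_list)):
        if criteria and "dhs" in criteria and not context["dhs"][i]:
            continue
        if criteria and "methylation" in criteria and context["methylation"][i]:
            continue
        buckets.setdefault(ctx_key(i), {True: [], False: []})[
            bool(group_flags[i])].append(i)

    pairs = []
    hi_idx, lo_idx = [], []
    for key, sides in buckets.items():
        for hi in sides[True]:
            for lo in sides[False]:
                pairs.append(MatchedPair(site_list[hi], site_list[lo],
                                         frozenset(criteria),
                                         float(frac[hi] - frac[lo])))
                hi_idx.append(hi)
                lo_idx.append(lo)
    result = {"n_pairs": len(pairs), "p": math.nan,
              "mean_delta": math.nan, "control_deltas": np.zeros(0)}
    if not pairs:
        return pairs, result
    deltas = np.array([p.delta_signal for p in pairs])
    result["mean_delta"] = float(deltas.mean())
    if (deltas != 0).any():
        result["p"] = float(stats.wilcoxon(deltas,
                                           zero_method="zsplit").pvalue)
    else:
        result["p"] = 1.0
    # control: pool both members of every pair and re-pair at random, so
    # group identity is destroyed and the expected delta is zero
    rng = np.random.default_rng(seed)
    pool = np.concatenate([frac[np.asarray(hi_idx)], frac[np.asarray(lo_idx)]])
    n_pairs = len(pairs)
    controls = []
    for _ in range(max(1, n_control)):
        perm = rng.permutation(pool)
        controls.append(perm[:n_pairs] - perm[n_pairs:])
    result["control_deltas"] = np.concatenate(controls)
    return pairs, result


# ---------------------------------------------------------------------------
# Rank-sum comparison and separation profiles
# ---------------------------------------------------------------------------

def rank_sum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return 1.0
    method = "exact" if (len(a) <= 25 and len(b) <= 25) else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def separation_profile(sites: GenomicSiteSet, anchors):
    """Signed distances from sites to their nearest anchor (TSS/CTCF).

    distance = site_center - anchor_position; the nearest anchor by
    absolute distance wins, ties to the left anchor.  Returns a dict with
    per-site signed distances, the cumulative curve over absolute
    distances, and the mean absolute deviation of the signed distances.
    """
    by_chrom: dict[str, list] = {}
    for entry in anchors:
        chrom, pos = entry[0], entry[1]
        by_chrom.setdefault(chrom, []).append(int(pos))
    if not by_chrom:
        raise ValueError("anchors must be nonempty")
    by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    dists = []
    skipped = 0
    for s in sites:
        pos = by_chrom.get(s.chrom)
        if pos is None:
            skipped += 1
            continue
        c = s.center
        k = int(np.searchsorted(pos, c))
        cands = [pos[i] for i in (k - 1, k) if 0 <= i < len(pos)]
        # nearest by absolute distance; ties to the left (smaller) anchor
        best = min(cands, key=lambda a: (abs(c - a), a))
        dists.append(c - best)
    dists = np.asarray(dists, dtype=float)
    absd = np.sort(np.abs(dists))
    cum = (np.arange(1, len(absd) + 1) / len(absd)) if len(absd) else absd
    mad = float(np.mean(np.abs(dists - dists.mean()))) if len(dists) else math.nan
    return {"signed_distances": dists, "cumulative_x": absd,
            "cumulative_y": cum, "mad": mad, "n_skipped": skipped}
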