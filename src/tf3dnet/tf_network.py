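"""Permutation null models, significant TF-pair calling, contact-enrichment
(CE) scores and proximity sub-network clustering.

The null for direction A->B permutes the binding sites of all available TFs
except B within each stratum (chromosome, or sub-compartment x chromosome),
keeping each TF's per-stratum site count and TF B's sites fixed.  The CE
score is a signed Kullback-Leibler divergence between the observed and
permuted CCL-score histograms on unit-width bins; the sign follows the
direction of the observed median shift.  TF pairs cluster on the distance

    d(A, B) = exp(-(CE_AB + CE_BA) / 2)

with Ward or average linkage; cluster labels come from an adaptive cut
(height scan maximizing the silhouette subject to a minimum cluster size)
with a fixed k=2 fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .core_io import CompartmentAnnotation, GenomicSite, GenomicSiteSet
from .hic_ccl import PairScoreTable, SiteScoreVector

__all__ = [
    "PermutationNull",
    "PairMatrix",
    "ClusterResult",
    "permute_sites",
    "heterotypic_null",
    "heterotypic_nulls_vs_partner",
    "direction_result",
    "call_significant_pairs",
    "ce_score",
    "ce_distance_matrix",
    "cluster_tfs",
    "rank_pairs",
    "min_site_filter",
]


@dataclass
class PermutationNull:
    """Permuted per-site score vectors for one direction (A given B)."""

    scores: np.ndarray          # (n_perm, n_query_sites)
    n_perm: int
    stratify_by: str = "chromosome"

    @property
    def pooled(self) -> np.ndarray:
        return self.scores.ravel()


@dataclass
class PairMatrix:
    """TF x TF enrichment matrix (CE is asymmetric; PE symmetric)."""

    tf_ids: list[str]
    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.tf_ids), len(self.tf_ids)):
            raise ValueError("matrix shape does not match tf_ids")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.tf_ids.index(a), self.tf_ids.index(b)])


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: dict[str, int]
    method: str
    cut: str

    def label_array(self, tf_ids) -> np.ndarray:
        return np.array([self.labels[t] for t in tf_ids])


# ---------------------------------------------------------------------------
# Permutations
# ---------------------------------------------------------------------------

def _stratum_key(site: GenomicSite, strata: CompartmentAnnotation | None):
    if strata is None:
        return site.chrom
    return (site.chrom, strata.label_at(site.chrom, site.center))


def permute_sites(site_sets: list[GenomicSiteSet], fixed_tf: str,
                  strata: CompartmentAnnotation | None, n_perm: int,
                  seed: int):
    """Yield ``n_perm`` permuted site lists.

    Within each stratum the pooled positions of all non-fixed TFs are
    reassigned to TF labels, preserving each TF's per-stratum count; the
    fixed TF is returned untouched.  Single-site strata cannot move and are
    left as-is.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    fixed = [ss for ss in site_sets if ss.tf_id == fixed_tf]
    movable = [ss for ss in site_sets if ss.tf_id != fixed_tf]
    # stratum -> ordered list of (tf_index, site)
    pool: dict = {}
    for t, ss in enumerate(movable):
        for site in ss:
            pool.setdefault(_stratum_key(site, strata), []).append((t, site))
    for _ in range(n_perm):
        assigned: list[list[GenomicSite]] = [[] for _ in movable]
        for key, entries in pool.items():
            order = (rng.permutation(len(entries)) if len(entries) > 1
                     else np.arange(len(entries)))
            for (t, _), k in zip(entries, order):
                _, donor = entries[int(k)]
                # the position (and positional attributes) of the donor site
                # is reassigned to TF t's label
                assigned[t].append(GenomicSite(
                    donor.chrom, donor.start, donor.end, donor.strand,
                    movable[t].tf_id, donor.signal_value, donor.motif_pvalue,
                    donor.bound, donor.sequence_key))
        out = [GenomicSiteSet(ss.tf_id, sites, ss.cell_type)
               for ss, sites in zip(movable, assigned)]
        out.extend(fixed)
        yield out


def heterotypic_null(site_sets: list[GenomicSiteSet], tf_a: str, tf_b: str,
                     tables: dict[str, PairScoreTable], n_perm: int,
                     seed: int, strata: CompartmentAnnotation | None = None,
                     bound_only: bool = True):
    """Observed HetCCL_{A,B} plus its permutation null, vectorized.

    Site positions enter only through their contact-map bin, so each
    permutation reduces to a relabelling of pooled bin indices; the per-bin
    partner sums are precomputed once per chromosome.
    """
    by_tf = {ss.tf_id: (ss.bound_sites if bound_only else ss)
             for ss in site_sets}
    if tf_a not in by_tf or tf_b not in by_tf:
        raise ValueError("tf_a and tf_b must be present in site_sets")
    rng = np.random.default_rng(seed)

    # per-chromosome partner sums for TF B (scores only; pair counts are
    # not needed for the null)
    sums_by_chrom = {}
    for chrom, table in tables.items():
        pbins = table.bin_of(by_tf[tf_b].centers(chrom))
        if len(pbins):
            cnt = np.bincount(pbins, minlength=table.n_bins).astype(np.float64)
            sums_by_chrom[chrom] = table.score_filled @ cnt

    def site_scores(bins_by_chrom):
        parts = []
        for chrom, bins in bins_by_chrom:
            sums = sums_by_chrom.get(chrom)
            parts.append(sums[bins] if sums is not None
                         else np.zeros(bins.shape, dtype=float))
        return parts

    # strata: pooled movable-site bins per stratum, with A's slot indices
    obs_chunks: list[np.ndarray] = []       # observed A bins per stratum
    perm_chunks: list[np.ndarray] = []      # (n_perm, n_a) permuted A bins
    chrom_chunks: list[str] = []
    for chrom, table in tables.items():
        strata_keys: dict = {}
        for ss in site_sets:
            if ss.tf_id == tf_b:
                continue
            src = by_tf[ss.tf_id]
            for site in src.on_chrom(chrom):
                key = ("all" if strata is None
                       else strata.label_at(chrom, site.center))
                strata_keys.setdefault(key, {"bins": [], "is_a": []})
                strata_keys[key]["bins"].append(site.center // table.bin_size)
                strata_keys[key]["is_a"].append(ss.tf_id == tf_a)
        for key, d in strata_keys.items():
            bins = np.asarray(d["bins"], dtype=np.int64)
            is_a = np.asarray(d["is_a"], dtype=bool)
            n_a = int(is_a.sum())
            if n_a == 0:
                continue
            obs_chunks.append(bins[is_a])
            if len(bins) > 1:
                perms = np.stack([rng.permutation(bins)[:n_a]
                                  for _ in range(n_perm)])
            else:
                perms = np.tile(bins[:n_a], (n_perm, 1))
            perm_chunks.append(perms)
            chrom_chunks.append(chrom)

    obs_parts = site_scores(zip(chrom_chunks, obs_chunks))
    perm_parts = site_scores(zip(chrom_chunks, perm_chunks))
    obs = (np.concatenate(obs_parts) if obs_parts
           else np.zeros(0))
    perm = (np.concatenate(perm_parts, axis=1) if perm_parts
            else np.zeros((n_perm, 0)))

    sites_df = pd.DataFrame({"chrom": np.repeat(chrom_chunks,
                                                [len(c) for c in obs_chunks])
                             if obs_chunks else []})
    obs_vec = SiteScoreVector(tf_a, tf_b, sites_df, obs,
                              np.zeros(len(obs), dtype=np.int64))
    return obs_vec, PermutationNull(perm, n_perm,
                                    "chromosome" if strata is None
                                    else "subcompartment")


def heterotypic_nulls_vs_partner(site_sets: list[GenomicSiteSet], tf_b: str,
                                 tables: dict[str, PairScoreTable],
                                 n_perm: int, seed: int,
                                 strata: CompartmentAnnotation | None = None,
                                 bound_only: bool = True) -> dict:
    """Observed scores and permutation nulls for every direction (A, B)
    sharing the fixed partner B.

    All non-fixed TFs are permuted jointly (one pooled permutation per
    stratum per draw serves every query TF), which is both the exact null
    of :func:`permute_sites` and much cheaper than drawing per-direction.
    Returns {tf_a: (SiteScoreVector, PermutationNull)}.
    """
    by_tf = {ss.tf_id: (ss.bound_sites if bound_only else ss)
             for ss in site_sets}
    movable = [t for t in by_tf if t != tf_b]
    rng = np.random.default_rng(seed)

    sums_by_chrom = {}
    for chrom, table in tables.items():
        pbins = table.bin_of(by_tf[tf_b].centers(chrom))
        if len(pbins):
            cnt = np.bincount(pbins, minlength=table.n_bins).astype(np.float64)
            sums_by_chrom[chrom] = table.score_filled @ cnt

    obs_parts = {t: [] for t in movable}
    perm_parts = {t: [] for t in movable}
    for chrom, table in tables.items():
        # stratum -> pooled (bins, tf labels)
        pools: dict = {}
        for t in movable:
            for site in by_tf[t].on_chrom(chrom):
                key = ("all" if strata is None
                       else strata.label_at(chrom, site.center))
                pools.setdefault(key, ([], []))
                pools[key][0].append(site.center // table.bin_size)
                pools[key][1].append(t)
        v = sums_by_chrom.get(chrom)
        for key, (bins_l, labels_l) in pools.items():
            bins = np.asarray(bins_l, dtype=np.int64)
            labels = np.asarray(labels_l, dtype=object)
            scores = (v[bins] if v is not None
                      else np.zeros(len(bins)))
            slot = {t: np.flatnonzero(labels == t) for t in movable}
            if len(bins) > 1:
                perm_idx = np.stack([rng.permutation(len(bins))
                                     for _ in range(n_perm)])
            else:
                perm_idx = np.zeros((n_perm, len(bins)), dtype=np.int64)
            perm_scores = scores[perm_idx]      # (n_perm, n_pool)
            for t in movable:
                sl = slot[t]
                if len(sl) == 0:
                    continue
                obs_parts[t].append(scores[sl])
                # slots of TF t receive the pooled sites the permutation
                # routed there
                perm_parts[t].append(perm_scores[:, sl])
    out = {}
    for t in movable:
        obs = (np.concatenate(obs_parts[t]) if obs_parts[t] else np.zeros(0))
        perm = (np.concatenate(perm_parts[t], axis=1) if perm_parts[t]
                else np.zeros((n_perm, 0)))
        vec = SiteScoreVector(t, tf_b, pd.DataFrame(), obs,
                              np.zeros(len(obs), dtype=np.int64))
        out[t] = (vec, PermutationNull(perm, n_perm,
                                       "chromosome" if strata is None
                                       else "subcompartment"))
    return out


# ---------------------------------------------------------------------------
# Significance calling
# ---------------------------------------------------------------------------

def direction_result(obs_scores: SiteScoreVector, null: PermutationNull,
                     top_fracs=(0.20, 0.10, 0.05)) -> dict:
    """Empirical enrichment p-value of high-CCL sites for one direction.

    For each top fraction, the cutoff is the corresponding quantile of the
    pooled null score distribution; the observed count of sites above it is
    compared against the per-permutation counts with the smoothed estimator
    p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    obs = np.asarray(obs_scores.ccl, dtype=float)
    out = {}
    pooled = null.pooled
    for frac in top_fracs:
        cutoff = np.quantile(pooled, 1.0 - frac)
        obs_count = int((obs > cutoff).sum())
        perm_counts = (null.scores > cutoff).sum(axis=1)
        b = int((perm_counts >= obs_count).sum())
        p = (1 + b) / (1 + null.n_perm)
        out[frac] = {
            "p": p,
            "obs_count": obs_count,
            "null_mean_count": float(perm_counts.mean()),
        }
    return out


def call_significant_pairs(directions: dict, fdr: float = 0.05,
                           top_fracs=(0.20, 0.10, 0.05),
                           combine: str = "any") -> pd.DataFrame:
    """Call significantly co-localized TF pairs.

    ``directions`` maps ordered (tf_a, tf_b) to the dict returned by
    :func:`direction_result` (or to an (obs, null) tuple).  BH correction
    runs across all directions separately per top fraction; a direction
    passes per ``combine``: at any fraction ("any"), at all three ("all"),
    or at the middle fraction only ("fraction=0.10").  A pair is significant
    only when both of its directions pass.
    """
    if combine not in ("any", "all", "fraction=0.10"):
        raise ValueError(f"unknown combine rule {combine!r}")
    keys = list(directions)
    results = {}
    for key, val in directions.items():
        results[key] = (direction_result(val[0], val[1], top_fracs)
                        if isinstance(val, tuple) else val)
    fracs = list(next(iter(results.values()))) if results else list(top_fracs)
    # BH per fraction across all directions
    adj = {}
    for frac in fracs:
        pvals = np.array([results[k][frac]["p"] for k in keys])
        adj[frac] = multipletests(pvals, method="fdr_bh")[1] if len(pvals) \
            else pvals
    passes = {}
    for idx, key in enumerate(keys):
        flags = {frac: adj[frac][idx] <= fdr for frac in fracs}
        if combine == "any":
            passes[key] = any(flags.values())
        elif combine == "all":
            passes[key] = all(flags.values())
        else:
            passes[key] = flags[0.10]
    rows = []
    seen = set()
    for a, b in keys:
        pair = tuple(sorted((a, b)))
        if pair in seen or (b, a) not in results:
            continue
        seen.add(pair)
        fa, fb = (a, b), (b, a)
        rows.append({
            "tf_a": pair[0], "tf_b": pair[1],
            "p_ab": min(results[fa][f]["p"] for f in fracs),
            "p_ba": min(results[fb][f]["p"] for f in fracs),
            "fdr_ab": min(adj[f][keys.index(fa)] for f in fracs),
            "fdr_ba": min(adj[f][keys.index(fb)] for f in fracs),
            "pass_ab": passes[fa], "pass_ba": passes[fb],
            "significant": passes[fa] and passes[fb],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CE score (signed KL divergence)
# ---------------------------------------------------------------------------

def ce_score(obs_scores, null_scores, bin_width: float = 1.0) -> float:
    """Signed KL divergence between observed and expected CCL histograms.

    Histograms share unit-width bins (k = floor(score / bin_width)); terms
    with zero observed mass contribute 0; when an observed bin has zero
    expected mass every expected bin receives one pseudo-observation before
    normalization.  Sign is +1 when the observed median is >= the null
    median, else -1.  Natural log.
    """
    obs = np.asarray(obs_scores.ccl if isinstance(obs_scores, SiteScoreVector)
                     else obs_scores, dtype=float)
    null = np.asarray(null_scores.pooled
                      if isinstance(null_scores, PermutationNull)
                      else null_scores, dtype=float)
    if len(obs) == 0 or len(null) == 0:
        raise ValueError("need at least one observed and one null score")
    k_obs = np.floor(obs / bin_width).astype(np.int64)
    k_null = np.floor(null / bin_width).astype(np.int64)
    lo = min(k_obs.min(), k_null.min())
    hi = max(k_obs.max(), k_null.max())
    nbins = int(hi - lo + 1)
    c_obs = np.bincount(k_obs - lo, minlength=nbins).astype(float)
    c_null = np.bincount(k_null - lo, minlength=nbins).astype(float)
    if ((c_obs > 0) & (c_null == 0)).any():
        c_null = c_null + 1.0
    p_obs = c_obs / c_obs.sum()
    p_null = c_null / c_null.sum()
    mask = p_obs > 0
    kl = float(np.sum(p_obs[mask] * np.log(p_obs[mask] / p_null[mask])))
    sign = 1.0 if np.median(obs) >= np.median(null) else -1.0
    return sign * kl


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def ce_distance_matrix(matrix: PairMatrix) -> np.ndarray:
    """Pairwise clustering distance d(A,B) = exp(-(CE_AB + CE_BA)/2).

    Symmetric by construction; the diagonal is set to zero.  Two TFs with
    no enrichment either way (CE = 0) sit at distance 1; mutual enrichment
    of 1 gives e^-1.
    """
    V = matrix.values
    D = np.exp(-(V + V.T) / 2.0)
    np.fill_diagonal(D, 0.0)
    return D


def cluster_tfs(matrix: PairMatrix, method: str = "ward",
                distance: str = "ce_exp", cut: str = "dynamic",
                min_cluster_size: int = 3, k: int = 2) -> ClusterResult:
    """Agglomerative clustering of TFs from a pairwise enrichment matrix.

    ``distance="ce_exp"`` uses d(A,B) = exp(-(CE_AB + CE_BA)/2);
    ``"euclidean"`` uses squared-Euclidean distance between matrix rows.
    The dynamic cut scans candidate heights and keeps the labelling with
    the best silhouette among those whose clusters all reach
    ``min_cluster_size``; if none qualifies, it falls back to k clusters.
    """
    n = len(matrix.tf_ids)
    if n < 3:
        raise ValueError("need at least 3 TFs to cluster")
    V = matrix.values
    if distance == "ce_exp":
        D = ce_distance_matrix(matrix)
    elif distance == "euclidean":
        diff = V[:, None, :] - V[None, :, :]
        D = (diff ** 2).sum(axis=2)
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    D = (D + D.T) / 2.0
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method=method)

    labels = None
    if cut == "dynamic":
        heights = Z[:, 2]
        candidates = np.unique((heights[:-1] + heights[1:]) / 2.0) \
            if len(heights) > 1 else heights
        best = -np.inf
        for h in candidates:
            lab = fcluster(Z, t=h, criterion="distance")
            ngroups = len(np.unique(lab))
            if ngroups < 2 or ngroups >= n:
                continue
            if np.bincount(lab).max() == 0 or \
                    np.bincount(lab)[1:].min() < min_cluster_size:
                continue
            sil = silhouette_score(D, lab, metric="precomputed")
            if sil > best + 1e-12:
                best = sil
                labels = lab
    if labels is None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(Z, dict(zip(matrix.tf_ids, (int(l) for l in labels))),
                         method, cut)


# ---------------------------------------------------------------------------
# Pair ranking and eligibility
# ---------------------------------------------------------------------------

def rank_pairs(directions: dict, frac: float = 0.20) -> pd.DataFrame:
    """Rank TF pairs by the percentage increase of high-proximity sites.

    %delta = 100 * (obs_count - mean_null_count) / mean_null_count summed
    over both directions of a pair; ties break toward the smaller empirical
    p; a zero null mean ranks the pair first with an infinite %delta.
    """
    results = {}
    for key, val in directions.items():
        results[key] = (direction_result(val[0], val[1], (frac,))
                        if isinstance(val, tuple) else val)
    rows = []
    seen = set()
    for a, b in results:
        pair = tuple(sorted((a, b)))
        if pair in seen:
            continue
        seen.add(pair)
        use = [results[(a, b)]]
        if (b, a) in results and a != b:
            use.append(results[(b, a)])
        obs = sum(r[frac]["obs_count"] for r in use)
        exp = sum(r[frac]["null_mean_count"] for r in use)
        p = min(r[frac]["p"] for r in use)
        pct = math.inf if exp == 0 else 100.0 * (obs - exp) / exp
        rows.append({"tf_a": pair[0], "tf_b": pair[1], "pct_delta": pct,
                     "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["pct_delta", "p"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    return df


def min_site_filter(site_sets: list[GenomicSiteSet],
                    strata: CompartmentAnnotation,
                    required_labels=("A1", "A2"),
                    min_sites: int = 300) -> list[str]:
    """TFs eligible for sub-compartment analyses: at least ``min_sites``
    ChIP-identified sites in every required stratum (0 disables)."""
    eligible = []
    for ss in site_sets:
        bound = ss.bound_sites
        counts = {label: 0 for label in required_labels}
        for site in bound:
            label = strata.label_at(site.chrom, site.center)
            if label in counts:
                counts[label] += 1
        if min_sites == 0 or all(c >= min_sites for c in counts.values()):
            eligible.append(ss.tf_id)
    return eligible
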