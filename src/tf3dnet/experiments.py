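"""Canned synthetic experiments: null calibration and planted-signal
recovery.

These bundle the study conditions used to validate the pipeline end to
end: a no-signal calibration (are permutation p-values uniform and the
FDR-controlled caller quiet?), planted two-group recovery through CE and
PE clustering, and planted-pair detection in genome structures.  Problem
sizes are desk-scale stand-ins for the genome-wide inputs: ten TFs at one
site per 80 kb over eight 5-Mb chromosomes for the calibration, and two
eight-TF groups for the recovery experiments.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .hic_ccl import CCLConfig, expected_profile, filter_low_coverage, \
    pair_score_table
from .structure3d import pe_matrix, pe_score, qc_structure
from .synthetic import StructureSpec, SyntheticSpec, TFSpec, \
    make_contact_map, make_structure
from .tf_network import PairMatrix, call_significant_pairs, ce_score, \
    cluster_tfs, direction_result, heterotypic_nulls_vs_partner

__all__ = [
    "score_tables",
    "all_direction_nulls",
    "null_calibration_replicate",
    "null_calibration",
    "planted_ce_recovery",
    "planted_pe_recovery",
    "planted_structure_pair",
]


def score_tables(maps, config: CCLConfig = CCLConfig()):
    """Coverage-filter every map and build its ln(Obs/Exp) table."""
    tables = {}
    for chrom, cmap in maps.items():
        filtered = filter_low_coverage(cmap, config.low_coverage_fraction)
        tables[chrom] = pair_score_table(filtered, expected_profile(filtered),
                                         config)
    return tables


def all_direction_nulls(site_sets, tables, n_perm: int, seed: int,
                        strata=None):
    """(obs, null) for every ordered TF pair, batched per fixed partner."""
    rng = np.random.default_rng(seed)
    directions = {}
    for ss in site_sets:
        b = ss.tf_id
        res = heterotypic_nulls_vs_partner(site_sets, b, tables, n_perm,
                                           seed=int(rng.integers(2 ** 31)),
                                           strata=strata)
        for a, pair in res.items():
            directions[(a, b)] = pair
    return directions


def null_calibration_replicate(seed: int, n_tfs: int = 10,
                               sites_per_tf: int = 500, n_chroms: int = 8,
                               chrom_length: int = 5_000_000,
                               n_perm: int = 200, fdr: float = 0.05,
                               top_frac: float = 0.20):
    """One replicate of the no-planted-signal calibration.

    Returns (direction p-values at ``top_frac``, n significant pairs,
    n pairs tested).
    """
    spec = SyntheticSpec(seed=seed, n_chroms=n_chroms,
                         chrom_length=chrom_length,
                         tf_specs=tuple(TFSpec(f"TF{i:02d}", sites_per_tf)
                                        for i in range(n_tfs)))
    maps, site_sets, _ = make_contact_map(spec)
    tables = score_tables(maps)
    directions = all_direction_nulls(site_sets, tables, n_perm, seed + 1)
    pvals = np.array([direction_result(o, n, (top_frac,))[top_frac]["p"]
                      for o, n in directions.values()])
    calls = call_significant_pairs(directions, fdr=fdr)
    return pvals, int(calls["significant"].sum()), len(calls)


def null_calibration(n_replicates: int = 50, seed: int = 0, **kwargs):
    """Pooled direction p-values and mean false-positive pair fraction."""
    rng = np.random.default_rng(seed)
    pooled = []
    fp_fracs = []
    for _ in range(n_replicates):
        pvals, n_sig, n_pairs = null_calibration_replicate(
            int(rng.integers(2 ** 31)), **kwargs)
        pooled.append(pvals)
        fp_fracs.append(n_sig / n_pairs)
    return np.concatenate(pooled), float(np.mean(fp_fracs))


def _two_group_spec(seed: int, sites_per_tf: int = 150,
                    enrichment: float = 3.0, group_size: int = 8,
                    n_chroms: int = 4, chrom_length: int = 5_000_000,
                    structure_spec: StructureSpec = StructureSpec()):
    g1 = [f"G1_{i}" for i in range(group_size)]
    g2 = [f"G2_{i}" for i in range(group_size)]
    planted = tuple((a, b, enrichment) for g in (g1, g2)
                    for a, b in itertools.combinations(g, 2))
    return SyntheticSpec(
        seed=seed, n_chroms=n_chroms, chrom_length=chrom_length,
        tf_specs=tuple(TFSpec(t, sites_per_tf) for t in g1 + g2),
        planted_pairs=planted, structure_spec=structure_spec), g1, g2


def planted_ce_recovery(seed: int = 5, n_perm: int = 200, **kwargs):
    """Cluster the CE matrix of two planted TF groups; returns (ARI,
    labels, CE matrix)."""
    spec, g1, g2 = _two_group_spec(seed, **kwargs)
    maps, site_sets, _ = make_contact_map(spec)
    tables = score_tables(maps)
    tf_ids = [ss.tf_id for ss in site_sets]
    n = len(tf_ids)
    ce = np.zeros((n, n))
    rng = np.random.default_rng(seed + 1)
    for j, b in enumerate(tf_ids):
        res = heterotypic_nulls_vs_partner(site_sets, b, tables, n_perm,
                                           seed=int(rng.integers(2 ** 31)))
        for i, a in enumerate(tf_ids):
            if a != b:
                ce[i, j] = ce_score(*res[a])
    clus = cluster_tfs(PairMatrix(tf_ids, ce), method="ward",
                       distance="ce_exp")
    truth = [0] * len(g1) + [1] * len(g2)
    labels = clus.label_array(tf_ids)
    return adjusted_rand_score(truth, labels), labels, ce


def planted_pe_recovery(seed: int = 5, n_perm: int = 100, **kwargs):
    """Cluster the PE matrix of two planted structural groups; returns
    (ARI, labels, PE matrix)."""
    spec, g1, g2 = _two_group_spec(seed, **kwargs)
    structure, site_sets = make_structure(spec)
    qc = qc_structure(structure)
    mat, clus = pe_matrix(site_sets, structure, qc, n_perm=n_perm,
                          seed=seed + 1)
    truth = [0] * len(g1) + [1] * len(g2)
    labels = clus.label_array(mat.tf_ids)
    return adjusted_rand_score(truth, labels), labels, mat.values


def planted_structure_pair(seed: int = 3, n_perm: int = 100,
                           sites_per_tf: int = 100, n_background: int = 4):
    """PE of one planted TF pair vs an unrelated background pair.

    Two planted pair components plus random background TFs, so the
    crowding-stratified null retains sites to exchange.  Returns a dict
    with planted and background (pe, p).
    """
    tfs = [TFSpec(t, sites_per_tf) for t in ("A", "B", "C", "D")]
    tfs += [TFSpec(f"bg{i}", sites_per_tf) for i in range(n_background)]
    spec = SyntheticSpec(seed=seed, n_chroms=2, tf_specs=tuple(tfs),
                         planted_pairs=(("A", "B", 3.0), ("C", "D", 3.0)))
    structure, site_sets = make_structure(spec)
    qc = qc_structure(structure)
    by = {ss.tf_id: ss for ss in site_sets}
    pe, p, obs, exp = pe_score(by["A"], by["B"], structure, qc,
                               all_site_sets=site_sets, n_perm=n_perm,
                               seed=seed + 10)
    pe_bg, p_bg, *_ = pe_score(by["bg0"], by["bg1"], structure, qc,
                               all_site_sets=site_sets, n_perm=n_perm,
                               seed=seed + 11)
    return {"planted_pe": pe, "planted_p": p, "background_pe": pe_bg,
            "background_p": p_bg, "obs": obs, "exp": exp}
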