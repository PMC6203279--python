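"""Single-cell genome-structure analyses.

A structure is an ensemble of (typically 10) coordinate models over 100-kb
particles.  Analyses use only particles whose position is consistent across
models (per-particle RMSD < 1 particle radius after rigid-body
superposition), and only site pairs that are proximal in *every* model and
more than three particles apart sequentially (300 kb), to suppress model
noise and trivial sequential clustering.

Homotypic spatial clustering of a TF is measured per particle by the
inverse-cube radial density

    r_i = sum_j n_j / d_ij^3

(n_j = weighted site count of particle j, distances averaged over models)
compared against a circular-permutation null of the site track computed
separately within A and B compartments:

    SDE_i = log2(r_i^0 / r_i)        [as printed; an "enrichment"
                                      orientation log2(r_i / r_i^0) is
                                      available via a switch]

Heterotypic proximity between two TFs is the structural proximity
enrichment

    PE = log2(Obs / Exp)

where Obs counts consistently proximal (A-site, B-site) pairs and Exp is
the mean count over permutations that relabel sites within chromosome x
compartment x crowding-level stratum, preserving compartment totals and the
local crowding of every position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenomeStructure, GenomicSiteSet
from .tf_network import ClusterResult, PairMatrix, cluster_tfs

__all__ = [
    "StructureQC",
    "ProximityPairs",
    "SpatialDensity",
    "qc_structure",
    "consistent_pairs",
    "spatial_density",
    "sde",
    "z_normalize_sde",
    "site_particles",
    "crowding_strata",
    "pe_score",
    "pe_matrix",
]

SEQ_EXCLUSION_PARTICLES = 3     # sequential separation filter (= 300 kb)


@dataclass
class StructureQC:
    rmsd: np.ndarray            # per-particle RMSD to the reference model, in radii
    defined_mask: np.ndarray    # particles with RMSD < 1 radius

    @property
    def coverage_fraction(self) -> float:
        return float(self.defined_mask.mean())


@dataclass
class ProximityPairs:
    """Particle pairs proximal in all models, at one threshold (in radii)."""

    threshold: float
    mode: str                   # all | cis | trans
    pairs: np.ndarray           # (n_pairs, 2) particle indices, i < j
    n_particles: int

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_particles, self.n_particles))
        if len(self.pairs):
            A[self.pairs[:, 0], self.pairs[:, 1]] = 1.0
            A[self.pairs[:, 1], self.pairs[:, 0]] = 1.0
        return A


@dataclass
class SpatialDensity:
    r: np.ndarray
    r0: np.ndarray | None = None
    sde: np.ndarray | None = None
    z_sde: np.ndarray | None = None


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _kabsch_align(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares rigid-body superposition of ``mobile`` onto ``ref``."""
    mc = mobile - mobile.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return mc @ R + ref.mean(axis=0)


def qc_structure(structure: GenomeStructure) -> StructureQC:
    """Per-particle RMSD (in radii) to the first model after superposition.

    A single-model structure passes every particle (with a warning), so the
    all-model consistency filters degenerate to that model.
    """
    M = structure.n_models
    ref = structure.models[0]
    if M < 2:
        warnings.warn("single-model structure: all particles pass QC")
        rmsd = np.zeros(structure.n_particles)
    else:
        sq = np.zeros(structure.n_particles)
        for m in range(M):
            aligned = _kabsch_align(structure.models[m], ref) if m else ref
            sq += ((aligned - ref) ** 2).sum(axis=1)
        rmsd = np.sqrt(sq / M) / structure.radius
    return StructureQC(rmsd, rmsd < 1.0)


# ---------------------------------------------------------------------------
# Consistent proximity
# ---------------------------------------------------------------------------

def _model_max_distance(structure: GenomeStructure) -> np.ndarray:
    """Max over models of pairwise particle distances."""
    P = structure.n_particles
    dmax = np.zeros((P, P))
    for m in range(structure.n_models):
        xyz = structure.models[m]
        diff = xyz[:, None, :] - xyz[None, :, :]
        np.maximum(dmax, np.sqrt((diff ** 2).sum(axis=2)), out=dmax)
    return dmax


def consistent_pairs(structure: GenomeStructure, qc: StructureQC,
                     threshold: float = 3.0, mode: str = "all") -> ProximityPairs:
    """Particle pairs within ``threshold`` radii in every model.

    Same-chromosome pairs must additionally be more than three particles
    apart sequentially; mode "cis" keeps only same-chromosome pairs,
    "trans" only different-chromosome ones.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mode not in ("all", "cis", "trans"):
        raise ValueError(f"unknown mode {mode!r}")
    dmax = _model_max_distance(structure)
    close = dmax <= threshold * structure.radius
    chrom = structure.particles["chrom"].to_numpy()
    seq = structure.seq_index()
    same_chrom = chrom[:, None] == chrom[None, :]
    seq_ok = np.abs(seq[:, None] - seq[None, :]) > SEQ_EXCLUSION_PARTICLES
    keep = close & ((same_chrom & seq_ok) | ~same_chrom)
    if mode == "cis":
        keep &= same_chrom
    elif mode == "trans":
        keep &= ~same_chrom
    ok = qc.defined_mask
    keep &= ok[:, None] & ok[None, :]
    iu, ju = np.nonzero(np.triu(keep, 1))
    return ProximityPairs(threshold, mode,
                          np.column_stack([iu, ju]).astype(np.int64),
                          structure.n_particles)


# ---------------------------------------------------------------------------
# Spatial density and SDE
# ---------------------------------------------------------------------------

def _density_weights(structure: GenomeStructure, qc: StructureQC) -> np.ndarray:
    """W[i, j] = mean over models of 1/d_ij^3 for admissible (i, j); zero for
    excluded pairs (undefined particles, sequential separation <= 300 kb,
    and the diagonal)."""
    P = structure.n_particles
    chrom = structure.particles["chrom"].to_numpy()
    seq = structure.seq_index()
    same_chrom = chrom[:, None] == chrom[None, :]
    admissible = (~same_chrom) | \
        (np.abs(seq[:, None] - seq[None, :]) > SEQ_EXCLUSION_PARTICLES)
    ok = qc.defined_mask
    admissible &= ok[:, None] & ok[None, :]
    np.fill_diagonal(admissible, False)
    W = np.zeros((P, P))
    for m in range(structure.n_models):
        xyz = structure.models[m]
        diff = xyz[:, None, :] - xyz[None, :, :]
        d2 = (diff ** 2).sum(axis=2)
        if (d2[admissible] == 0).any():
            raise ValueError("coincident particles: zero inter-particle distance")
        with np.errstate(divide="ignore"):
            inv3 = np.where(admissible, 1.0 / np.where(d2 > 0, d2, 1.0) ** 1.5,
                            0.0)
        W += inv3
    return W / structure.n_models


def spatial_density(structure: GenomeStructure, qc: StructureQC,
                    track: np.ndarray) -> SpatialDensity:
    """Radial density r_i = sum_j n_j / d_ij^3 (model-averaged)."""
    track = np.asarray(track, dtype=float)
    if len(track) != structure.n_particles:
        raise ValueError("track length must equal the particle count")
    W = _density_weights(structure, qc)
    return SpatialDensity(r=W @ track)


def _circular_offsets(rng, n: int) -> int:
    return int(rng.integers(0, n)) if n > 0 else 0


def sde(structure: GenomeStructure, qc: StructureQC, track: np.ndarray,
        n_perm: int = 100, seed: int = 0,
        orientation: str = "as_printed") -> SpatialDensity:
    """Spatial density enrichment against a circular-permutation null.

    Each permutation rotates the site track by an independent random offset
    along the particles of each chromosome, separately within the A and B
    compartment classes, preserving the sequential/compartment composition.
    ``orientation="as_printed"`` gives log2(r0 / r); ``"enrichment"`` gives
    log2(r / r0).  Particles where either density is zero get NaN and are
    excluded from summaries.
    """
    if structure.compartment is None:
        raise ValueError("structure has no compartment labels")
    if orientation not in ("as_printed", "enrichment"):
        raise ValueError(f"unknown orientation {orientation!r}")
    track = np.asarray(track, dtype=float)
    W = _density_weights(structure, qc)
    r = W @ track
    rng = np.random.default_rng(seed)
    chrom = structure.particles["chrom"].to_numpy()
    comp = structure.compartment
    groups = []
    for c in pd.unique(chrom):
        for label in ("A", "B"):
            idx = np.flatnonzero((chrom == c) & (comp == label))
            if len(idx):
                groups.append(idx)
    r0 = np.zeros_like(r)
    for _ in range(n_perm):
        permuted = track.copy()
        for idx in groups:
            permuted[idx] = np.roll(track[idx], _circular_offsets(rng, len(idx)))
        r0 += W @ permuted
    r0 /= n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((r > 0) & (r0 > 0),
                         r0 / r if orientation == "as_printed" else r / r0,
                         np.nan)
        vals = np.log2(ratio)
    return SpatialDensity(r=r, r0=r0, sde=vals)


def z_normalize_sde(sde_values: np.ndarray, track: np.ndarray) -> np.ndarray:
    """Standardize SDE by the mean/SD of the quartile of particles with the
    lowest sequential site density (those behave most like a random
    normal)."""
    sde_values = np.asarray(sde_values, dtype=float)
    track = np.asarray(track, dtype=float)
    if len(sde_values) < 8:
        raise ValueError("need at least 8 particles to Z-normalize")
    n_ref = max(1, len(track) // 4)
    order = np.argsort(track, kind="mergesort")
    ref = sde_values[order[:n_ref]]
    ref = ref[np.isfinite(ref)]
    mu, sd = float(np.mean(ref)), float(np.std(ref))
    if sd == 0:
        raise ValueError("zero SD in the low-density reference quartile")
    return (sde_values - mu) / sd


# ---------------------------------------------------------------------------
# Site-level proximity enrichment
# ---------------------------------------------------------------------------

def site_particles(sites: GenomicSiteSet, structure: GenomeStructure) -> np.ndarray:
    """Particle index of every site (center containment; -1 = unmapped)."""
    out = np.full(len(sites), -1, dtype=np.int64)
    for k, s in enumerate(sites):
        out[k] = structure.particle_index(s.chrom, s.center)
    return out


def crowding_strata(pairs: ProximityPairs, site_particle_idx: np.ndarray,
                    compartment: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Crowding-level stratum per site.

    N_j = number of sites of any TF at particles consistently proximal to
    site j's particle; within each compartment class the sites split into
    ``n_groups`` equal-sized rank groups (ties and remainders spread from
    the lowest group upward).
    """
    A = pairs.adjacency()
    counts = np.bincount(site_particle_idx[site_particle_idx >= 0],
                         minlength=pairs.n_particles).astype(float)
    per_particle_crowd = A @ counts
    N = per_particle_crowd[site_particle_idx]
    N[site_particle_idx < 0] = -1.0
    strata = np.full(len(N), -1, dtype=np.int64)
    site_comp = np.asarray([compartment[p] if p >= 0 else "none"
                            for p in site_particle_idx], dtype=object)
    for label in ("A", "B"):
        idx = np.flatnonzero((site_comp == label) & (site_particle_idx >= 0))
        if len(idx) == 0:
            continue
        order = idx[np.argsort(N[idx], kind="mergesort")]
        base, extra = divmod(len(order), n_groups)
        sizes = [base + (1 if g < extra else 0) for g in range(n_groups)]
        pos = 0
        for g, size in enumerate(sizes):
            strata[order[pos:pos + size]] = g
            pos += size
    return strata


def _count_proximal_pairs(adj: np.ndarray, cnt_a: np.ndarray,
                          cnt_b: np.ndarray, homotypic: bool) -> float:
    total = float(cnt_a @ adj @ cnt_b)
    return total / 2.0 if homotypic else total


@dataclass
class _PEContext:
    """Shared state for PE scoring: proximity adjacency plus the pooled
    site -> particle assignment and its permutation strata."""

    adj: np.ndarray
    particles: np.ndarray       # particle index per pooled site
    labels: np.ndarray          # tf_id per pooled site
    group_indices: list         # site-index groups (chrom x comp x stratum)
    n_particles: int


def _pe_context(pool_sets, structure, qc, threshold, mode,
                n_crowding_groups) -> _PEContext:
    if structure.compartment is None:
        raise ValueError("structure has no compartment labels")
    pairs = consistent_pairs(structure, qc, threshold, mode)
    if mode == "trans" and len(pairs.pairs) == 0:
        raise ValueError("no trans pairs: structure has a single chromosome "
                         "or no inter-chromosome contacts")
    adj = pairs.adjacency()
    particles = np.concatenate([site_particles(ss, structure)
                                for ss in pool_sets])
    labels = np.concatenate([np.full(len(ss), ss.tf_id, dtype=object)
                             for ss in pool_sets])
    chroms = np.concatenate([[s.chrom for s in ss] for ss in pool_sets])
    mapped = particles >= 0
    particles, labels, chroms = particles[mapped], labels[mapped], chroms[mapped]
    comp = np.asarray([structure.compartment[p] for p in particles],
                      dtype=object)
    strata = crowding_strata(pairs, particles, structure.compartment,
                             n_crowding_groups)
    keys = np.asarray([f"{c}|{co}|{st}" for c, co, st in
                       zip(chroms, comp, strata)])
    group_indices = [np.flatnonzero(keys == key) for key in np.unique(keys)]
    return _PEContext(adj, particles, labels, group_indices,
                      structure.n_particles)


def _pe_from_context(ctx: _PEContext, tf_a: str, tf_b: str, n_perm: int,
                     rng: np.random.Generator, log_base: float):
    homotypic = tf_a == tf_b

    def count(lab):
        cnt_a = np.bincount(ctx.particles[lab == tf_a],
                            minlength=ctx.n_particles).astype(float)
        cnt_b = np.bincount(ctx.particles[lab == tf_b],
                            minlength=ctx.n_particles).astype(float)
        return _count_proximal_pairs(ctx.adj, cnt_a, cnt_b, homotypic)

    obs = count(ctx.labels)
    perm_counts = np.zeros(n_perm)
    for t in range(n_perm):
        lab = ctx.labels.copy()
        for idx in ctx.group_indices:
            if len(idx) > 1:
                lab[idx] = ctx.labels[idx][rng.permutation(len(idx))]
        perm_counts[t] = count(lab)
    exp = float(perm_counts.mean())
    pe = math.nan if exp == 0 else math.log(obs / exp, log_base) \
        if obs > 0 else -math.inf
    p = (1 + int((perm_counts >= obs).sum())) / (1 + n_perm)
    return pe, p, obs, exp


def pe_score(sites_a: GenomicSiteSet, sites_b: GenomicSiteSet,
             structure: GenomeStructure, qc: StructureQC,
             all_site_sets: list[GenomicSiteSet] | None = None,
             n_perm: int = 100, threshold: float = 3.0, mode: str = "all",
             seed: int = 0, n_crowding_groups: int = 5,
             log_base: float = 2.0):
    """Structural proximity enrichment PE = log2(Obs/Exp) plus empirical p.

    Obs counts consistently proximal (A-site, B-site) pairs; Exp averages
    the count over permutations relabelling sites within chromosome x
    compartment x crowding stratum.  The permutation pool is
    ``all_site_sets`` (defaults to just A and B).  Returns (pe, p, obs,
    exp); pe is NaN when Exp = 0.
    """
    if all_site_sets is not None:
        pool_sets = all_site_sets
    elif sites_a.tf_id == sites_b.tf_id:
        pool_sets = [sites_a]
    else:
        pool_sets = [sites_a, sites_b]
    names = [ss.tf_id for ss in pool_sets]
    if sites_a.tf_id not in names or sites_b.tf_id not in names:
        raise ValueError("sites_a and sites_b must be in the permutation pool")
    ctx = _pe_context(pool_sets, structure, qc, threshold, mode,
                      n_crowding_groups)
    rng = np.random.default_rng(seed)
    return _pe_from_context(ctx, sites_a.tf_id, sites_b.tf_id, n_perm, rng,
                            log_base)


def pe_matrix(site_sets: list[GenomicSiteSet], structure: GenomeStructure,
              qc: StructureQC | None = None, n_perm: int = 100,
              threshold: float = 3.0, mode: str = "all", seed: int = 0,
              cluster: bool = True, method: str = "ward"):
    """Full TF x TF PE matrix, optionally clustered into sub-networks.

    The diagonal holds the homotypic self-enrichment (unordered within-set
    pairs).  Trans mode restricts the pair counting to inter-chromosome
    particle pairs (use threshold 3, as smaller thresholds starve the
    counts)."""
    if len(site_sets) < 3:
        raise ValueError("need at least 3 TFs")
    if qc is None:
        qc = qc_structure(structure)
    tf_ids = [ss.tf_id for ss in site_sets]
    n = len(tf_ids)
    values = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    ctx = _pe_context(site_sets, structure, qc, threshold, mode, 5)
    for i in range(n):
        for j in range(i, n):
            pe, _, _, _ = _pe_from_context(ctx, tf_ids[i], tf_ids[j], n_perm,
                                           rng, 2.0)
            values[i, j] = values[j, i] = pe
    # clustering needs finite entries: pairs with zero observed (or zero
    # expected) counts are floored at the smallest finite enrichment
    finite = np.isfinite(values)
    if not finite.all():
        floor = values[finite].min() if finite.any() else 0.0
        values = np.where(finite, values, floor)
    matrix = PairMatrix(tf_ids, values, symmetric=True)
    result: ClusterResult | None = None
    if cluster:
        result = cluster_tfs(matrix, method=method, distance="ce_exp")
    return matrix, result
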