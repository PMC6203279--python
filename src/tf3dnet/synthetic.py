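"""Synthetic Hi-C maps, TF site sets, annotations and genome structures
with planted, known signal.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for, at desk scale:

* normalized contacts decay as a power law of separation,
  c * s^-alpha (alpha = 1 by default), with log-normal multiplicative
  noise (sigma = 0.3) and raw counts Poisson around the normalized score;
* planted pairwise enrichment: bin pairs holding a bound site of TF A and
  a bound site of TF B are multiplied by an enrichment factor f >= 1
  (max over qualifying planted pairs);
* TF site sets with controllable count, ChIP occupancy and A/B
  compartment bias; compartments alternate in fixed-size blocks;
* particle-on-string structures: per-chromosome 3D random walks with
  constant step length 2 * radius (uniformly random direction), ten models
  derived by small coordinate jitter, and planted spatial clustering that
  places the sites of TFs connected by planted pairs inside a shared
  sphere;
* DHS / motif / histone-mark tracks that realize the promoter/enhancer
  categories used by the site-categorization rules.

Every draw flows through one seeded generator per product (spawned from
the spec seed), so identical specs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (CompartmentAnnotation, ContactMap, GenomeStructure,
                      GenomicSite, GenomicSiteSet, IntervalSet)
import pandas as pd

__all__ = [
    "TFSpec",
    "StructureSpec",
    "SyntheticSpec",
    "make_contact_map",
    "make_structure",
    "make_occupancy_sites",
]


@dataclass(frozen=True)
class TFSpec:
    tf_id: str
    n_sites: int
    occupancy_target: float = 1.0
    compartment_bias: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.occupancy_target <= 1.0:
            raise ValueError("occupancy_target must be in [0, 1]")
        if not 0.0 <= self.compartment_bias <= 1.0:
            raise ValueError("compartment_bias must be in [0, 1]")


@dataclass(frozen=True)
class StructureSpec:
    n_particles: int = 300          # per chromosome
    cluster_tightness: float = 1.0  # 1 = sites on the nearest particles only
    cluster_radius_radii: float | None = None  # explicit sphere radius
    n_models: int = 10
    jitter: float = 0.3             # model jitter, in particle radii (< 0.5)
    cluster_fraction: float = 0.5   # fraction of a clustered TF's sites planted


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 10_000_000
    bin_size: int = 5_000
    decay_exponent: float = 1.0
    contact_scale: float = 200.0
    noise_sigma: float = 0.3
    tf_specs: tuple[TFSpec, ...] = ()
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    structure_spec: StructureSpec = StructureSpec()
    compartment_block: int = 1_000_000   # bp per A/B block along the sequence
    site_width: int = 200

    def __post_init__(self):
        for a, b, f in self.planted_pairs:
            if f < 1.0:
                raise ValueError("enrichment_factor must be >= 1")
        names = [t.tf_id for t in self.tf_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tf_id in tf_specs")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


def _rng_for(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def compartment_annotation(spec: SyntheticSpec) -> CompartmentAnnotation:
    """Alternating A/B blocks along each chromosome."""
    ivs = []
    for chrom in spec.chrom_names():
        pos = 0
        k = 0
        while pos < spec.chrom_length:
            end = min(pos + spec.compartment_block, spec.chrom_length)
            ivs.append((chrom, pos, end, "A" if k % 2 == 0 else "B"))
            pos = end
            k += 1
    return CompartmentAnnotation(ivs)


def _split_counts(total: int, n_parts: int) -> list[int]:
    base, extra = divmod(total, n_parts)
    return [base + (1 if i < extra else 0) for i in range(n_parts)]


def _place_sites(spec: SyntheticSpec, rng: np.random.Generator
                 ) -> list[GenomicSiteSet]:
    """Sites on the bin grid, with per-TF A-compartment bias and bound
    flags drawn at the occupancy target."""
    n_bins = spec.chrom_length // spec.bin_size
    block_bins = max(1, spec.compartment_block // spec.bin_size)
    bin_block = (np.arange(n_bins) // block_bins) % 2
    a_bins = np.flatnonzero(bin_block == 0)
    b_bins = np.flatnonzero(bin_block == 1)
    site_sets = []
    for tf in spec.tf_specs:
        sites = []
        for chrom, n_sites in zip(spec.chrom_names(),
                                  _split_counts(tf.n_sites, spec.n_chroms)):
            if n_sites > n_bins:
                raise ValueError(
                    f"{tf.tf_id}: {n_sites} sites exceed {n_bins} bins on {chrom}")
            n_a = int(np.round(n_sites * tf.compartment_bias))
            n_a = min(n_a, len(a_bins))
            n_b = min(n_sites - n_a, len(b_bins))
            n_a = n_sites - n_b
            chosen = np.concatenate([
                rng.choice(a_bins, size=n_a, replace=False),
                rng.choice(b_bins, size=n_b, replace=False)])
            bound = rng.random(n_sites) < tf.occupancy_target
            for b, isb in zip(np.sort(chosen),
                              bound[np.argsort(chosen, kind="mergesort")]):
                center = int(b) * spec.bin_size + spec.bin_size // 2
                start = center - spec.site_width // 2
                sites.append(GenomicSite(chrom, start,
                                         start + spec.site_width, ".",
                                         tf.tf_id, 0.0, None, bool(isb)))
        site_sets.append(GenomicSiteSet(tf.tf_id, sites))
    return site_sets


def make_contact_map(spec: SyntheticSpec):
    """Per-chromosome contact maps plus the site sets they were planted
    with.

    Baseline normalized score at bin separation s is
    contact_scale * max(s, 1)^-decay_exponent times log-normal noise
    (exp(N(0, sigma^2)); sigma = 0 switches the noise off).  For every
    planted pair (A, B, f), bin pairs holding a bound A site and a bound B
    site are multiplied by f (max over qualifying pairs).  Raw counts are
    Poisson around the normalized score.

    Returns (maps: dict chrom -> ContactMap, site_sets, annotation).
    """
    rng = _rng_for(spec, 1)
    site_sets = _place_sites(spec, _rng_for(spec, 0))
    by_tf = {ss.tf_id: ss for ss in site_sets}
    n_bins = spec.chrom_length // spec.bin_size
    maps = {}
    for chrom in spec.chrom_names():
        s = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
        base = spec.contact_scale * np.maximum(s, 1) ** (-spec.decay_exponent)
        factor = np.ones((n_bins, n_bins))
        for a, b, f in spec.planted_pairs:
            bins_a = np.unique(by_tf[a].bound_sites.centers(chrom)
                               // spec.bin_size)
            bins_b = np.unique(by_tf[b].bound_sites.centers(chrom)
                               // spec.bin_size)
            if len(bins_a) == 0 or len(bins_b) == 0:
                continue
            sub = factor[np.ix_(bins_a, bins_b)]
            factor[np.ix_(bins_a, bins_b)] = np.maximum(sub, f)
            sub = factor[np.ix_(bins_b, bins_a)]
            factor[np.ix_(bins_b, bins_a)] = np.maximum(sub, f)
        mean = base * factor
        if spec.noise_sigma > 0:
            noise = np.exp(rng.normal(0.0, spec.noise_sigma,
                                      size=(n_bins, n_bins)))
            noise = np.triu(noise) + np.triu(noise, 1).T
            norm = mean * noise
        else:
            norm = mean
        raw = rng.poisson(norm)
        raw = np.triu(raw) + np.triu(raw, 1).T
        maps[chrom] = ContactMap(chrom, spec.bin_size, norm, raw)
    return maps, site_sets, compartment_annotation(spec)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _planted_groups(spec: SyntheticSpec) -> list[set[str]]:
    """Connected components of the planted-pair graph: TFs planted as
    contact-enriched share one spatial cluster."""
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in spec.planted_pairs:
        parent[find(a)] = find(b)
    groups: dict[str, set[str]] = {}
    for a, b, _ in spec.planted_pairs:
        groups.setdefault(find(a), set()).update((a, b))
    return list(groups.values())


def make_structure(spec: SyntheticSpec):
    """Particle-on-string structure with planted spatial clustering.

    Each chromosome is a 3D random walk with constant step length
    2 * radius (radius = 0.5 model units); A/B compartments follow the same
    alternating blocks as the contact maps.  TFs connected by planted pairs
    get (a fraction of) their sites placed on particles inside a shared
    sphere around a random anchor particle; the sphere holds the
    ``m = n_needed + (1 - tightness) * (n_particles - n_needed)`` particles
    nearest the anchor, or the explicit ``cluster_radius_radii`` when set
    (too-small explicit spheres raise).  Models beyond the first add
    Gaussian jitter of ``jitter`` radii per coordinate.

    Returns (GenomeStructure, site_sets).
    """
    ss_spec = spec.structure_spec
    rng = _rng_for(spec, 2)
    radius = 0.5
    step = 2 * radius
    coords = []
    chroms = []
    for ci, chrom in enumerate(spec.chrom_names()):
        # separate walks, offset so chromosomes do not start on top of
        # each other (chromosome territories)
        origin = rng.normal(0.0, 4 * radius, size=3) + \
            np.array([8.0 * radius * ci, 0.0, 0.0])
        steps = rng.normal(size=(ss_spec.n_particles - 1, 3))
        steps *= step / np.linalg.norm(steps, axis=1, keepdims=True)
        walk = origin + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        coords.append(walk)
        chroms.extend([chrom] * ss_spec.n_particles)
    xyz = np.vstack(coords)
    n_total = len(xyz)
    particle_size = 100_000
    particles = pd.DataFrame({
        "chrom": chroms,
        "start": np.concatenate([np.arange(ss_spec.n_particles) * particle_size
                                 for _ in spec.chrom_names()]),
    })
    block_particles = max(1, spec.compartment_block // particle_size)
    seq = np.concatenate([np.arange(ss_spec.n_particles)
                          for _ in spec.chrom_names()])
    compartment = np.where((seq // block_particles) % 2 == 0, "A", "B")

    models = np.stack([xyz] * ss_spec.n_models).astype(float)
    if ss_spec.jitter > 0:
        for m in range(1, ss_spec.n_models):
            models[m] += rng.normal(0.0, ss_spec.jitter * radius,
                                    size=xyz.shape)
    structure = GenomeStructure(models, particles, particle_size=particle_size,
                                radius=None, compartment=compartment)

    # site placement: every planted group gets one anchor per chromosome
    # (TF hubs recur genome-wide), chosen by a farthest-point rule within
    # the chromosome so distinct groups occupy separated neighborhoods
    groups = _planted_groups(spec)
    tf_to_group = {tf: gi for gi, g in enumerate(groups) for tf in g}
    chrom_arr = particles["chrom"].to_numpy()
    chrom_particles = {c: np.flatnonzero(chrom_arr == c)
                       for c in spec.chrom_names()}
    anchors: dict[tuple[int, str], int] = {}
    for chrom, idx in chrom_particles.items():
        for gi in range(len(groups)):
            if gi == 0:
                anchors[(gi, chrom)] = int(rng.choice(idx))
            else:
                chosen = xyz[[anchors[(g, chrom)] for g in range(gi)]]
                min_d = np.linalg.norm(xyz[idx, None, :] - chosen[None, :, :],
                                       axis=2).min(axis=1)
                anchors[(gi, chrom)] = int(idx[np.argmax(min_d)])

    def cluster_candidates(gi: int, chrom: str, n_needed: int) -> np.ndarray:
        idx = chrom_particles[chrom]
        dists = np.linalg.norm(xyz[idx] - xyz[anchors[(gi, chrom)]], axis=1)
        if ss_spec.cluster_radius_radii is not None:
            cand = idx[dists <= ss_spec.cluster_radius_radii * radius]
            if len(cand) < n_needed:
                raise ValueError(
                    f"cluster sphere too small: {len(cand)} particles for "
                    f"{n_needed} sites on {chrom}")
            return cand
        m = n_needed + int(round((1.0 - ss_spec.cluster_tightness)
                                 * (len(idx) - n_needed)))
        m = min(max(m, n_needed), len(idx))
        return idx[np.argsort(dists, kind="mergesort")[:m]]

    site_sets = []
    for tf in spec.tf_specs:
        gi = tf_to_group.get(tf.tf_id)
        chosen_particles = []
        for chrom, n_c in zip(spec.chrom_names(),
                              _split_counts(tf.n_sites, spec.n_chroms)):
            n_clustered = (int(round(n_c * ss_spec.cluster_fraction))
                           if gi is not None else 0)
            if n_clustered:
                cand = cluster_candidates(gi, chrom, n_clustered)
                chosen_particles.extend(rng.choice(cand, size=n_clustered,
                                                   replace=False))
            if n_c - n_clustered > 0:
                chosen_particles.extend(rng.choice(chrom_particles[chrom],
                                                   size=n_c - n_clustered))
        sites = []
        used_offsets: dict[int, int] = {}
        for p in chosen_particles:
            p = int(p)
            # several sites may share a particle; spread them inside it
            k = used_offsets.get(p, 0)
            used_offsets[p] = k + 1
            center = (int(particles["start"].iloc[p]) + 10_000
                      + k * 2_000 + 500)
            sites.append(GenomicSite(chrom_arr[p], center - 100,
                                     center + 100, ".", tf.tf_id, 0.0, None,
                                     True))
        site_sets.append(GenomicSiteSet(tf.tf_id, sites))
    return structure, site_sets


# ---------------------------------------------------------------------------
# Occupancy-analysis inputs
# ---------------------------------------------------------------------------

def make_occupancy_sites(spec: SyntheticSpec, propensity=None):
    """Putative and bound site sets inside generated DHS, plus the mark
    tracks that realize promoter/enhancer categories.

    Each putative site sits at the center of its own DHS interval; it is
    bound with probability ``occupancy_target`` (or the per-site
    ``propensity`` when supplied, e.g. to plant an occupancy-score
    correlation).  Motif p-values are log-uniform below the 1e-4 putative
    threshold.  Mark tracks (H3K4me1/3, H3K27ac/me3, H3K9ac/me, H3K36me3),
    TSS positions, chromatin-state enhancer intervals and methylated
    intervals are laid out so that roughly fixed fractions of sites fall in
    each category.

    Returns a dict per TF: {"putative", "bound", "dhs", "marks", "tss",
    "chromatin_state", "methylation"}.
    """
    rng = _rng_for(spec, 3)
    out = {}
    dhs_width = 300
    categories = ("strong_promoter", "weak_promoter", "active_enhancer",
                  "inactive_enhancer", "other")
    probs = (0.1, 0.15, 0.2, 0.1, 0.45)
    for tf in spec.tf_specs:
        putative = []
        marks = {name: [] for name in ("H3K4me1", "H3K4me3", "H3K27ac",
                                       "H3K27me3", "H3K9me", "H3K9ac",
                                       "H3K36me3")}
        tss = []
        states = []
        methylated = []
        dhs = []
        counts = _split_counts(tf.n_sites, spec.n_chroms)
        for chrom, n_sites in zip(spec.chrom_names(), counts):
            # non-overlapping DHS on a coarse grid
            grid = np.arange(1, spec.chrom_length // 4000 - 1)
            slots = rng.choice(grid, size=n_sites, replace=False) * 4000
            slots.sort()
            roles = rng.choice(len(categories), size=n_sites, p=probs)
            for pos, role_idx in zip(slots, roles):
                role = categories[role_idx]
                center = int(pos) + dhs_width // 2
                dhs.append((chrom, int(pos), int(pos) + dhs_width))
                start = center - spec.site_width // 2
                pval = float(10 ** rng.uniform(-8, -4))
                putative.append(GenomicSite(chrom, start,
                                            start + spec.site_width, ".",
                                            tf.tf_id, 0.0, pval, False))
                if role in ("strong_promoter", "weak_promoter"):
                    tss.append((chrom, center + 500, "+"))
                    marks["H3K4me3"].append((chrom, center - 200, center + 200))
                    marks["H3K27ac"].append((chrom, center - 200, center + 200))
                    if role == "strong_promoter":
                        marks["H3K36me3"].append((chrom, center + 100,
                                                  center + 1000))
                elif role in ("active_enhancer", "inactive_enhancer"):
                    states.append((chrom, center - 500, center + 500))
                    marks["H3K4me1"].append((chrom, center - 200, center + 200))
                    if role == "active_enhancer":
                        marks["H3K27ac"].append((chrom, center - 200,
                                                 center + 200))
                    else:
                        marks["H3K27me3"].append((chrom, center - 200,
                                                  center + 200))
        putative_set = GenomicSiteSet(tf.tf_id, putative)
        if propensity is not None:
            prob = np.asarray(propensity, dtype=float)
            if len(prob) != len(putative_set):
                raise ValueError("propensity must have one value per site")
        else:
            prob = np.full(len(putative_set), tf.occupancy_target)
        bound_mask = rng.random(len(putative_set)) < prob
        bound_sites = [
            GenomicSite(s.chrom, s.start, s.end, s.strand, s.tf_id,
                        float(rng.gamma(2.0, 4.0)), s.motif_pvalue, True)
            for s, b in zip(putative_set, bound_mask) if b]
        out[tf.tf_id] = {
            "putative": putative_set,
            "bound": GenomicSiteSet(tf.tf_id, bound_sites),
            "dhs": IntervalSet(dhs),
            "marks": {name: IntervalSet(iv) for name, iv in marks.items()},
            "tss": tss,
            "chromatin_state": IntervalSet(states),
            "methylation": IntervalSet(methylated),
        }
    return out
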