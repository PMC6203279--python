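"""Putative-site construction, genomic-marker categorization, linear site
density and cross-cell-line conservation.

Putative sites are motif matches (FIMO-style, p <= 1e-4 by default) whose
center lies in accessible chromatin (DHS); ChIP-seq peaks are reduced to
binding sites by mapping each peak to its best-scoring overlapping motif.
Mark association always tests whether the *center* of a site falls inside a
mark interval.  Strand is carried through I/O but ignored by every
co-localization computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (GenomeStructure, GenomicSite, GenomicSiteSet,
                      IntervalSet)

__all__ = [
    "SiteCategory",
    "LinearDensityTrack",
    "putative_sites",
    "map_peaks_to_motifs",
    "categorize_sites",
    "categorize_structure_flanks",
    "linear_density",
    "conservation_map",
]

CATEGORY_LABELS = ("strong_promoter", "weak_promoter", "active_enhancer",
                   "inactive_enhancer", "other", "excluded_ambiguous",
                   "excluded_methylated")

REQUIRED_MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3", "H3K9me",
                  "H3K9ac", "H3K36me3")


@dataclass(frozen=True)
class SiteCategory:
    label: str
    basis: frozenset

    def __post_init__(self):
        if self.label not in CATEGORY_LABELS:
            raise ValueError(f"unknown category label {self.label!r}")


@dataclass
class LinearDensityTrack:
    """Weighted site count per fixed-size region (100 kb by default).

    Interior sites contribute total weight 1, so the track conserves the
    site count away from chromosome ends.
    """

    region_size: int
    values: dict  # chrom -> np.ndarray of region-indexed weights

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


# ---------------------------------------------------------------------------
# Putative sites / peak-to-motif mapping
# ---------------------------------------------------------------------------

def putative_sites(motif_matches: GenomicSiteSet, dhs: IntervalSet,
                   pvalue_max: float = 1e-4) -> GenomicSiteSet:
    """Motif matches with p <= pvalue_max whose center lies in a DHS."""
    kept = []
    for m in motif_matches:
        if m.motif_pvalue is None:
            raise ValueError(f"motif match {m.chrom}:{m.start} lacks a p-value")
        if m.motif_pvalue <= pvalue_max and dhs.contains(m.chrom, m.center):
            kept.append(GenomicSite(m.chrom, m.start, m.end, m.strand,
                                    motif_matches.tf_id, m.signal_value,
                                    m.motif_pvalue, bound=False,
                                    sequence_key=m.sequence_key))
    return GenomicSiteSet(motif_matches.tf_id, kept, motif_matches.cell_type)


def map_peaks_to_motifs(peaks: GenomicSiteSet,
                        motif_matches: GenomicSiteSet) -> GenomicSiteSet:
    """Reduce each ChIP-seq peak to its best-scoring overlapping motif.

    Best = lowest motif p-value; ties go to the leftmost match; peaks with
    no overlapping motif are dropped.  Output sites are bound.
    """
    out = []
    matches = sorted(motif_matches, key=lambda m: (m.chrom, m.start))
    for peak in peaks:
        best = None
        for m in matches:
            if m.chrom != peak.chrom:
                continue
            if m.start < peak.end and peak.start < m.end:  # overlap
                key = (m.motif_pvalue if m.motif_pvalue is not None else 1.0,
                       m.start)
                if best is None or key < best[0]:
                    best = (key, m)
        if best is not None:
            m = best[1]
            out.append(GenomicSite(m.chrom, m.start, m.end, m.strand,
                                   peaks.tf_id, peak.signal_value,
                                   m.motif_pvalue, bound=True,
                                   sequence_key=m.sequence_key))
    # a motif can be the best match of two peaks; keep unique sites
    uniq = {}
    for s in out:
        uniq[(s.chrom, s.start, s.end, s.strand)] = s
    return GenomicSiteSet(peaks.tf_id, uniq.values(), peaks.cell_type)


# ---------------------------------------------------------------------------
# Genomic-marker categorization
# ---------------------------------------------------------------------------

def _tss_upstream_windows(tss, window: int):
    """(chrom, start, end, tss_pos) upstream windows; strand-aware when the
    TSS entries carry a strand, else the window is taken on the left."""
    out = []
    for entry in tss:
        if len(entry) == 2:
            chrom, pos = entry
            strand = "+"
        else:
            chrom, pos, strand = entry[:3]
        if strand == "-":
            out.append((chrom, pos, pos + window, pos))
        else:
            out.append((chrom, max(0, pos - window), pos, pos))
    return out


def categorize_sites(sites: GenomicSiteSet, marks: dict, tss,
                     chromatin_state: IntervalSet,
                     methylation: IntervalSet | None = None,
                     promoter_window: int = 2000,
                     strong_window: int = 1000,
                     strong_min_overlap: int = 300) -> list[SiteCategory]:
    """One category per site from histone marks, TSS and chromatin state.

    Promoters: center within 2000 bp upstream of a TSS, with H3K4me3 and
    H3K27ac; strong when an H3K36me3 peak overlaps the TSS +/- 1000 bp
    window by >= 300 bp, else weak.  Enhancers: center in a chromatin-state
    enhancer with H3K4me1; active with H3K27ac, inactive without H3K27ac
    but with H3K27me3.  Ambiguous mark combinations (H3K27ac+H3K27me3 or
    H3K9ac+H3K9me) and methylated regions are excluded, taking precedence
    over every other label.
    """
    for name in REQUIRED_MARKS:
        if name not in marks:
            raise ValueError(f"missing required mark track {name!r}")
    upstream = _tss_upstream_windows(tss, promoter_window)
    up_set = IntervalSet((c, a, b) for c, a, b, _ in upstream if a < b)
    out = []
    for s in sites:
        c = s.center
        has = {name: marks[name].contains(s.chrom, c) for name in REQUIRED_MARKS}
        fired = frozenset(n for n, v in has.items() if v)
        if has["H3K27ac"] and has["H3K27me3"] or has["H3K9ac"] and has["H3K9me"]:
            out.append(SiteCategory("excluded_ambiguous", fired))
            continue
        if methylation is not None and methylation.contains(s.chrom, c):
            out.append(SiteCategory("excluded_methylated", fired))
            continue
        if up_set.contains(s.chrom, c) and has["H3K4me3"] and has["H3K27ac"]:
            strong = False
            for chrom_u, a, b, pos in upstream:
                if chrom_u == s.chrom and a <= c < b:
                    ov = marks["H3K36me3"].max_overlap(
                        s.chrom, pos - strong_window, pos + strong_window)
                    if ov >= strong_min_overlap:
                        strong = True
                        break
            out.append(SiteCategory(
                "strong_promoter" if strong else "weak_promoter", fired))
            continue
        if chromatin_state.contains(s.chrom, c) and has["H3K4me1"]:
            if has["H3K27ac"]:
                out.append(SiteCategory("active_enhancer", fired))
                continue
            if has["H3K27me3"]:
                out.append(SiteCategory("inactive_enhancer", fired))
                continue
        out.append(SiteCategory("other", fired))
    return out


def categorize_structure_flanks(sites: GenomicSiteSet, marks: dict, tss,
                                flank: int = 2000) -> list[str]:
    """Coarse promoter/enhancer call from marks within +/- flank of the
    center: enhancer = H3K4me1 and no H3K4me3; promoter = TSS with H3K4me3
    and no H3K4me1; otherwise "other"."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    tss_positions: dict[str, np.ndarray] = {}
    for entry in tss:
        chrom, pos = entry[0], entry[1]
        tss_positions.setdefault(chrom, []).append(pos)
    tss_positions = {c: np.sort(np.asarray(p)) for c, p in tss_positions.items()}
    out = []
    for s in sites:
        lo, hi = s.center - flank, s.center + flank + 1
        k4me1 = marks["H3K4me1"].overlaps(s.chrom, lo, hi)
        k4me3 = marks["H3K4me3"].overlaps(s.chrom, lo, hi)
        pos = tss_positions.get(s.chrom, np.empty(0))
        has_tss = bool(len(pos)) and bool(
            np.any((pos >= lo) & (pos < hi)))
        if k4me1 and not k4me3:
            out.append("enhancer")
        elif has_tss and k4me3 and not k4me1:
            out.append("promoter")
        else:
            out.append("other")
    return out


# ---------------------------------------------------------------------------
# Linear density
# ---------------------------------------------------------------------------

def linear_density(sites: GenomicSiteSet, structure: GenomeStructure | None = None,
                   region_size: int | None = None,
                   chrom_lengths: dict[str, int] | None = None) -> LinearDensityTrack:
    """Weighted site count per 100-kb region.

    Each site spreads weight over regions as the overlap fraction of a
    region-size window centered on the site, i.e. the average of a sliding
    window count; a site exactly on a region boundary gives 0.5 to each
    neighbor, an interior site's weights sum to 1.
    """
    if structure is not None:
        region_size = structure.particle_size
        counts = {}
        chrom_arr = structure.particles["chrom"].to_numpy()
        for c in np.unique(chrom_arr):
            counts[c] = np.zeros(int((chrom_arr == c).sum()))
    elif region_size is not None and chrom_lengths is not None:
        counts = {c: np.zeros(int(np.ceil(L / region_size)))
                  for c, L in chrom_lengths.items()}
    else:
        raise ValueError("provide a structure or region_size + chrom_lengths")
    half = region_size / 2.0
    for s in sites:
        if s.chrom not in counts:
            continue
        vals = counts[s.chrom]
        lo, hi = s.center - half, s.center + half
        r0 = max(0, int(lo // region_size))
        r1 = min(len(vals) - 1, int((hi - 1e-9) // region_size))
        for r in range(r0, r1 + 1):
            ov = min(hi, (r + 1) * region_size) - max(lo, r * region_size)
            if ov > 0:
                vals[r] += ov / region_size
    return LinearDensityTrack(region_size, counts)


# ---------------------------------------------------------------------------
# Conservation between cell lines
# ---------------------------------------------------------------------------

def conservation_map(peaks_a: GenomicSiteSet, peaks_b: GenomicSiteSet,
                     max_center_dist: int = 300):
    """Fraction of A peaks conserved in B.

    A peak is conserved when a B peak overlaps its center with
    center-to-center distance < max_center_dist; among several qualifying B
    peaks the nearest center wins.  Returns (fraction, per-peak match list
    of B-site indices or -1).
    """
    b_sites = list(peaks_b)
    matches = np.full(len(peaks_a), -1, dtype=np.int64)
    for k, a in enumerate(peaks_a):
        c = a.center
        best = None
        for idx, b in enumerate(b_sites):
            if b.chrom != a.chrom or not (b.start <= c < b.end):
                continue
            dist = abs(b.center - c)
            if dist < max_center_dist and (best is None or dist < best[0]):
                best = (dist, idx)
        if best is not None:
            matches[k] = best[1]
    frac = float((matches >= 0).mean()) if len(peaks_a) else 0.0
    return frac, matches
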