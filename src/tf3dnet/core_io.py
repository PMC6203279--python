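"""Domain containers and text-format I/O shared by the whole pipeline.

Coordinates are 0-based half-open (BED convention) throughout.  The binary
Hi-C and structure formats (.hic/.cool/HDF5) are deliberately out of scope:
contact maps are consumed as per-chromosome TSV triples and structures as a
whitespace-separated particle table, both documented in the README.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicSite",
    "GenomicSiteSet",
    "IntervalSet",
    "CompartmentAnnotation",
    "ContactMap",
    "ExpectedProfile",
    "GenomeStructure",
    "read_sites",
    "write_sites",
    "read_intervals",
    "read_compartments",
    "read_contact_map",
    "write_contact_map",
    "read_structure",
    "write_structure",
]


# ---------------------------------------------------------------------------
# Genomic sites
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicSite:
    """One binding site / peak / motif match.

    ``signal_value`` carries the ENCODE narrowPeak SignalValue (0 when the
    source format has none); ``bound`` distinguishes ChIP-seq-identified
    sites from putative (motif-in-DHS) sites.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    tf_id: str = ""
    signal_value: float = 0.0
    motif_pvalue: float | None = None
    bound: bool = False
    sequence_key: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"site {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.signal_value < 0:
            raise ValueError("signal_value must be nonnegative")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class GenomicSiteSet:
    """Sites of one TF in one cell type, sorted by (chrom, start).

    Duplicate (chrom, start, end, strand) entries are rejected: they would
    double-count contacts in every downstream sum.
    """

    def __init__(self, tf_id: str, sites: Iterable[GenomicSite] = (),
                 cell_type: str = ""):
        self.tf_id = tf_id
        self.cell_type = cell_type
        self.sites = sorted(sites, key=lambda s: (s.chrom, s.start, s.end))
        keys = [(s.chrom, s.start, s.end, s.strand) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate sites in set for {tf_id!r}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenomicSiteSet)
                and self.tf_id == other.tf_id
                and self.sites == other.sites)

    def chroms(self) -> list[str]:
        return sorted({s.chrom for s in self.sites})

    def on_chrom(self, chrom: str) -> list[GenomicSite]:
        return [s for s in self.sites if s.chrom == chrom]

    def centers(self, chrom: str | None = None) -> np.ndarray:
        sites = self.sites if chrom is None else self.on_chrom(chrom)
        return np.array([s.center for s in sites], dtype=np.int64)

    def subset(self, keep: Sequence[bool] | Sequence[int]) -> "GenomicSiteSet":
        arr = np.asarray(keep)
        if arr.dtype == bool:
            chosen = [s for s, k in zip(self.sites, arr) if k]
        else:
            chosen = [self.sites[i] for i in arr]
        return GenomicSiteSet(self.tf_id, chosen, self.cell_type)

    @property
    def bound_sites(self) -> "GenomicSiteSet":
        return GenomicSiteSet(self.tf_id, [s for s in self.sites if s.bound],
                              self.cell_type)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "start": [s.start for s in self.sites],
                "end": [s.end for s in self.sites],
                "strand": [s.strand for s in self.sites],
                "tf_id": [s.tf_id for s in self.sites],
                "signal_value": [s.signal_value for s in self.sites],
                "bound": [s.bound for s in self.sites],
            }
        )


# ---------------------------------------------------------------------------
# Interval sets (marks, DHS, chromatin states, anchors)
# ---------------------------------------------------------------------------

class IntervalSet:
    """Chromosome-keyed intervals with point/window queries.

    Intervals may overlap.  Point containment uses the classic start-sorted
    prefix-max-of-ends trick so queries are O(log n) even with overlaps.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"interval {chrom}:{start}-{end}: start must be < end")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._cummax_end: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts = np.array([a for a, _ in ivs], dtype=np.int64)
            ends = np.array([b for _, b in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._cummax_end[chrom] = np.maximum.accumulate(ends)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in self.chroms():
            out.extend((chrom, int(a), int(b))
                       for a, b in zip(self._starts[chrom], self._ends[chrom]))
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        idx = int(np.searchsorted(starts, pos, side="right"))
        return idx > 0 and int(self._cummax_end[chrom][idx - 1]) > pos

    def contains_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts = self._starts.get(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        if starts is None:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(starts, pos, side="right")
        ok = idx > 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = self._cummax_end[chrom][idx[ok] - 1] > pos[ok]
        return out

    def max_overlap(self, chrom: str, start: int, end: int) -> int:
        """Largest overlap (bp) of [start, end) with any single interval."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return 0
        ov = (np.minimum(self._ends[chrom], end)
              - np.maximum(starts, start))
        return max(0, int(ov.max()))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.max_overlap(chrom, start, end) > 0


class CompartmentAnnotation:
    """Non-overlapping labelled intervals (A/B compartments or Rao-style
    A1/A2/B1..B4 sub-compartments)."""

    LABELS = {"A1", "A2", "B1", "B2", "B3", "B4", "A", "B", "none"}

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]] = ()):
        by_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in intervals:
            if start >= end:
                raise ValueError(f"interval {chrom}:{start}-{end}: start must be < end")
            by_chrom.setdefault(chrom, []).append((int(start), int(end), label))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._labels: dict[str, list[str]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s0, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping compartment intervals on {chrom}")
            self._starts[chrom] = np.array([a for a, _, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([b for _, b, _ in ivs], dtype=np.int64)
            self._labels[chrom] = [l for _, _, l in ivs]

    def intervals(self) -> list[tuple[str, int, int, str]]:
        out = []
        for chrom in sorted(self._starts):
            out.extend(
                (chrom, int(a), int(b), l)
                for a, b, l in zip(self._starts[chrom], self._ends[chrom],
                                   self._labels[chrom]))
        return out

    def label_at(self, chrom: str, pos: int) -> str:
        starts = self._starts.get(chrom)
        if starts is None:
            return "none"
        idx = int(np.searchsorted(starts, pos, side="right")) - 1
        if idx >= 0 and pos < self._ends[chrom][idx]:
            return self._labels[chrom][idx]
        return "none"

    def labels_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return np.array([self.label_at(chrom, int(p)) for p in np.asarray(pos)],
                        dtype=object)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

class ContactMap:
    """Intra-chromosomal binned contacts, stored densely and symmetrically.

    ``normalized`` holds KR-style normalized scores, ``raw`` the raw read
    counts; ``valid`` marks bins that survive coverage filtering (all True
    on construction).
    """

    def __init__(self, chrom: str, bin_size: int, normalized: np.ndarray,
                 raw: np.ndarray, valid: np.ndarray | None = None):
        normalized = np.asarray(normalized, dtype=np.float64)
        raw = np.asarray(raw, dtype=np.int64)
        if normalized.shape != raw.shape or normalized.ndim != 2 \
                or normalized.shape[0] != normalized.shape[1]:
            raise ValueError("normalized and raw must be equal square matrices")
        if not np.allclose(normalized, normalized.T):
            raise ValueError("normalized matrix must be symmetric")
        if not np.array_equal(raw, raw.T):
            raise ValueError("raw matrix must be symmetric")
        if (normalized < 0).any() or (raw < 0).any():
            raise ValueError("contact counts must be nonnegative")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.normalized = normalized
        self.raw = raw
        self.valid = (np.ones(normalized.shape[0], dtype=bool)
                      if valid is None else np.asarray(valid, dtype=bool))

    @property
    def n_bins(self) -> int:
        return self.normalized.shape[0]

    @property
    def bin_raw_total(self) -> np.ndarray:
        """Per-bin sum of raw reads over all partners (diagonal once)."""
        return self.raw.sum(axis=1)

    def bin_of(self, pos: int) -> int:
        return int(pos) // self.bin_size

    def lookup(self, i: int, j: int) -> float:
        return float(self.normalized[i, j])

    def with_valid(self, valid: np.ndarray) -> "ContactMap":
        return ContactMap(self.chrom, self.bin_size, self.normalized,
                          self.raw, valid=valid)


@dataclass
class ExpectedProfile:
    """Mean normalized contact per bin separation (the Exp in Obs/Exp)."""

    chrom: str
    bin_size: int
    values: np.ndarray  # index = separation in bins; NaN where no valid pair

    def at(self, separation_bins: int) -> float:
        return float(self.values[separation_bins])


# ---------------------------------------------------------------------------
# Genome structures
# ---------------------------------------------------------------------------

class GenomeStructure:
    """Multi-model particle-on-string genome structure (100-kb particles).

    ``models`` is (n_models, n_particles, 3); every model covers the same
    particle list.  The repulsive particle radius is not recorded in the
    deposited coordinate tables, whose length unit is arbitrary, so it is
    estimated per structure as half the median 3D distance between
    sequentially adjacent intra-chromosome particles of the first model.
    """

    def __init__(self, models: np.ndarray, particles: pd.DataFrame,
                 particle_size: int = 100_000, radius: float | None = None,
                 compartment: np.ndarray | None = None):
        models = np.asarray(models, dtype=np.float64)
        if models.ndim != 3 or models.shape[2] != 3:
            raise ValueError("models must have shape (n_models, n_particles, 3)")
        if models.shape[1] != len(particles):
            raise ValueError("models and particle table disagree on particle count")
        for chrom, grp in particles.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            if not np.all(np.diff(starts) > 0):
                raise ValueError(f"particle starts not increasing on {chrom}")
        self.models = models
        self.particles = particles.reset_index(drop=True)
        self.particle_size = int(particle_size)
        self.radius = float(radius) if radius is not None \
            else self._estimate_radius()
        self.compartment = (np.asarray(compartment, dtype=object)
                            if compartment is not None else None)

    def _estimate_radius(self) -> float:
        dists = []
        chrom = self.particles["chrom"].to_numpy()
        xyz = self.models[0]
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            if len(idx) > 1:
                d = np.linalg.norm(np.diff(xyz[idx], axis=0), axis=1)
                dists.append(d)
        if not dists:
            raise ValueError("cannot estimate radius: no adjacent particle pairs")
        return float(np.median(np.concatenate(dists)) / 2.0)

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def n_particles(self) -> int:
        return self.models.shape[1]

    def particle_index(self, chrom: str, pos: int) -> int:
        """Index of the particle whose region contains ``pos`` (-1 if none)."""
        mask = self.particles["chrom"].to_numpy() == chrom
        starts = self.particles["start"].to_numpy()[mask]
        idx_all = np.flatnonzero(mask)
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        if k < 0 or pos >= starts[k] + self.particle_size:
            return -1
        return int(idx_all[k])

    def particle_indices(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return np.array([self.particle_index(chrom, int(p)) for p in pos],
                        dtype=np.int64)

    def seq_index(self) -> np.ndarray:
        """Within-chromosome sequential index of every particle."""
        out = np.empty(self.n_particles, dtype=np.int64)
        chrom = self.particles["chrom"].to_numpy()
        for c in pd.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            out[idx] = np.arange(len(idx))
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_BED_FORMATS = {"bed6", "narrowPeak", "broadPeak"}


def read_sites(path, format: str = "narrowPeak", tf_id: str = "",
               cell_type: str = "", bound: bool = True,
               chroms: set[str] | None = None,
               on_unknown_chrom: str = "error") -> GenomicSiteSet:
    """Read BED6 / ENCODE narrowPeak / broadPeak into a site set.

    narrowPeak column 7 (SignalValue) and column 8 (-log10 p, ignored) follow
    the ENCODE definition; summit offsets (column 10) are ignored and the
    peak center is floor((start+end)/2).  ``on_unknown_chrom`` is "error" or
    "skip" and only applies when ``chroms`` is given.
    """
    if format not in _BED_FORMATS:
        raise ValueError(f"unknown format {format!r}")
    min_cols = {"bed6": 3, "narrowPeak": 10, "broadPeak": 9}[format]
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for "
                    f"{format}, got {len(cols)}")
            chrom = cols[0]
            if chroms is not None and chrom not in chroms:
                if on_unknown_chrom == "skip":
                    warnings.warn(f"{path}:{lineno}: skipping unknown chromosome "
                                  f"{chrom!r}")
                    continue
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-." else "."
            signal = 0.0
            pval = None
            if format in ("narrowPeak", "broadPeak"):
                try:
                    signal = float(cols[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad SignalValue") from exc
            try:
                sites.append(GenomicSite(chrom, start, end, strand,
                                         tf_id or (cols[3] if len(cols) > 3 else ""),
                                         signal, pval, bound))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return GenomicSiteSet(tf_id, sites, cell_type)


def write_sites(site_set: GenomicSiteSet, path, format: str = "narrowPeak") -> None:
    if format not in _BED_FORMATS:
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for s in site_set:
            name = s.tf_id or "."
            if format == "bed6":
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\n")
            elif format == "broadPeak":
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\t"
                         f"{s.signal_value:g}\t-1\t-1\n")
            else:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\t"
                         f"{s.signal_value:g}\t-1\t-1\t-1\n")


def read_intervals(path) -> IntervalSet:
    """Read a plain BED3+ file as an unlabelled interval set."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            ivs.append((cols[0], int(cols[1]), int(cols[2])))
    return IntervalSet(ivs)


def read_compartments(path) -> CompartmentAnnotation:
    """Read BED4 (chrom, start, end, label) compartment annotation."""
    ivs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            ivs.append((cols[0], int(cols[1]), int(cols[2]), cols[3]))
    return CompartmentAnnotation(ivs)


def read_contact_map(path, bin_size: int, n_bins: int | None = None) -> ContactMap:
    """Read TSV triples (chrom, bin_i_start, bin_j_start, norm[, raw]).

    One chromosome per file.  When the raw column is absent raw counts
    default to the rounded normalized score.  Duplicate (i, j)/(j, i)
    entries with conflicting values violate symmetry and raise.
    """
    recs: dict[tuple[int, int], tuple[float, int]] = {}
    chrom = None
    max_bin = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
            c, si, sj = cols[0], int(cols[1]), int(cols[2])
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise ValueError(f"{path}:{lineno}: multiple chromosomes in one map")
            if si % bin_size or sj % bin_size:
                raise ValueError(
                    f"{path}:{lineno}: bin start not a multiple of {bin_size}")
            norm = float(cols[3])
            raw = int(cols[4]) if len(cols) > 4 else int(round(norm))
            i, j = sorted((si // bin_size, sj // bin_size))
            if (i, j) in recs and recs[(i, j)] != (norm, raw):
                raise ValueError(
                    f"{path}:{lineno}: conflicting duplicate entry for bins "
                    f"({i}, {j})")
            recs[(i, j)] = (norm, raw)
            max_bin = max(max_bin, j)
    if chrom is None:
        raise ValueError(f"{path}: empty contact map")
    n = n_bins if n_bins is not None else max_bin + 1
    normalized = np.zeros((n, n))
    raw_m = np.zeros((n, n), dtype=np.int64)
    for (i, j), (norm, raw) in recs.items():
        normalized[i, j] = normalized[j, i] = norm
        raw_m[i, j] = raw_m[j, i] = raw
    return ContactMap(chrom, bin_size, normalized, raw_m)


def write_contact_map(cmap: ContactMap, path) -> None:
    with open(path, "w") as fh:
        iu, ju = np.nonzero(np.triu(cmap.normalized > 0) | np.triu(cmap.raw > 0))
        for i, j in zip(iu, ju):
            fh.write(f"{cmap.chrom}\t{i * cmap.bin_size}\t{j * cmap.bin_size}\t"
                     f"{cmap.normalized[i, j]:.10g}\t{cmap.raw[i, j]}\n")


def read_structure(path, particle_size: int = 100_000) -> GenomeStructure:
    """Read a whitespace table (model, chrom, particle_start, x, y, z)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["model", "chrom", "start", "x", "y", "z"])
    if df.empty:
        raise ValueError(f"{path}: empty structure file")
    model_ids = sorted(df["model"].unique())
    per_model = []
    ref_particles = None
    for m in model_ids:
        sub = df[df["model"] == m]
        particles = list(zip(sub["chrom"], sub["start"]))
        if ref_particles is None:
            ref_particles = particles
        elif particles != ref_particles:
            raise ValueError(f"{path}: model {m} has a different particle list")
        per_model.append(sub[["x", "y", "z"]].to_numpy(dtype=np.float64))
    ptab = pd.DataFrame(ref_particles, columns=["chrom", "start"])
    return GenomeStructure(np.stack(per_model), ptab, particle_size=particle_size)


def write_structure(struct: GenomeStructure, path) -> None:
    with open(path, "w") as fh:
        for m in range(struct.n_models):
            for k in range(struct.n_particles):
                chrom = struct.particles["chrom"].iloc[k]
                start = struct.particles["start"].iloc[k]
                x, y, z = struct.models[m, k]
                fh.write(f"{m}\t{chrom}\t{start}\t{x:.10g}\t{y:.10g}\t{z:.10g}\n")
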