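"""Segmented copy-number profiles: domain types, SEG I/O and harmonization.

Internal coordinates are 0-based half-open.  SEG files are read and written
in the dominant dialect (1-based inclusive coordinates, tab-delimited, six
columns).  Chromosome names are stored without a ``chr`` prefix; ordering
follows the :class:`GenomeModel` declared order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

#: Human autosome names as used internally (no "chr" prefix).
AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))

SEG_HEADER = "ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean"


class SegFormatError(ValueError):
    """Raised when a SEG file is malformed or violates profile invariants."""


def _normalize_chrom(token: str) -> str:
    return token[3:] if token.lower().startswith("chr") else token


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with their lengths in bp.

    Parameters
    ----------
    names
        Chromosome names, unique and non-empty, in display/sort order.
    lengths
        Chromosome lengths in bp, one per name, all positive.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(self.names) == 0:
            raise ValueError("genome must contain at least one chromosome")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(not n for n in self.names):
            raise ValueError("chromosome names must be non-empty")
        if any(length <= 0 for length in self.lengths):
            raise ValueError("chromosome lengths must be positive")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance (frozen dataclass -> object.__setattr__)
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {name: i for i, name in enumerate(self.names)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def index_of(self, chrom: str) -> int:
        try:
            return self._index[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.index_of(chrom)]

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @classmethod
    def toy(cls, n_chromosomes: int = 22, chromosome_length: int = 10_000_000) -> "GenomeModel":
        """A toy genome of equally sized autosomes named ``"1".."n"``."""
        names = tuple(str(i) for i in range(1, n_chromosomes + 1))
        return cls(names, (chromosome_length,) * n_chromosomes)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeModel":
        """Load a genome from a 2-column (name, length) chromosome-sizes file."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
                names.append(_normalize_chrom(parts[0]))
                try:
                    lengths.append(int(parts[1]))
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
        return cls(tuple(names), tuple(lengths))


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Segment:
    """One segment of a profile: an interval with a log2-ratio value."""

    interval: GenomicInterval
    log_ratio: float
    marker_count: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_ratio):
            raise ValueError(f"non-finite log_ratio {self.log_ratio!r}")
        if self.marker_count is not None and self.marker_count <= 0:
            raise ValueError(f"marker_count must be positive, got {self.marker_count}")


@dataclass(frozen=True)
class SegmentedProfile:
    """One sample's sorted, non-overlapping segments over a genome model.

    Segments must be sorted by (genome chromosome order, start) and must not
    overlap within a chromosome; intervals must fit inside their chromosome.
    """

    sample_id: str
    genome: GenomeModel
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if len(self.segments) == 0:
            raise ValueError(f"sample {self.sample_id!r}: profile has no segments")
        prev_key: tuple[int, int] | None = None
        prev_end = 0
        for seg in self.segments:
            iv = seg.interval
            if iv.chromosome not in self.genome:
                raise ValueError(
                    f"sample {self.sample_id!r}: unknown chromosome {iv.chromosome!r}"
                )
            if iv.end > self.genome.length_of(iv.chromosome):
                raise ValueError(
                    f"sample {self.sample_id!r} chromosome {iv.chromosome}: "
                    f"segment end {iv.end} exceeds chromosome length"
                )
            key = (self.genome.index_of(iv.chromosome), iv.start)
            if prev_key is not None:
                if key < prev_key:
                    raise ValueError(
                        f"sample {self.sample_id!r}: segments not sorted by genome order"
                    )
                if key[0] == prev_key[0] and iv.start < prev_end:
                    raise ValueError(
                        f"sample {self.sample_id!r} chromosome {iv.chromosome}: "
                        f"overlapping segments at {iv.start}"
                    )
            prev_key = key
            prev_end = iv.end

    @property
    def intervals(self) -> tuple[GenomicInterval, ...]:
        return tuple(seg.interval for seg in self.segments)

    @property
    def log_ratios(self) -> np.ndarray:
        return np.array([seg.log_ratio for seg in self.segments], dtype=float)

    def weights(self, mode: str = "bp") -> np.ndarray:
        """Per-segment weights: interval length in bp, or marker counts.

        ``mode="markers"`` requires every segment to carry a marker count.
        """
        if mode == "bp":
            return np.array([seg.interval.length for seg in self.segments], dtype=float)
        if mode == "markers":
            counts = [seg.marker_count for seg in self.segments]
            if any(c is None for c in counts):
                raise ValueError(
                    f"sample {self.sample_id!r}: marker weighting requested but "
                    "some segments have no marker count"
                )
            return np.array(counts, dtype=float)
        raise ValueError(f"unknown weight mode {mode!r} (expected 'bp' or 'markers')")


@dataclass(frozen=True)
class HarmonizedPair:
    """Two profiles re-expressed on the intersection of their segmentations."""

    intervals: tuple[GenomicInterval, ...]
    value_a: np.ndarray
    value_b: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if n == 0:
            raise ValueError("harmonized pair has no intervals")
        if len(self.value_a) != n or len(self.value_b) != n or len(self.weights) != n:
            raise ValueError("harmonized arrays must match the interval count")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def read_seg(path: str | Path, genome: GenomeModel) -> dict[str, SegmentedProfile]:
    """Read a SEG file into one :class:`SegmentedProfile` per sample.

    The file must be tab-delimited with a header row and exactly six columns
    (sample, chromosome, start, end, marker count, segment mean), coordinates
    1-based inclusive.  An empty marker-count field is stored as ``None``.
    """
    path = Path(path)
    rows_by_sample: dict[str, list[Segment]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise SegFormatError(f"{path}: empty file")
        if len(header.rstrip("\n").split("\t")) != 6:
            raise SegFormatError(f"{path}:1: header must have 6 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise SegFormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            sample, chrom_tok, start_s, end_s, nmark_s, mean_s = parts
            chrom = _normalize_chrom(chrom_tok)
            if chrom not in genome:
                raise SegFormatError(f"{path}:{lineno}: unknown chromosome {chrom_tok!r}")
            try:
                start = int(start_s)
                end = int(end_s)
                log_ratio = float(mean_s)
            except ValueError:
                raise SegFormatError(f"{path}:{lineno}: non-numeric coordinate or mean") from None
            marker_count: int | None = None
            if nmark_s != "":
                try:
                    marker_count = int(nmark_s)
                except ValueError:
                    raise SegFormatError(f"{path}:{lineno}: non-integer marker count") from None
            try:
                seg = Segment(GenomicInterval(chrom, start - 1, end), log_ratio, marker_count)
            except ValueError as exc:
                raise SegFormatError(f"{path}:{lineno}: {exc}") from None
            rows_by_sample.setdefault(sample, []).append(seg)

    profiles: dict[str, SegmentedProfile] = {}
    for sample, segs in rows_by_sample.items():
        segs.sort(key=lambda s: (genome.index_of(s.interval.chromosome), s.interval.start))
        try:
            profiles[sample] = SegmentedProfile(sample, genome, tuple(segs))
        except ValueError as exc:
            raise SegFormatError(f"{path}: {exc}") from exc
    return profiles


def write_seg(
    profiles: Mapping[str, SegmentedProfile] | Iterable[SegmentedProfile],
    path: str | Path,
) -> Path:
    """Write profiles as a canonical SEG file.

    Canonical form: fixed header, 1-based inclusive coordinates, segment
    means with 6 decimal places, rows sorted by sample then genome order.
    """
    if isinstance(profiles, Mapping):
        items = list(profiles.values())
    else:
        items = list(profiles)
    items.sort(key=lambda p: p.sample_id)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(SEG_HEADER + "\n")
        for profile in items:
            for seg in profile.segments:
                iv = seg.interval
                nmark = "" if seg.marker_count is None else str(seg.marker_count)
                fh.write(
                    f"{profile.sample_id}\t{iv.chromosome}\t{iv.start + 1}\t{iv.end}"
                    f"\t{nmark}\t{seg.log_ratio:.6f}\n"
                )
    return path


def infer_genome_from_seg(path: str | Path) -> GenomeModel:
    """Build a minimal genome model from the extent of a SEG file.

    Chromosome lengths are the maximum segment end seen per chromosome;
    numeric chromosome names sort numerically, others lexically after them.
    """
    maxima: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise SegFormatError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            chrom = _normalize_chrom(parts[1])
            try:
                end = int(parts[3])
            except ValueError:
                raise SegFormatError(f"{path}:{lineno}: non-integer end coordinate") from None
            maxima[chrom] = max(maxima.get(chrom, 0), end)
    if not maxima:
        raise SegFormatError(f"{path}: no data rows")

    def sort_key(name: str) -> tuple[int, int, str]:
        return (0, int(name), "") if name.isdigit() else (1, 0, name)

    names = tuple(sorted(maxima, key=sort_key))
    return GenomeModel(names, tuple(maxima[n] for n in names))


def restrict_to_autosomes(profile: SegmentedProfile) -> SegmentedProfile:
    """Drop segments outside chromosomes 1-22; error if nothing remains."""
    kept = tuple(s for s in profile.segments if s.interval.chromosome in AUTOSOMES)
    if not kept:
        raise ValueError(f"sample {profile.sample_id!r}: no autosomal segments")
    if len(kept) == len(profile.segments):
        return profile
    return SegmentedProfile(profile.sample_id, profile.genome, kept)


def harmonize_pair(a: SegmentedProfile, b: SegmentedProfile) -> HarmonizedPair:
    """Intersect two segmentations so values can be compared interval-wise.

    Output intervals are the pairwise intersections of ``a``'s and ``b``'s
    segments; regions covered by only one profile are dropped.  Weight is the
    interval length in bp.
    """
    if a.genome != b.genome:
        raise ValueError("profiles use different genome models")
    by_chrom_a: dict[str, list[Segment]] = {}
    by_chrom_b: dict[str, list[Segment]] = {}
    for seg in a.segments:
        by_chrom_a.setdefault(seg.interval.chromosome, []).append(seg)
    for seg in b.segments:
        by_chrom_b.setdefault(seg.interval.chromosome, []).append(seg)

    intervals: list[GenomicInterval] = []
    va: list[float] = []
    vb: list[float] = []
    for chrom in a.genome.names:
        sa = by_chrom_a.get(chrom)
        sb = by_chrom_b.get(chrom)
        if not sa or not sb:
            continue
        i = j = 0
        while i < len(sa) and j < len(sb):
            lo = max(sa[i].interval.start, sb[j].interval.start)
            hi = min(sa[i].interval.end, sb[j].interval.end)
            if lo < hi:
                intervals.append(GenomicInterval(chrom, lo, hi))
                va.append(sa[i].log_ratio)
                vb.append(sb[j].log_ratio)
            if sa[i].interval.end < sb[j].interval.end:
                i += 1
            elif sa[i].interval.end > sb[j].interval.end:
                j += 1
            else:
                i += 1
                j += 1
    if not intervals:
        raise ValueError(
            f"profiles {a.sample_id!r} and {b.sample_id!r} share no genomic coverage"
        )
    weights = np.array([iv.length for iv in intervals], dtype=float)
    return HarmonizedPair(tuple(intervals), np.array(va), np.array(vb), weights)


def weighted_mean_std(values, weights) -> tuple[float, float]:
    """Weighted mean and population-form weighted standard deviation."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights differ in length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = w.sum()
    mean = float((w * v).sum() / total)
    var = float((w * (v - mean) ** 2).sum() / total)
    return mean, math.sqrt(var)
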