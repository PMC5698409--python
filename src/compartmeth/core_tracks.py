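"""Genome coordinate frame, binned tracks, and plain-text interval I/O.

All coordinates are 0-based, half-open (BED convention), everywhere —
input, output and in memory. Chromosomes are tiled by fixed-width bins;
the last bin of a chromosome may be short and is flagged, not dropped,
so that the (chrom, start) <-> bin-index mapping stays a bijection.
Missing values are an explicit boolean mask, never a sentinel: 0 is a
legal eigenvector or methylation value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("compartmeth")

FLOAT_FORMAT = "%.6g"  # bedGraph round-trip precision: 6 significant digits


class CompartmethError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CompartmethError):
    """A text input file could not be parsed."""


@dataclass(frozen=True)
class Genome:
    """An ordered set of chromosomes with lengths.

    The chromosome order is stable and defines the concatenation order of
    every genome-wide vector in the package.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise CompartmethError("duplicate chromosome names in genome")
        if len(self.names) != len(self.lengths):
            raise CompartmethError("names and lengths differ in length")
        if any(l < 1 for l in self.lengths):
            raise CompartmethError("chromosome lengths must be >= 1")

    @property
    def length_of(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise CompartmethError(f"unknown chromosome {chrom!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path) -> "Genome":
        """Read a two-column chrom-sizes file (name, length)."""
        names: list[str] = []
        lengths: list[int] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 columns")
                try:
                    length = int(parts[1])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: length {parts[1]!r} is not an integer"
                    ) from None
                names.append(parts[0])
                lengths.append(length)
        return cls(tuple(names), tuple(lengths))

    def write_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


class BinTable:
    """Fixed-width genomic bins tiling every chromosome of a genome.

    Bins are half-open intervals ``[k*s, min((k+1)*s, L))``; they tile each
    chromosome without gaps or overlaps. Genome-wide vectors concatenate
    chromosomes in genome order.
    """

    def __init__(self, genome: Genome, bin_size: int):
        if bin_size < 1:
            raise CompartmethError("bin size must be >= 1")
        self.genome = genome
        self.bin_size = int(bin_size)
        counts = [-(-l // bin_size) for l in genome.lengths]  # ceil division
        self._counts = dict(zip(genome.names, counts))
        offsets = np.concatenate([[0], np.cumsum(counts)])
        self._offsets = dict(zip(genome.names, offsets[:-1].astype(int)))
        self.n_bins = int(offsets[-1])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.genome == other.genome
            and self.bin_size == other.bin_size
        )

    def n_bins_of(self, chrom: str) -> int:
        return self._counts[chrom]

    def offset_of(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        o = self._offsets[chrom]
        return slice(o, o + self._counts[chrom])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Genome-wide index of the bin containing position ``pos``."""
        if not 0 <= pos < self.genome.length(chrom):
            raise CompartmethError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval(self, index: int) -> "Interval":
        """Inverse of :meth:`bin_index`: the interval of a genome-wide bin."""
        for chrom in self.genome.names:
            o, n = self._offsets[chrom], self._counts[chrom]
            if o <= index < o + n:
                k = index - o
                start = k * self.bin_size
                end = min(start + self.bin_size, self.genome.length(chrom))
                return Interval(chrom, start, end)
        raise CompartmethError(f"bin index {index} out of range")

    def starts_of(self, chrom: str) -> np.ndarray:
        return np.arange(self._counts[chrom], dtype=np.int64) * self.bin_size

    def ends_of(self, chrom: str) -> np.ndarray:
        ends = self.starts_of(chrom) + self.bin_size
        return np.minimum(ends, self.genome.length(chrom))

    def widths(self) -> np.ndarray:
        """Genome-wide vector of bin widths in bp."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for chrom in self.genome.names:
            out[self.chrom_slice(chrom)] = self.ends_of(chrom) - self.starts_of(chrom)
        return out

    def short_bin_mask(self) -> np.ndarray:
        """True for terminal bins shorter than the nominal bin size."""
        return self.widths() < self.bin_size


@dataclass
class Interval:
    """A genomic interval, 0-based half-open, with optional value/label."""

    chrom: str
    start: int
    end: int
    value: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise CompartmethError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


class BinTrack:
    """One real value per bin of a :class:`BinTable`, with a validity mask."""

    def __init__(self, bin_table: BinTable, values=None, valid=None):
        self.bin_table = bin_table
        n = bin_table.n_bins
        self.values = (
            np.zeros(n) if values is None else np.asarray(values, dtype=float).copy()
        )
        self.valid = (
            np.zeros(n, dtype=bool)
            if valid is None and values is None
            else np.ones(n, dtype=bool)
            if valid is None
            else np.asarray(valid, dtype=bool).copy()
        )
        if self.values.shape != (n,) or self.valid.shape != (n,):
            raise CompartmethError("track length does not match bin count")

    def copy(self) -> "BinTrack":
        return BinTrack(self.bin_table, self.values, self.valid)

    def chrom_values(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sl = self.bin_table.chrom_slice(chrom)
        return self.values[sl], self.valid[sl]

    def masked_mean(self) -> float:
        if not self.valid.any():
            raise CompartmethError("no valid bins")
        return float(self.values[self.valid].mean())


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sorted, overlapping/adjacent runs merged per chrom."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(Interval(chrom, cur_start, cur_end))
    return out


def overlap_fraction(query: Interval, targets: Sequence[Interval]) -> float:
    """Fraction of ``query`` bases covered by the union of ``targets``.

    Targets may be passed unmerged; they are unioned internally, so the
    result is invariant under permutation and under splitting a target.
    """
    if not targets:
        return 0.0
    covered = 0
    for t in merge_intervals(targets):
        if t.chrom != query.chrom:
            continue
        covered += max(0, min(query.end, t.end) - max(query.start, t.start))
    return covered / query.width


def interval_union_length(intervals: Iterable[Interval]) -> int:
    return sum(iv.width for iv in merge_intervals(intervals)) if intervals else 0


def jaccard(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Jaccard index between two interval sets (union of bases)."""
    a = merge_intervals(a) if a else []
    b = merge_intervals(b) if b else []
    inter = 0
    for iv in a:
        inter += sum(
            max(0, min(iv.end, t.end) - max(iv.start, t.start))
            for t in b
            if t.chrom == iv.chrom
        )
    union = interval_union_length(list(a) + list(b))
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# BED / bedGraph I/O
# ---------------------------------------------------------------------------

def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if (
                not stripped.strip()
                or stripped.startswith("#")
                or stripped.startswith("track")
                or stripped.startswith("browser")
            ):
                continue
            yield lineno, stripped


def read_bed(path, genome: Genome | None = None) -> list[Interval]:
    """Read a 3+-column BED file into a list of :class:`Interval`.

    Column 4 becomes ``label`` and column 5 ``value`` (where numeric).
    If a genome is given, chromosomes absent from it are rejected.
    """
    out: list[Interval] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom = parts[0]
        if genome is not None and chrom not in genome:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start >= end or start < 0:
            raise ParseError(
                f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
            )
        label = parts[3] if len(parts) > 3 and parts[3] != "." else None
        value = None
        if len(parts) > 4:
            try:
                value = float(parts[4])
            except ValueError:
                value = None
        out.append(Interval(chrom, start, end, value=value, label=label))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.label is not None or iv.value is not None:
                fields.append(iv.label if iv.label is not None else ".")
            if iv.value is not None:
                fields.append(FLOAT_FORMAT % iv.value)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path, bin_table: BinTable) -> BinTrack:
    """Read a bedGraph file onto a bin table by coverage-weighted mean.

    Records not aligned to bin boundaries are split across the bins they
    cover, weighted by covered bases. Bins with no record at all are
    masked. Overlapping records (two records covering the same base on the
    same chromosome) are an error. Chromosomes not in the bin table's
    genome are skipped with a warning.
    """
    genome = bin_table.genome
    wsum = np.zeros(bin_table.n_bins)
    cover = np.zeros(bin_table.n_bins, dtype=np.int64)
    seen: dict[str, list[tuple[int, int, int]]] = {}
    skipped: set[str] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom = parts[0]
        if chrom not in genome:
            skipped.add(chrom)
            continue
        try:
            start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed record") from None
        if start >= end or start < 0 or end > genome.length(chrom):
            raise ParseError(f"{path}:{lineno}: invalid interval")
        seen.setdefault(chrom, []).append((start, end, lineno))
        s = bin_table.bin_size
        offset = bin_table.offset_of(chrom)
        for k in range(start // s, (end - 1) // s + 1):
            lo, hi = max(start, k * s), min(end, (k + 1) * s)
            wsum[offset + k] += value * (hi - lo)
            cover[offset + k] += hi - lo
    for chrom, recs in seen.items():
        recs.sort()
        for (s1, e1, _), (s2, _e2, ln) in zip(recs, recs[1:]):
            if s2 < e1:
                raise ParseError(
                    f"{path}:{ln}: record overlaps a previous record on {chrom}"
                )
    if skipped:
        logger.warning(
            "%s: skipped chromosomes not in genome: %s", path, sorted(skipped)
        )
    valid = cover > 0
    values = np.zeros(bin_table.n_bins)
    values[valid] = wsum[valid] / cover[valid]
    return BinTrack(bin_table, values, valid)


def write_bedgraph(track: BinTrack, path) -> None:
    """Write one bedGraph record per unmasked bin (zero is a value)."""
    bt = track.bin_table
    with open(path, "w") as fh:
        for chrom in bt.genome.names:
            vals, valid = track.chrom_values(chrom)
            starts, ends = bt.starts_of(chrom), bt.ends_of(chrom)
            for k in np.flatnonzero(valid):
                fh.write(
                    f"{chrom}\t{starts[k]}\t{ends[k]}\t{FLOAT_FORMAT % vals[k]}\n"
                )


def track_to_intervals(
    track: BinTrack, predicate, merge: bool = True
) -> list[Interval]:
    """Intervals of the bins whose (valid) value satisfies ``predicate``."""
    bt = track.bin_table
    ivs: list[Interval] = []
    for chrom in bt.genome.names:
        vals, valid = track.chrom_values(chrom)
        starts, ends = bt.starts_of(chrom), bt.ends_of(chrom)
        hit = valid & predicate(vals)
        for k in np.flatnonzero(hit):
            ivs.append(Interval(chrom, int(starts[k]), int(ends[k])))
    return merge_intervals(ivs) if merge and ivs else ivs
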