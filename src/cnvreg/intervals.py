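"""Coordinate conventions and overlap arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` — the BED dialect
native to CNV caller output. Touching intervals (``end == start``) overlap
by zero bases and never merge. Strand is ignored throughout: copy-number
events are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "CoordinateError",
    "Interval",
    "GenomeMeta",
    "Genome",
    "Thresholds",
    "overlap_bp",
    "overlap_fraction",
    "reciprocal_overlap",
    "union_length",
]


class CoordinateError(ValueError):
    """Raised for malformed genomic coordinates (e.g. start >= end)."""


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeMeta:
    """One chromosome's metadata: length and ploidy category.

    ``category`` is one of ``autosome`` (ploidy 2 in both sexes), ``X``
    (2 in females, 1 in males) or ``Y`` (0 in females, 1 in males).
    """

    name: str
    length: int
    category: str = "autosome"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")
        if self.category not in ("autosome", "X", "Y"):
            raise ValueError(
                f"chromosome {self.name}: category must be autosome|X|Y, "
                f"got {self.category!r}"
            )

    def expected_ploidy(self, sex: str) -> int:
        """Expected copy count of this chromosome for a ``male``/``female`` sample."""
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be male|female, got {sex!r}")
        if self.category == "autosome":
            return 2
        if self.category == "X":
            return 2 if sex == "female" else 1
        return 0 if sex == "female" else 1


class Genome:
    """An ordered collection of chromosomes with unique names."""

    def __init__(self, chromosomes: Iterable[GenomeMeta]):
        self.chromosomes = list(chromosomes)
        self._by_name = {}
        for c in self.chromosomes:
            if c.name in self._by_name:
                raise ValueError(f"duplicate chromosome name {c.name!r}")
            self._by_name[c.name] = c

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> GenomeMeta:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]


@dataclass(frozen=True)
class Thresholds:
    """The pipeline's four overlap/length cutoffs.

    support_fraction
        Minimum one-way overlap fraction of a primary call by a single
        support-caller call for the primary call to be retained (default
        0.10; the comparison is inclusive, >=).
    reciprocal_fraction
        Minimum pairwise reciprocal overlap for two calls to be merged
        into the same CNVR (default 0.50).
    min_cnvr_length
        CNVRs shorter than this many bp are filtered out (default 200;
        a CNVR of exactly this length is kept).
    min_feature_overlap
        Minimum shared bases for a CNVR to count as overlapping an
        annotation feature (default 1).
    """

    support_fraction: float = 0.10
    reciprocal_fraction: float = 0.50
    min_cnvr_length: int = 200
    min_feature_overlap: int = 1

    def __post_init__(self) -> None:
        for name in ("support_fraction", "reciprocal_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_cnvr_length", "min_feature_overlap"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")


def overlap_bp(i1: Interval, i2: Interval) -> int:
    """Number of shared bases between two intervals (0 if disjoint or
    on different chromosomes). Touching half-open intervals share 0 bp."""
    if i1.chrom != i2.chrom:
        return 0
    return max(0, min(i1.end, i2.end) - max(i1.start, i2.start))


def overlap_fraction(query: Interval, target: Interval) -> float:
    """Fraction of *query* covered by *target*: overlap_bp / len(query).

    Asymmetric by construction — this is the "ratio of overlapped bases
    to the length of the primary call" used by the consensus filter.
    """
    return overlap_bp(query, target) / query.length


def reciprocal_overlap(i1: Interval, i2: Interval) -> float:
    """Symmetric overlap criterion: min of the two one-way fractions."""
    ov = overlap_bp(i1, i2)
    return min(ov / i1.length, ov / i2.length)


def union_length(intervals: Sequence[Interval]) -> int:
    """Total unique bases covered by a set of intervals.

    Overlaps are counted once; intervals on different chromosomes never
    merge. Equivalent to a per-base bitmap count.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    total = 0
    for ivs in by_chrom.values():
        ivs.sort(key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                total += cur_end - cur_start
                cur_start, cur_end = iv.start, iv.end
        total += cur_end - cur_start
    return total
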