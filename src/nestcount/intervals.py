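"""Genomic interval primitives (1-based, inclusive ends, GTF convention)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a contig; coordinates are 1-based inclusive."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different contig)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) inclusive pairs as sorted, disjoint, maximal runs.

    Adjacent intervals (end + 1 == next start) are merged: the union is over
    integer base positions, not real-line segments.
    """
    pairs = sorted(pairs)
    if not pairs:
        return []
    merged = [pairs[0]]
    for s, e in pairs[1:]:
        ls, le = merged[-1]
        if s <= le + 1:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def subtract_pairs(
    exon: tuple[int, int], cuts: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Delete every base of ``exon`` covered by any of ``cuts``.

    Returns the surviving pieces in order (possibly empty). ``cuts`` need not
    be sorted or disjoint.
    """
    pieces = [exon]
    for cs, ce in merge_intervals(cuts):
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if ce < s or cs > e:
                nxt.append((s, e))
                continue
            if cs > s:
                nxt.append((s, cs - 1))
            if ce < e:
                nxt.append((ce + 1, e))
        pieces = nxt
    return pieces


def union_length(pairs: Iterable[tuple[int, int]]) -> int:
    """Total number of distinct bases covered by the (start, end) pairs."""
    return sum(e - s + 1 for s, e in merge_intervals(pairs))
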