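"""Alignment ingest: fragment reconstruction from SAM/BAM.

Records are regrouped by read name, mates are joined into per-locus
fragments, CIGAR strings become aligned blocks (M/=/X runs; N and D gaps
excluded), and each fragment is classified by the number of distinct loci
it aligns to.  A fragment's multiplicity is the number of loci actually
observed for its read name; the NH tag, when present, is used only as a
consistency check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from nestcount.intervals import GenomicInterval, merge_intervals

log = logging.getLogger(__name__)


@dataclass
class AlignmentLocus:
    """One genomic alignment of a fragment: merged mate blocks on one contig."""

    contig: str
    blocks: list[GenomicInterval]
    strand: str
    is_primary: bool = True

    def block_pairs(self) -> list[tuple[int, int]]:
        return [(b.start, b.end) for b in self.blocks]

    def total_block_length(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass
class FragmentAlignment:
    """A sequencing fragment (read pair or single read) and its alignment loci."""

    fragment_id: str
    loci: list[AlignmentLocus] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.loci)

    def primary_locus(self) -> AlignmentLocus:
        for locus in self.loci:
            if locus.is_primary:
                return locus
        return self.loci[0]


def _blocks_1based(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    # get_blocks() yields 0-based half-open M/=/X runs, split at N and D
    return [(s + 1, e) for s, e in rec.get_blocks()]


def _mates_match(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> bool:
    return (
        r1.reference_id == r2.next_reference_id
        and r2.reference_id == r1.next_reference_id
        and r1.reference_start == r2.next_reference_start
        and r2.reference_start == r1.next_reference_start
    )


def _locus_from(
    recs: list[pysam.AlignedSegment], header: pysam.AlignmentHeader
) -> AlignmentLocus:
    contig = recs[0].reference_name
    pairs = merge_intervals([p for r in recs for p in _blocks_1based(r)])
    mate1 = next((r for r in recs if not r.is_read2), recs[0])
    strand = "-" if mate1.is_reverse else "+"
    primary = not any(r.is_secondary for r in recs)
    return AlignmentLocus(
        contig=contig,
        blocks=[GenomicInterval(contig, s, e, strand) for s, e in pairs],
        strand=strand,
        is_primary=primary,
    )


def _build_fragment(
    name: str, recs: list[pysam.AlignedSegment], header: pysam.AlignmentHeader
) -> FragmentAlignment:
    read1 = [r for r in recs if r.is_paired and r.is_read1]
    read2 = [r for r in recs if r.is_paired and r.is_read2]
    single = [r for r in recs if not r.is_paired]

    loci: list[AlignmentLocus] = []
    unmatched2 = list(read2)
    for r1 in read1:
        mate = next((r2 for r2 in unmatched2 if _mates_match(r1, r2)), None)
        if mate is not None:
            unmatched2.remove(mate)
            loci.append(_locus_from([r1, mate], header))
        else:
            # mate unmapped or on another contig: keep as a single-end locus
            loci.append(_locus_from([r1], header))
    for r2 in unmatched2:
        log.debug("read %s: mate2 alignment without matching mate1", name)
        loci.append(_locus_from([r2], header))
    for r in single:
        loci.append(_locus_from([r], header))

    frag = FragmentAlignment(fragment_id=name, loci=loci)
    nh_vals = {r.get_tag("NH") for r in recs if r.has_tag("NH")}
    if nh_vals and nh_vals != {frag.multiplicity}:
        log.warning(
            "read %s: NH tag %s disagrees with observed multiplicity %d",
            name,
            sorted(nh_vals),
            frag.multiplicity,
        )
    return frag


def parse_alignments(path) -> Iterator[FragmentAlignment]:
    """Read SAM/BAM and yield one :class:`FragmentAlignment` per read name.

    Unmapped and supplementary records are dropped.  Input may be
    name-grouped or coordinate-sorted: records are regrouped by name in
    memory before fragments are emitted.
    """
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        header = af.header
        for rec in af:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            if rec.cigartuples is None:
                continue
            by_name.setdefault(rec.query_name, []).append(rec)
    for name, recs in by_name.items():
        frag = _build_fragment(name, recs, header)
        if frag.loci:
            yield frag


def classify_fragments(
    fragments: Iterable[FragmentAlignment],
) -> tuple[list[FragmentAlignment], list[FragmentAlignment]]:
    """Partition fragments into uniquely mapped (one locus) and multimapped."""
    unique: list[FragmentAlignment] = []
    multi: list[FragmentAlignment] = []
    for frag in fragments:
        (unique if frag.multiplicity == 1 else multi).append(frag)
    return unique, multi
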