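"""Assignment core: interval index and largest-overlap fragment assignment.

Each alignment locus votes for genes by the number of its block bases
overlapping the genes' exonic intervals (after gapping).  A unique strict
maximum wins; an exact tie between two or more genes is ambiguous; no
exonic overlap at all is unassigned.  Unassigned unique fragments whose
blocks lie entirely within a hosting feature (the intron or retained-intron
exon containing a nested gene) are tallied as pure background for that
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from intervaltree import IntervalTree

from nestcount.alignments import AlignmentLocus, FragmentAlignment
from nestcount.annotation import GappedAnnotation, GeneModel
from nestcount.intervals import union_length

Strandedness = Literal["unstranded", "forward", "reverse"]

EXONIC = "exonic"
HOSTING = "hosting_feature"

HostingKey = tuple[str, tuple[int, int]]  # (host gene_id, (start, end))


@dataclass
class FeatureIndex:
    """Per-contig interval index over exonic and hosting-feature intervals."""

    exonic: dict[str, IntervalTree] = field(default_factory=dict)
    hosting: dict[str, IntervalTree] = field(default_factory=dict)
    gene_strand: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes: Sequence[GeneModel]) -> "FeatureIndex":
        """Index an annotation's exon intervals (gapped or not)."""
        idx = cls()
        for gene in genes:
            idx.gene_strand[gene.gene_id] = gene.strand
            for exon in gene.exon_intervals():
                tree = idx.exonic.setdefault(gene.contig, IntervalTree())
                # interval tree is half-open; store [start, end+1)
                tree.addi(exon.start, exon.end + 1, gene.gene_id)
        return idx

    @classmethod
    def from_annotation(cls, annotation: GappedAnnotation) -> "FeatureIndex":
        idx = cls.from_genes(annotation.full)
        for host in annotation.hosting_features:
            for tx in host.transcripts:
                for iv in tx.exons:
                    tree = idx.hosting.setdefault(host.contig, IntervalTree())
                    tree.addi(iv.start, iv.end + 1, (host.gene_id, (iv.start, iv.end)))
        return idx

    def query_exonic(self, contig: str, pos: int) -> set[str]:
        tree = self.exonic.get(contig)
        if tree is None:
            return set()
        return {hit.data for hit in tree.at(pos)}

    def hosting_hits(self, contig: str, start: int, end: int) -> set[HostingKey]:
        tree = self.hosting.get(contig)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(start, end + 1)}


@dataclass
class LocusAssignment:
    gene_votes: dict[str, int]
    outcome: Literal["assigned", "ambiguous", "unassigned"]
    gene_id: str | None = None


def _strand_ok(gene_strand: str, locus_strand: str, strandedness: Strandedness) -> bool:
    if strandedness == "unstranded" or gene_strand == ".":
        return True
    if strandedness == "forward":
        return gene_strand == locus_strand
    return gene_strand != locus_strand


def assign_locus(
    locus: AlignmentLocus,
    index: FeatureIndex,
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
) -> LocusAssignment:
    """Score one alignment locus against the exonic index.

    Votes are distinct overlapped bases per gene (a base covered by several
    transcripts of the same gene counts once).  Strand filtering compares
    the gene strand with the strand of mate 1.
    """
    tree_hits: dict[str, list[tuple[int, int]]] = {}
    trees = index.exonic.get(locus.contig)
    if trees is not None:
        for block in locus.blocks:
            for hit in trees.overlap(block.start, block.end + 1):
                gid = hit.data
                tree_hits.setdefault(gid, []).append(
                    (max(block.start, hit.begin), min(block.end, hit.end - 1))
                )
    votes: dict[str, int] = {}
    for gid, pairs in tree_hits.items():
        if not _strand_ok(index.gene_strand.get(gid, "."), locus.strand, strandedness):
            continue
        ov = union_length(pairs)
        if ov >= min_overlap:
            votes[gid] = ov
    if not votes:
        return LocusAssignment(gene_votes={}, outcome="unassigned")
    best = max(votes.values())
    winners = [g for g, v in votes.items() if v == best]
    if len(winners) == 1:
        return LocusAssignment(gene_votes=votes, outcome="assigned", gene_id=winners[0])
    return LocusAssignment(gene_votes=votes, outcome="ambiguous")


@dataclass
class UniqueCounts:
    unique_counts: dict[str, float]
    ambiguous_count: int
    unassigned_count: int
    hosting_counts: dict[HostingKey, int]


def _pure_background_key(
    locus: AlignmentLocus, index: FeatureIndex
) -> HostingKey | None:
    """Hosting interval fully containing every block, or None."""
    keys: set[HostingKey] | None = None
    for block in locus.blocks:
        hits = {
            k
            for k in index.hosting_hits(locus.contig, block.start, block.end)
            if k[1][0] <= block.start and block.end <= k[1][1]
        }
        keys = hits if keys is None else keys & hits
        if not keys:
            return None
    if keys:
        return sorted(keys)[0]
    return None


def count_unique(
    unique_fragments: Iterable[FragmentAlignment],
    index: FeatureIndex,
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
) -> UniqueCounts:
    """Count uniquely mapped fragments: each contributes one to exactly one
    of {a gene, ambiguous, unassigned}.

    Unassigned fragments falling entirely inside a hosting feature (no
    exonic overlap anywhere, nested genes included) also increment that
    feature's background tally.
    """
    counts: dict[str, float] = {}
    ambiguous = 0
    unassigned = 0
    hosting: dict[HostingKey, int] = {}
    for frag in unique_fragments:
        locus = frag.loci[0]
        res = assign_locus(locus, index, strandedness, min_overlap)
        if res.outcome == "assigned":
            counts[res.gene_id] = counts.get(res.gene_id, 0) + 1
        elif res.outcome == "ambiguous":
            ambiguous += 1
        else:
            unassigned += 1
            key = _pure_background_key(locus, index)
            if key is not None:
                hosting[key] = hosting.get(key, 0) + 1
    return UniqueCounts(
        unique_counts=counts,
        ambiguous_count=ambiguous,
        unassigned_count=unassigned,
        hosting_counts=hosting,
    )
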