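"""Annotation engine: GTF parsing, redundancy filtering and exon gapping.

The central operation is :func:`subtract_nested`, which removes from every
host-gene exon the positions overlapped by nested small-RNA genes (snoRNA,
scaRNA, snRNA, tRNA, miRNA by default).  An exon fully containing a nested
gene is split in two; an exon overlapped at its edge is truncated; an exon
fully inside a nested gene disappears.  The result is a *gapped* annotation
in which a read falling on a nested gene can no longer tie with its host,
plus a companion *hosting-feature* annotation listing, per host gene, the
intron (or retained-intron exon) that contains each nested gene — the
substrate for background estimation during counting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from nestcount.intervals import GenomicInterval, merge_intervals, subtract_pairs

log = logging.getLogger(__name__)

#: Biotypes treated as nested genes to be carved out of host exons.
NESTED_BIOTYPES = frozenset({"snoRNA", "scaRNA", "snRNA", "tRNA", "miRNA"})


class GtfParseError(ValueError):
    """Raised on a malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def sort_exons(self) -> None:
        self.exons.sort(key=lambda iv: (iv.start, iv.end))

    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene with its biotype, genomic span and transcript/exon structure."""

    gene_id: str
    gene_name: str
    biotype: str
    span: GenomicInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    all_exons_removed: bool = False

    @property
    def contig(self) -> str:
        return self.span.contig

    @property
    def strand(self) -> str:
        return self.span.strand

    def exon_intervals(self) -> list[GenomicInterval]:
        return [e for t in self.transcripts for e in t.exons]


@dataclass
class GappedAnnotation:
    """Gapped gene models plus the hosting-feature companion annotation.

    ``full`` holds every gene with host exons gapped; ``hosting_features``
    holds one synthetic gene per host whose exons are the hosting intervals
    (introns or retained-intron exons containing a nested gene);
    ``removed_regions`` records, per host gene_id, which intervals were
    subtracted.
    """

    full: list[GeneModel]
    hosting_features: list[GeneModel]
    removed_regions: dict[str, list[GenomicInterval]]


_ATTR_RE = re.compile(r'(\S+) "([^"]*)"')


def _parse_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def parse_gtf(path) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    Gene/transcript structure is assembled from ``gene``, ``transcript`` and
    ``exon`` features; files carrying only exon lines are accepted (gene
    spans are then inferred from exon unions).  Genes without a
    ``gene_biotype`` attribute get biotype ``"unknown"``.
    """
    genes: dict[str, GeneModel] = {}
    transcripts: dict[tuple[str, str], TranscriptModel] = {}
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}", lineno
                )
            contig, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
                ) from None
            if end < start:
                raise GtfParseError(f"end ({end}) < start ({start})", lineno)
            if start < 1:
                raise GtfParseError(f"start ({start}) < 1", lineno)
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise GtfParseError("missing gene_id attribute", lineno)
            if strand not in ("+", "-", "."):
                raise GtfParseError(f"invalid strand {strand!r}", lineno)

            iv = GenomicInterval(contig, start, end, strand)
            gene = genes.get(gene_id)
            if gene is None:
                gene = GeneModel(
                    gene_id=gene_id,
                    gene_name=attrs.get("gene_name", gene_id),
                    biotype=attrs.get("gene_biotype", "unknown"),
                    span=iv,
                )
                genes[gene_id] = gene
                gene_order.append(gene_id)
            else:
                if gene.contig != contig or gene.strand != strand:
                    raise GtfParseError(
                        f"gene_id {gene_id!r} seen with conflicting contig/strand",
                        lineno,
                    )

            if feature == "gene":
                gene.span = iv
                if "gene_biotype" in attrs:
                    gene.biotype = attrs["gene_biotype"]
                if "gene_name" in attrs:
                    gene.gene_name = attrs["gene_name"]
            elif feature in ("transcript", "exon"):
                tid = attrs.get("transcript_id")
                if not tid:
                    raise GtfParseError(
                        f"{feature} line missing transcript_id", lineno
                    )
                key = (gene_id, tid)
                tx = transcripts.get(key)
                if tx is None:
                    tx = TranscriptModel(transcript_id=tid)
                    transcripts[key] = tx
                    gene.transcripts.append(tx)
                if feature == "exon":
                    tx.exons.append(iv)
            # other feature types (CDS, UTR, ...) are ignored

    for gene in genes.values():
        for tx in gene.transcripts:
            tx.sort_exons()
        exons = gene.exon_intervals()
        if exons:
            lo = min(e.start for e in exons)
            hi = max(e.end for e in exons)
            # span must cover the exon union; widen if the gene line was absent
            gene.span = GenomicInterval(
                gene.contig,
                min(gene.span.start, lo),
                max(gene.span.end, hi),
                gene.strand,
            )
    return [genes[g] for g in gene_order]


def filter_redundant_genes(
    genes: Sequence[GeneModel], threshold: float = 0.9
) -> tuple[list[GeneModel], list[tuple[str, str]]]:
    """Drop genes that reciprocally overlap a same-biotype gene over more
    than ``threshold`` of both spans.

    Keeping both members of such a pair would make every read aligning to
    them ambiguous.  Within a violating pair the gene whose gene_id sorts
    lexicographically later is removed; removal is applied transitively so
    that no kept pair violates the rule.  Returns the kept genes (input
    order) and the list of (kept_id, removed_id) pairs.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    # Greedy scan in lexicographic gene_id order: a gene is dropped iff it
    # violates the rule against an already-kept gene. Deterministic, and the
    # removed member of each offending pair is always the later-sorting one.
    kept: list[GeneModel] = []
    removed_pairs: list[tuple[str, str]] = []
    by_key: dict[tuple[str, str], list[GeneModel]] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        clash = None
        for other in by_key.get((gene.contig, gene.biotype), ()):
            ov = gene.span.overlap_len(other.span)
            if ov / len(gene.span) > threshold and ov / len(other.span) > threshold:
                clash = other
                break
        if clash is not None:
            removed_pairs.append((clash.gene_id, gene.gene_id))
        else:
            kept.append(gene)
            by_key.setdefault((gene.contig, gene.biotype), []).append(gene)
    kept_ids = {g.gene_id for g in kept}
    ordered = [g for g in genes if g.gene_id in kept_ids]
    if removed_pairs:
        log.info("redundancy filter removed %d gene(s)", len(removed_pairs))
    return ordered, removed_pairs


def _main_transcript(gene: GeneModel) -> TranscriptModel | None:
    """Transcript with greatest summed exon length; ties go to the
    lexicographically smallest transcript_id."""
    if not gene.transcripts:
        return None
    return min(gene.transcripts, key=lambda t: (-t.exonic_length(), t.transcript_id))


def _hosting_intervals(
    host: GeneModel, nested: Sequence[GeneModel]
) -> list[GenomicInterval]:
    """Intervals of ``host`` (pre-gapping structure) that contain a nested gene.

    Emitted at intron granularity: each inter-exon gap of the host's main
    transcript overlapping >= 1 nested gene becomes one interval.  A nested
    gene sitting inside a retained-intron *exon* of the main transcript
    (hence inside no intron) falls back to that exon.
    """
    tx = _main_transcript(host)
    if tx is None or not tx.exons:
        return []
    introns: list[GenomicInterval] = []
    for a, b in zip(tx.exons, tx.exons[1:]):
        if b.start > a.end + 1:
            introns.append(
                GenomicInterval(host.contig, a.end + 1, b.start - 1, host.strand)
            )
    out: list[GenomicInterval] = []
    for n in nested:
        hit = next((iv for iv in introns if iv.overlap_len(n.span) > 0), None)
        if hit is None:
            hit = next((e for e in tx.exons if e.overlap_len(n.span) > 0), None)
        if hit is not None and hit not in out:
            out.append(hit)
    return sorted(out, key=lambda iv: iv.start)


def subtract_nested(
    genes: Sequence[GeneModel],
    nested_biotypes: frozenset[str] | set[str] = NESTED_BIOTYPES,
    stranded: bool = False,
) -> GappedAnnotation:
    """Carve nested-biotype gene spans out of every other gene's exons.

    Overlap is computed ignoring strand by default (``stranded=True``
    restricts subtraction to same-strand nested genes).  Nested-biotype
    genes themselves pass through untouched.  A host gene whose every exon
    is deleted stays in ``full`` with an empty exon set and is flagged.
    """
    if not nested_biotypes:
        raise ValueError("nested_biotypes must be non-empty")
    nested = [g for g in genes if g.biotype in nested_biotypes]
    nested_by_contig: dict[str, list[GeneModel]] = {}
    for n in nested:
        nested_by_contig.setdefault(n.contig, []).append(n)

    full: list[GeneModel] = []
    hosting: list[GeneModel] = []
    removed: dict[str, list[GenomicInterval]] = {}

    for gene in genes:
        if gene.biotype in nested_biotypes:
            full.append(gene)
            continue
        cand = nested_by_contig.get(gene.contig, [])
        if stranded:
            cand = [n for n in cand if n.strand == gene.strand]
        cuts = [
            (n.span.start, n.span.end)
            for n in cand
            if n.span.overlap_len(gene.span) > 0
        ]
        if not cuts:
            full.append(gene)
            continue

        cut_regions: list[tuple[int, int]] = []
        new_transcripts: list[TranscriptModel] = []
        for tx in gene.transcripts:
            new_exons: list[GenomicInterval] = []
            for exon in tx.exons:
                pieces = subtract_pairs((exon.start, exon.end), cuts)
                for s, e in pieces:
                    new_exons.append(GenomicInterval(gene.contig, s, e, gene.strand))
                lost = merge_intervals(
                    [
                        (max(exon.start, cs), min(exon.end, ce))
                        for cs, ce in cuts
                        if cs <= exon.end and ce >= exon.start
                    ]
                )
                cut_regions.extend(lost)
            ntx = TranscriptModel(tx.transcript_id, new_exons)
            ntx.sort_exons()
            new_transcripts.append(ntx)

        gapped = GeneModel(
            gene_id=gene.gene_id,
            gene_name=gene.gene_name,
            biotype=gene.biotype,
            span=gene.span,
            transcripts=new_transcripts,
        )
        if cut_regions:
            removed[gene.gene_id] = [
                GenomicInterval(gene.contig, s, e, gene.strand)
                for s, e in merge_intervals(cut_regions)
            ]
        if not gapped.exon_intervals() and gene.exon_intervals():
            gapped.all_exons_removed = True
            log.warning(
                "gene %s lost all exons to nested-gene subtraction", gene.gene_id
            )
        full.append(gapped)

        # hosting features come from the ORIGINAL structure of hosts that
        # actually overlap a nested gene (whether or not exons were cut:
        # intron-nested genes cut nothing but still define a hosting intron)
        overlapping = [n for n in cand if n.span.overlap_len(gene.span) > 0]
        hiv = _hosting_intervals(gene, overlapping)
        if hiv:
            hosting.append(
                GeneModel(
                    gene_id=gene.gene_id,
                    gene_name=gene.gene_name,
                    biotype=gene.biotype,
                    span=gene.span,
                    transcripts=[
                        TranscriptModel(f"{gene.gene_id}::hosting", list(hiv))
                    ],
                )
            )
    return GappedAnnotation(full=full, hosting_features=hosting, removed_regions=removed)


def merge_supplement(
    base: Sequence[GeneModel], extra: Sequence[GeneModel]
) -> list[GeneModel]:
    """Union of two annotations; colliding gene_ids are an error."""
    seen = {g.gene_id for g in base}
    for g in extra:
        if g.gene_id in seen:
            raise ValueError(f"gene_id collision in supplement: {g.gene_id!r}")
    return list(base) + list(extra)


def _fmt_attrs(pairs: Iterable[tuple[str, str]]) -> str:
    return "".join(f'{k} "{v}"; ' for k, v in pairs).rstrip()


def write_gene_records(genes: Iterable[GeneModel], fh, source: str = "nestcount") -> None:
    for gene in genes:
        gattrs = [
            ("gene_id", gene.gene_id),
            ("gene_name", gene.gene_name),
            ("gene_biotype", gene.biotype),
        ]
        fh.write(
            "\t".join(
                [
                    gene.contig,
                    source,
                    "gene",
                    str(gene.span.start),
                    str(gene.span.end),
                    ".",
                    gene.strand,
                    ".",
                    _fmt_attrs(gattrs),
                ]
            )
            + "\n"
        )
        for tx in gene.transcripts:
            if not tx.exons:
                continue
            tattrs = gattrs + [("transcript_id", tx.transcript_id)]
            fh.write(
                "\t".join(
                    [
                        gene.contig,
                        source,
                        "transcript",
                        str(min(e.start for e in tx.exons)),
                        str(max(e.end for e in tx.exons)),
                        ".",
                        gene.strand,
                        ".",
                        _fmt_attrs(tattrs),
                    ]
                )
                + "\n"
            )
            for i, exon in enumerate(tx.exons, start=1):
                eattrs = tattrs + [("exon_number", str(i))]
                fh.write(
                    "\t".join(
                        [
                            gene.contig,
                            source,
                            "exon",
                            str(exon.start),
                            str(exon.end),
                            ".",
                            gene.strand,
                            ".",
                            _fmt_attrs(eattrs),
                        ]
                    )
                    + "\n"
                )


def write_genes_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write a plain gene collection as Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        fh.write("#!nestcount annotation\n")
        write_gene_records(genes, fh)


def write_gtf(annotation: GappedAnnotation, full_path, hosting_path) -> None:
    """Write the gapped 'full' GTF and the companion hosting-feature GTF.

    Exon records are renumbered consecutively after splits; both files
    round-trip through :func:`parse_gtf` with intervals preserved exactly.
    """
    write_genes_gtf(annotation.full, full_path)
    with open(hosting_path, "w") as fh:
        fh.write("#!nestcount hosting features (introns/exons containing nested genes)\n")
        write_gene_records(annotation.hosting_features, fh)
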