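"""Annotation engine: GTF parsing, redundancy filter, nested-gene gapping."""

import itertools

import pytest
from hypothesis import given, strategies as st

from nestcount.annotation import (
    GeneModel,
    GtfParseError,
    TranscriptModel,
    filter_redundant_genes,
    merge_supplement,
    parse_gtf,
    subtract_nested,
    write_genes_gtf,
    write_gtf,
)
from nestcount.intervals import GenomicInterval


def make_gene(gene_id, biotype, start, end, strand="+", contig="chr1", exons=None):
    span = GenomicInterval(contig, start, end, strand)
    if exons is None:
        exons = [(start, end)]
    tx = TranscriptModel(
        f"{gene_id}-t1", [GenomicInterval(contig, s, e, strand) for s, e in exons]
    )
    return GeneModel(gene_id, gene_id, biotype, span, [tx])


GTF_3LINE = """chr1\tsrc\tgene\t100\t200\t.\t+\t.\tgene_id "G1"; gene_biotype "snoRNA";
chr1\tsrc\ttranscript\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""


class TestParseGtf:
    def test_minimal_gene(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_3LINE)
        genes = parse_gtf(p)
        assert len(genes) == 1
        g = genes[0]
        assert g.gene_id == "G1" and g.biotype == "snoRNA"
        assert len(g.transcripts) == 1
        assert g.transcripts[0].exons == [GenomicInterval("chr1", 100, 200, "+")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.gtf"
        p.write_text("")
        assert parse_gtf(p) == []

    def test_reversed_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(
            GTF_3LINE
            + 'chr1\tsrc\texon\t100\t99\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        )
        with pytest.raises(GtfParseError) as exc:
            parse_gtf(p)
        assert exc.value.line_number == 4

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\tsrc\texon\t1\t10\t.\t+\t.",  # 8 columns
            'chr1\tsrc\texon\tx\t10\t.\t+\t.\tgene_id "G";',  # non-integer
            'chr1\tsrc\texon\t1\t10\t.\t+\t.\tfoo "bar";',  # no gene_id
            'chr1\tsrc\texon\t1\t10\t.\t+\t.\tgene_id "G";',  # no transcript_id
        ],
    )
    def test_malformed_lines_raise(self, tmp_path, line):
        p = tmp_path / "bad.gtf"
        p.write_text(line + "\n")
        with pytest.raises(GtfParseError):
            parse_gtf(p)

    def test_conflicting_strand_raises(self, tmp_path):
        p = tmp_path / "dup.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "G";\n'
            'chr1\tsrc\tgene\t1\t10\t.\t-\t.\tgene_id "G";\n'
        )
        with pytest.raises(GtfParseError):
            parse_gtf(p)

    def test_missing_biotype_defaults_to_unknown(self, tmp_path):
        p = tmp_path / "n.gtf"
        p.write_text('chr1\tsrc\tgene\t1\t10\t.\t+\t.\tgene_id "G";\n')
        assert parse_gtf(p)[0].biotype == "unknown"


def brute_force_redundancy(genes, threshold=0.9):
    """All-pairs reference check: no kept pair may violate the rule."""
    removed = set()
    for a, b in itertools.combinations(sorted(genes, key=lambda g: g.gene_id), 2):
        if a.gene_id in removed or b.gene_id in removed:
            continue
        if a.biotype != b.biotype:
            continue
        ov = a.span.overlap_len(b.span)
        if ov / len(a.span) > threshold and ov / len(b.span) > threshold:
            removed.add(max(a.gene_id, b.gene_id))
    return removed


class TestRedundancyFilter:
    def test_reciprocal_overlap_above_threshold_removes_one(self):
        a = make_gene("A", "snoRNA", 100, 200)
        b = make_gene("B", "snoRNA", 105, 195)
        kept, removed = filter_redundant_genes([a, b])
        assert [g.gene_id for g in kept] == ["A"]
        assert removed == [("A", "B")]

    def test_one_sided_overlap_keeps_both(self):
        a = make_gene("A", "snoRNA", 100, 200)
        b = make_gene("B", "snoRNA", 150, 400)
        kept, removed = filter_redundant_genes([a, b])
        assert len(kept) == 2 and removed == []

    def test_different_biotypes_coincident_keep_both(self):
        a = make_gene("A", "snoRNA", 100, 200)
        b = make_gene("B", "miRNA", 100, 200)
        kept, _ = filter_redundant_genes([a, b])
        assert len(kept) == 2

    def test_exact_threshold_keeps_both(self):
        # overlap exactly 90% of both spans: strict inequality keeps both
        a = make_gene("A", "snoRNA", 1, 100)
        b = make_gene("B", "snoRNA", 11, 110)
        kept, _ = filter_redundant_genes([a, b])
        assert len(kept) == 2

    @given(st.data())
    def test_agrees_with_brute_force(self, data):
        n = data.draw(st.integers(1, 30))
        genes = []
        for i in range(n):
            start = data.draw(st.integers(1, 500))
            length = data.draw(st.integers(1, 120))
            bt = data.draw(st.sampled_from(["snoRNA", "miRNA"]))
            genes.append(make_gene(f"G{i:03d}", bt, start, start + length - 1))
        kept, removed = filter_redundant_genes(genes)
        assert {r for _, r in removed} == brute_force_redundancy(genes)
        # no kept pair violates the rule
        for a, b in itertools.combinations(kept, 2):
            if a.biotype != b.biotype:
                continue
            ov = a.span.overlap_len(b.span)
            assert not (ov / len(a.span) > 0.9 and ov / len(b.span) > 0.9)


def host_with_exon(exon, nested_span=None, contig="chr1"):
    genes = [make_gene("HOST", "protein_coding", exon[0], exon[1], exons=[exon])]
    if nested_span:
        genes.append(make_gene("SNO", "snoRNA", *nested_span))
    return genes


class TestSubtractNested:
    @pytest.mark.parametrize(
        "exon, nested, expected",
        [
            ((100, 500), (200, 260), [(100, 199), (261, 500)]),  # split in two
            ((100, 500), (450, 520), [(100, 449)]),  # edge truncation
            ((100, 500), (50, 120), [(121, 500)]),  # left truncation
        ],
    )
    def test_exon_surgery(self, exon, nested, expected):
        ann = subtract_nested(host_with_exon(exon, nested))
        host = next(g for g in ann.full if g.gene_id == "HOST")
        got = [(e.start, e.end) for e in host.transcripts[0].exons]
        assert got == expected

    def test_no_nested_gene_leaves_exon_unchanged(self):
        ann = subtract_nested(host_with_exon((100, 500)))
        host = ann.full[0]
        assert [(e.start, e.end) for e in host.transcripts[0].exons] == [(100, 500)]

    def test_exon_fully_inside_nested_gene_vanishes(self):
        ann = subtract_nested(host_with_exon((210, 240), (200, 260)))
        host = next(g for g in ann.full if g.gene_id == "HOST")
        assert host.exon_intervals() == [] and host.all_exons_removed

    def test_nested_genes_carried_unmodified(self):
        genes = host_with_exon((100, 500), (200, 260))
        ann = subtract_nested(genes)
        sno = next(g for g in ann.full if g.gene_id == "SNO")
        assert sno.exon_intervals() == genes[1].exon_intervals()

    def test_gap_completeness(self):
        """No surviving host exon base may overlap any nested gene span."""
        genes = host_with_exon((100, 500), (200, 260))
        genes.append(make_gene("TRNA", "tRNA", 480, 530))
        ann = subtract_nested(genes)
        nested_spans = [g.span for g in ann.full if g.biotype in ("snoRNA", "tRNA")]
        for g in ann.full:
            if g.biotype in ("snoRNA", "tRNA"):
                continue
            for exon in g.exon_intervals():
                for span in nested_spans:
                    assert exon.overlap_len(span) == 0

    def test_idempotence(self):
        genes = host_with_exon((100, 500), (200, 260))
        once = subtract_nested(genes)
        twice = subtract_nested(once.full)
        assert [
            [(e.start, e.end) for e in g.exon_intervals()] for g in once.full
        ] == [[(e.start, e.end) for e in g.exon_intervals()] for g in twice.full]

    def test_stranded_subtraction_skips_opposite_strand(self):
        genes = [
            make_gene("HOST", "protein_coding", 100, 500, strand="+"),
            make_gene("SNO", "snoRNA", 200, 260, strand="-"),
        ]
        ann = subtract_nested(genes, stranded=True)
        host = next(g for g in ann.full if g.gene_id == "HOST")
        assert [(e.start, e.end) for e in host.transcripts[0].exons] == [(100, 500)]

    def test_removed_regions_overlap_nested_genes(self):
        ann = subtract_nested(host_with_exon((100, 500), (200, 260)))
        assert ann.removed_regions["HOST"] == [GenomicInterval("chr1", 200, 260, "+")]

    def test_hosting_feature_for_intronic_nested_gene(self):
        host = make_gene(
            "HOST", "protein_coding", 100, 1000, exons=[(100, 200), (800, 1000)]
        )
        sno = make_gene("SNO", "snoRNA", 400, 460)
        ann = subtract_nested([host, sno])
        assert len(ann.hosting_features) == 1
        iv = ann.hosting_features[0].transcripts[0].exons[0]
        assert (iv.start, iv.end) == (201, 799)  # the whole intron

    def test_hosting_feature_retained_intron_falls_back_to_exon(self):
        host = make_gene("HOST", "protein_coding", 100, 1000, exons=[(100, 1000)])
        sno = make_gene("SNO", "snoRNA", 400, 460)
        ann = subtract_nested([host, sno])
        iv = ann.hosting_features[0].transcripts[0].exons[0]
        assert (iv.start, iv.end) == (100, 1000)


class TestMergeAndRoundTrip:
    def test_merge_supplement(self):
        base = [make_gene("A", "snoRNA", 1, 10), make_gene("B", "snoRNA", 20, 30)]
        extra = [make_gene("C", "tRNA", 40, 50)]
        assert len(merge_supplement(base, extra)) == 3
        assert merge_supplement(base, []) == base
        with pytest.raises(ValueError, match="A"):
            merge_supplement(base, [make_gene("A", "tRNA", 5, 9)])

    def test_write_then_parse_round_trip(self, tmp_path):
        genes = host_with_exon((100, 500), (200, 260))
        genes[0].transcripts.append(
            TranscriptModel("HOST-t2", [GenomicInterval("chr1", 100, 150, "+")])
        )
        ann = subtract_nested(genes)
        full, introns = tmp_path / "full.gtf", tmp_path / "introns.gtf"
        write_gtf(ann, full, introns)
        reparsed = {g.gene_id: g for g in parse_gtf(full)}
        for g in ann.full:
            got = reparsed[g.gene_id]
            assert [(e.start, e.end) for e in got.exon_intervals()] == [
                (e.start, e.end) for e in g.exon_intervals()
            ]
            assert got.biotype == g.biotype and got.strand == g.strand

    def test_no_nested_genes_gives_header_only_introns_file(self, tmp_path):
        genes = [make_gene("A", "protein_coding", 1, 100)]
        ann = subtract_nested(genes)
        full, introns = tmp_path / "f.gtf", tmp_path / "i.gtf"
        write_gtf(ann, full, introns)
        lines = introns.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    @given(st.data())
    def test_round_trip_random_annotations(self, data):
        import tempfile
        from pathlib import Path

        n = data.draw(st.integers(1, 8))
        genes = []
        pos = 1
        for i in range(n):
            nex = data.draw(st.integers(1, 4))
            exons = []
            for _ in range(nex):
                pos += data.draw(st.integers(1, 50))
                length = data.draw(st.integers(1, 80))
                exons.append((pos, pos + length - 1))
                pos += length
            genes.append(
                make_gene(
                    f"G{i}",
                    data.draw(st.sampled_from(["protein_coding", "snoRNA"])),
                    exons[0][0],
                    exons[-1][1],
                    strand=data.draw(st.sampled_from(["+", "-"])),
                    exons=exons,
                )
            )
        with tempfile.TemporaryDirectory() as td:
            p = Path(td) / "rt.gtf"
            write_genes_gtf(genes, p)
            reparsed = parse_gtf(p)
        assert [(g.gene_id, [(e.start, e.end) for e in g.exon_intervals()]) for g in genes] == [
            (g.gene_id, [(e.start, e.end) for e in g.exon_intervals()]) for g in reparsed
        ]
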