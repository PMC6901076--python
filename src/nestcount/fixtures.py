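"""Synthetic GTF + SAM scenario generator with ground-truth manifests.

Each scenario instantiates one of the read-assignment situations the
pipeline exists to fix, on a single synthetic contig ``chrT``:

- ``nested_basic``   a host gene with a retained-intron exon containing a
                     nested snoRNA, plus reads fully inside the snoRNA,
                     reads slightly exceeding its annotation, host-only
                     reads and exactly-balanced ambiguous reads;
- ``nested_exceeds`` only the annotation-exceeding reads;
- ``snord103``       two snoRNA paralogs with byte-identical 70-nt bodies
                     and distinct flanks: 87 uniquely mapped flank-spanning
                     pairs and 2,314 pairs reported at both loci;
- ``mir101``         a paralog pair where only one member has uniquely
                     mapped reads (160) plus 5,335 dual-reported pairs;
- ``background_hot`` a miRNA inside a highly covered host intron (the
                     background subtraction floors its count at zero);
- ``background_low`` the same locus with sparse intronic background;
- ``redundancy_pairs`` same-biotype gene pairs around the >90% reciprocal
                     overlap threshold (no reads).

Reads are written as 2 x 50-nt proper pairs (fragment length drawn
uniformly in a category-dependent legal window); multimapped fragments get
a primary pair at one locus and a secondary pair at the other, NH:i:2 on
all records.  Sequences are arbitrary (assignment never inspects bases).
Identical scenario + seed give byte-identical SAM output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from nestcount.annotation import GeneModel, TranscriptModel, write_genes_gtf
from nestcount.intervals import GenomicInterval

CONTIG = "chrT"
READ_LEN = 50


@dataclass
class SamRecord:
    qname: str
    flag: int
    pos: int  # 1-based leftmost
    mapq: int
    cigar: str
    pnext: int
    tlen: int
    nh: int
    rname: str = CONTIG

    def to_line(self) -> str:
        seq = "A" * READ_LEN
        qual = "I" * READ_LEN
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                self.rname,
                str(self.pos),
                str(self.mapq),
                self.cigar,
                "=",
                str(self.pnext),
                str(self.tlen),
                seq,
                qual,
                f"NH:i:{self.nh}",
            ]
        )


@dataclass
class Scenario:
    name: str
    contig_length: int
    genes: list[GeneModel]
    records: list[SamRecord] = field(default_factory=list)
    truth: dict = field(default_factory=dict)


def _pair(
    qname: str, start: int, frag_len: int, nh: int = 1, secondary: bool = False
) -> list[SamRecord]:
    """A proper pair covering fragment [start, start+frag_len-1]."""
    assert frag_len >= READ_LEN
    p1, p2 = start, start + frag_len - READ_LEN
    f1, f2 = 99, 147  # paired, proper, mate-reverse/reverse, first/second
    mapq = 255
    if secondary:
        f1, f2, mapq = f1 | 0x100, f2 | 0x100, 0
    elif nh > 1:
        mapq = 0
    cig = f"{READ_LEN}M"
    return [
        SamRecord(qname, f1, p1, mapq, cig, p2, frag_len, nh),
        SamRecord(qname, f2, p2, mapq, cig, p1, -frag_len, nh),
    ]


def _dual_pair(qname: str, start_a: int, start_b: int, frag_len: int) -> list[SamRecord]:
    """A multimapped fragment: primary pair at ``start_a``, secondary at
    ``start_b`` (same within-locus offset)."""
    return _pair(qname, start_a, frag_len, nh=2) + _pair(
        qname, start_b, frag_len, nh=2, secondary=True
    )


def _simple_gene(
    gene_id: str, biotype: str, start: int, end: int, strand: str = "+"
) -> GeneModel:
    span = GenomicInterval(CONTIG, start, end, strand)
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=biotype,
        span=span,
        transcripts=[TranscriptModel(f"{gene_id}-t1", [span])],
    )


# ---------------------------------------------------------------- scenarios


def _paralog_scenario(
    name: str,
    gene_ids: tuple[str, str],
    biotype: str,
    body_len: int,
    n_unique: tuple[int, int],
    n_multi: int,
    seed: int,
) -> Scenario:
    """Two paralogs with identical bodies and distinguishing flanks.

    Unique fragments span a flank into the body (n_unique per paralog);
    multimapped fragments sit fully inside the body and are reported at
    both loci.
    """
    rng = np.random.default_rng(seed)
    a_start, b_start = 1031, 5031
    genes = [
        _simple_gene(gene_ids[0], biotype, a_start, a_start + body_len - 1),
        _simple_gene(gene_ids[1], biotype, b_start, b_start + body_len - 1),
    ]
    records: list[SamRecord] = []
    i = 0
    for n, start in zip(n_unique, (a_start, b_start)):
        for _ in range(n):
            x = start - int(rng.integers(0, 31))  # flank-spanning, frag 100 nt
            records.extend(_pair(f"uniq.{i}", x, 100))
            i += 1
    frag_lo, frag_hi = READ_LEN + 10, body_len - 10
    for j in range(n_multi):
        frag = int(rng.integers(frag_lo, frag_hi + 1))
        off = int(rng.integers(0, body_len - frag + 1))
        first_a = bool(rng.integers(0, 2))
        xa, xb = a_start + off, b_start + off
        if first_a:
            records.extend(_dual_pair(f"multi.{j}", xa, xb, frag))
        else:
            records.extend(_dual_pair(f"multi.{j}", xb, xa, frag))

    u_tot = sum(n_unique)
    totals = {}
    for n, gid in zip(n_unique, gene_ids):
        extra = n_multi * (n / u_tot) if u_tot else n_multi / 2
        totals[gid] = n + extra
    truth = {
        "totals": totals,
        "family_total": u_tot + n_multi,
        "multimapped_fraction": n_multi / (u_tot + n_multi),
        "ambiguous": 0,
        "unassigned": 0,
    }
    return Scenario(name, 10000, genes, records, truth)


def build_snord103(seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    n_a = int(rng.integers(30, 58))  # split of the 87 unique pairs
    return _paralog_scenario(
        "snord103", ("SNORD103A", "SNORD103B"), "snoRNA", 70, (n_a, 87 - n_a), 2314, seed
    )


def build_mir101(seed: int) -> Scenario:
    return _paralog_scenario(
        "mir101", ("MIR101-1", "MIR101-2"), "miRNA", 80, (160, 0), 5335, seed
    )


def _retained_intron_host() -> list[GeneModel]:
    """Host with a retained-intron exon [2001, 3200] containing snoRNA
    SNO1 [2501, 2600]; a spliced isoform skips that exon."""
    e1 = GenomicInterval(CONTIG, 1001, 1400, "+")
    e2 = GenomicInterval(CONTIG, 2001, 3200, "+")
    e3 = GenomicInterval(CONTIG, 4001, 4400, "+")
    host = GeneModel(
        gene_id="HOSTG1",
        gene_name="HOSTG1",
        biotype="protein_coding",
        span=GenomicInterval(CONTIG, 1001, 4400, "+"),
        transcripts=[
            TranscriptModel("HOSTG1-t1", [e1, e2, e3]),  # retained intron
            TranscriptModel("HOSTG1-t2", [e1, e3]),  # spliced
        ],
    )
    sno = _simple_gene("SNO1", "snoRNA", 2501, 2600)
    return [host, sno]


def build_nested_basic(
    seed: int, n_nested: int = 50, n_host: int = 30, n_exceed: int = 10, n_ambig: int = 5
) -> Scenario:
    rng = np.random.default_rng(seed)
    genes = _retained_intron_host()
    records: list[SamRecord] = []
    for i in range(n_nested):  # fully inside SNO1 [2501, 2600]
        frag = int(rng.integers(80, 101))
        x = int(rng.integers(2501, 2601 - frag + 1))
        records.extend(_pair(f"nested.{i}", x, frag))
    for i in range(n_host):  # inside exon 1
        frag = int(rng.integers(150, 251))
        x = int(rng.integers(1001, 1401 - frag + 1))
        records.extend(_pair(f"host.{i}", x, frag))
    for i in range(n_exceed):  # exceed SNO1 start by 1-5 nt into the gapped exon
        x = int(rng.integers(2496, 2501))
        records.extend(_pair(f"exceed.{i}", x, 65))
    for i in range(n_ambig):  # 50 nt in gapped host exon, 50 nt in SNO1
        records.extend(_pair(f"ambig.{i}", 2451, 100))
    truth = {
        "totals": {"SNO1": float(n_nested + n_exceed), "HOSTG1": float(n_host)},
        "ambiguous": n_ambig,
        "unassigned": 0,
    }
    return Scenario("nested_basic", 10000, genes, records, truth)


def build_nested_exceeds(seed: int, n: int = 20) -> Scenario:
    sc = build_nested_basic(seed, n_nested=0, n_host=0, n_exceed=n, n_ambig=0)
    sc.name = "nested_exceeds"
    sc.truth = {"totals": {"SNO1": float(n), "HOSTG1": 0.0}, "ambiguous": 0, "unassigned": 0}
    return sc


def _intron_host_genes() -> list[GeneModel]:
    """Host whose single transcript leaves intron [1401, 5000] containing
    miRNA MIR1 [3001, 3100]."""
    e1 = GenomicInterval(CONTIG, 1001, 1400, "+")
    e2 = GenomicInterval(CONTIG, 5001, 5400, "+")
    host = GeneModel(
        gene_id="HOSTG2",
        gene_name="HOSTG2",
        biotype="protein_coding",
        span=GenomicInterval(CONTIG, 1001, 5400, "+"),
        transcripts=[TranscriptModel("HOSTG2-t1", [e1, e2])],
    )
    mir = _simple_gene("MIR1", "miRNA", 3001, 3100)
    return [host, mir]


def _background_scenario(name: str, seed: int, n_nested: int, n_bg: int, n_host: int) -> Scenario:
    rng = np.random.default_rng(seed)
    genes = _intron_host_genes()
    records: list[SamRecord] = []
    for i in range(n_nested):  # inside MIR1 [3001, 3100]
        frag = int(rng.integers(80, 101))
        x = int(rng.integers(3001, 3101 - frag + 1))
        records.extend(_pair(f"nested.{i}", x, frag))
    for i in range(n_bg):  # intronic, avoiding the miRNA
        frag = int(rng.integers(100, 151))
        if rng.integers(0, 2):
            x = int(rng.integers(1401, 3001 - frag + 1))
        else:
            x = int(rng.integers(3101, 5001 - frag + 1))
        records.extend(_pair(f"bg.{i}", x, frag))
    for i in range(n_host):
        frag = int(rng.integers(150, 251))
        x = int(rng.integers(1001, 1401 - frag + 1))
        records.extend(_pair(f"host.{i}", x, frag))
    intron_len = 5000 - 1401 + 1
    mir_len = 100
    corrected = max(0.0, n_nested - n_bg / intron_len * mir_len)
    truth = {
        "totals": {"MIR1": corrected, "HOSTG2": float(n_host)},
        "raw_nested": float(n_nested),
        "background_fragments": n_bg,
        "ambiguous": 0,
        "unassigned": n_bg,
    }
    return Scenario(name, 10000, genes, records, truth)


def build_background_hot(seed: int) -> Scenario:
    return _background_scenario("background_hot", seed, n_nested=5, n_bg=720, n_host=20)


def build_background_low(seed: int) -> Scenario:
    return _background_scenario("background_low", seed, n_nested=1000, n_bg=10, n_host=20)


def build_redundancy_pairs(seed: int) -> Scenario:
    genes = [
        # reciprocal overlap 91/101 and 91/91 > 0.9 -> later-sorting R2 removed
        _simple_gene("R1", "snoRNA", 1001, 1101),
        _simple_gene("R2", "snoRNA", 1006, 1096),
        # one-sided overlap only -> both kept
        _simple_gene("K1", "snoRNA", 2001, 2100),
        _simple_gene("K2", "snoRNA", 2050, 2300),
        # coincident but different biotypes -> both kept
        _simple_gene("D1", "snoRNA", 3001, 3100),
        _simple_gene("D2", "miRNA", 3001, 3100),
    ]
    truth = {"removed": ["R2"], "kept": ["D1", "D2", "K1", "K2", "R1"]}
    return Scenario("redundancy_pairs", 10000, genes, [], truth)


SCENARIOS: dict[str, Callable[[int], Scenario]] = {
    "nested_basic": build_nested_basic,
    "nested_exceeds": build_nested_exceeds,
    "snord103": build_snord103,
    "mir101": build_mir101,
    "background_hot": build_background_hot,
    "background_low": build_background_low,
    "redundancy_pairs": build_redundancy_pairs,
}


def write_sam(scenario: Scenario, path) -> None:
    """Serialize records as coordinate-sorted SAM."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CONTIG}\tLN:{scenario.contig_length}\n")
        for rec in sorted(
            scenario.records, key=lambda r: (r.rname, r.pos, r.qname, r.flag)
        ):
            fh.write(rec.to_line() + "\n")


def generate_scenario(
    name: str, outdir, seed: int = 0
) -> tuple[Path, Path, dict]:
    """Materialize a scenario: returns (gtf_path, sam_path, truth).

    The GTF is the *ungapped* annotation; run the annotation correction on
    it before counting.  A ``<name>.truth.json`` manifest with the expected
    pipeline output is written alongside.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    scenario = SCENARIOS[name](seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gtf_path = outdir / f"{name}.gtf"
    sam_path = outdir / f"{name}.sam"
    write_genes_gtf(scenario.genes, gtf_path)
    write_sam(scenario, sam_path)
    with open(outdir / f"{name}.truth.json", "w") as fh:
        json.dump(scenario.truth, fh, indent=1, sort_keys=True)
    return gtf_path, sam_path, scenario.truth
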