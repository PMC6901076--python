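"""Counts-per-million and transcripts-per-million conversion.

CPM divides each gene's count by the total assigned count; TPM first
normalizes by the length of the gene's main transcript (the transcript
with the greatest summed exon length) and then by the summed rates, so
both columns total one million over expressed genes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from nestcount.annotation import GeneModel


def main_transcript_length(gene: GeneModel) -> int:
    """Summed exon length of the gene's main transcript.

    The main transcript is the one with the greatest exonic length; ties
    break to the lexicographically smallest transcript_id.
    """
    lengths = [
        (t.exonic_length(), t.transcript_id) for t in gene.transcripts if t.exons
    ]
    if not lengths:
        raise ValueError(f"gene {gene.gene_id!r} has no exons")
    return min(lengths, key=lambda lt: (-lt[0], lt[1]))[0]


def compute_cpm(counts: Mapping[str, float]) -> dict[str, float]:
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("cannot compute CPM: total count is zero")
    return {g: c / total * 1e6 for g, c in counts.items()}


def compute_tpm(
    counts: Mapping[str, float], lengths: Mapping[str, int]
) -> dict[str, float]:
    rates = {}
    for g, c in counts.items():
        if c == 0:
            rates[g] = 0.0
            continue
        length = lengths.get(g, 0)
        if length <= 0:
            raise ValueError(f"gene {g!r} has non-positive length {length}")
        rates[g] = c / length
    total = sum(rates.values())
    if total <= 0:
        raise ValueError("cannot compute TPM: no expressed gene")
    return {g: r / total * 1e6 for g, r in rates.items()}


def build_count_table(
    genes: Sequence[GeneModel], counts: Mapping[str, float]
) -> pd.DataFrame:
    """Assemble the final per-gene table with count, CPM and TPM columns.

    Genes absent from ``counts`` get count 0.  Genes with no exons (e.g.
    hosts whose every exon was subtracted away) get length 0 and are
    excluded from the TPM denominator; their TPM is reported as 0.
    """
    rows = []
    for gene in genes:
        lengths = [t.exonic_length() for t in gene.transcripts if t.exons]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "gene_name": gene.gene_name,
                "biotype": gene.biotype,
                "count": float(counts.get(gene.gene_id, 0.0)),
                "length": main_transcript_length(gene) if lengths else 0,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "biotype", "count", "length"]
    ).sort_values("gene_id", kind="mergesort", ignore_index=True)
    if len(df) and df["count"].sum() > 0:
        cmap = dict(zip(df["gene_id"], df["count"]))
        cpm = compute_cpm(cmap)
        lmap = dict(zip(df["gene_id"], df["length"]))
        tpm_in = {g: (c if lmap[g] > 0 else 0.0) for g, c in cmap.items()}
        tpm = compute_tpm(tpm_in, lmap)
        df["cpm"] = df["gene_id"].map(cpm)
        df["tpm"] = df["gene_id"].map(tpm)
    else:
        df["cpm"] = 0.0
        df["tpm"] = 0.0
    return df


def write_counts(table: pd.DataFrame, path) -> None:
    """Write the counts table as TSV (gene_id, gene_name, count, cpm, tpm)."""
    out = table.loc[:, ["gene_id", "gene_name", "count", "cpm", "tpm"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
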