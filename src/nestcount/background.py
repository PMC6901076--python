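"""Background correction for nested genes.

A nested gene sitting in a highly expressed host feature (usually an
intron) accumulates counts from the host's background signal even when the
gene itself is silent.  The correction subtracts the hosting feature's
per-base density of pure-background uniquely mapped fragments, scaled by
the nested gene's span length, flooring at zero:

    corrected[n] = max(0, total[n] - bg(h)/len(h) * len(n))

Only unique fragments contribute to the background (multimapped fragments
never do, which avoids circularity with the distribution step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from nestcount.annotation import GappedAnnotation, GeneModel
from nestcount.assign import HostingKey

log = logging.getLogger(__name__)


@dataclass
class BackgroundModel:
    """Per hosting interval: pure-background fragment count and length."""

    counts: dict[HostingKey, int] = field(default_factory=dict)
    lengths: dict[HostingKey, int] = field(default_factory=dict)
    contigs: dict[HostingKey, str] = field(default_factory=dict)

    def density(self, key: HostingKey) -> float:
        return self.counts.get(key, 0) / self.lengths[key]


def build_background_model(
    annotation: GappedAnnotation, hosting_counts: Mapping[HostingKey, int]
) -> BackgroundModel:
    model = BackgroundModel()
    for host in annotation.hosting_features:
        for tx in host.transcripts:
            for iv in tx.exons:
                key = (host.gene_id, (iv.start, iv.end))
                model.lengths[key] = len(iv)
                model.contigs[key] = host.contig
                model.counts[key] = hosting_counts.get(key, 0)
    return model


def correct_nested(
    totals: Mapping[str, float],
    background: BackgroundModel,
    nested_genes: Sequence[GeneModel],
) -> dict[str, float]:
    """Apply the background subtraction to nested genes; others unchanged."""
    corrected = dict(totals)
    for gene in nested_genes:
        key = _hosting_key_for(gene, background)
        if key is None:
            continue
        raw = corrected.get(gene.gene_id, 0.0)
        sub = background.density(key) * len(gene.span)
        corrected[gene.gene_id] = max(0.0, raw - sub)
    return corrected


def _hosting_key_for(gene: GeneModel, background: BackgroundModel) -> HostingKey | None:
    hits = [
        key
        for key, contig in background.contigs.items()
        if contig == gene.contig
        and key[1][0] <= gene.span.end
        and gene.span.start <= key[1][1]
    ]
    if not hits:
        return None
    if len(hits) > 1:
        # nested gene overlapped by hosting features of several hosts: use the
        # densest one (most conservative correction), deterministically
        hits.sort(key=lambda k: (-background.density(k), k))
    return hits[0]
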