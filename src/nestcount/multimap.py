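"""Proportional distribution of multimapped fragments.

A multimapped fragment's candidate set is the set of genes its loci are
individually assigned to (ambiguous or unassigned loci contribute
nothing).  Each distinct candidate set S carrying M fragments hands gene g
the share M * u_g / sum_{h in S} u_h of its mass, where u are the unique
counts; when no candidate has unique counts the mass is split uniformly.
A single proportional pass — no iterative refinement.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

from nestcount.alignments import FragmentAlignment
from nestcount.assign import FeatureIndex, Strandedness, assign_locus


def candidate_set(
    fragment: FragmentAlignment,
    index: FeatureIndex,
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
) -> frozenset[str]:
    """Genes the fragment's loci are assigned to; empty set == unassigned."""
    genes = set()
    for locus in fragment.loci:
        res = assign_locus(locus, index, strandedness, min_overlap)
        if res.outcome == "assigned":
            genes.add(res.gene_id)
    return frozenset(genes)


def collect_candidate_sets(
    fragments: Iterable[FragmentAlignment],
    index: FeatureIndex,
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
) -> tuple[Counter, int]:
    """Aggregate fragments by candidate set.

    Returns (counter of non-empty frozensets -> fragment count,
    number of fragments whose candidate set was empty).
    """
    sets: Counter = Counter()
    dropped = 0
    for frag in fragments:
        cs = candidate_set(frag, index, strandedness, min_overlap)
        if cs:
            sets[cs] += 1
        else:
            dropped += 1
    return sets, dropped


def distribute(
    candidates: Mapping[frozenset, int],
    unique_counts: Mapping[str, float],
) -> dict[str, float]:
    """Distribute each set's fragments proportionally to unique counts,
    uniformly when the set has no uniquely mapped support."""
    out: dict[str, float] = {}
    for genes, m in candidates.items():
        total_u = sum(unique_counts.get(g, 0) for g in genes)
        if total_u > 0:
            for g in genes:
                share = m * unique_counts.get(g, 0) / total_u
                if share:
                    out[g] = out.get(g, 0.0) + share
        else:
            share = m / len(genes)
            for g in genes:
                out[g] = out.get(g, 0.0) + share
    return out


def total_counts(
    unique_counts: Mapping[str, float], distributed: Mapping[str, float]
) -> dict[str, float]:
    """total[g] = unique[g] + distributed[g]."""
    out = dict(unique_counts)
    for g, v in distributed.items():
        out[g] = out.get(g, 0.0) + v
    return out
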