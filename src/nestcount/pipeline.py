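"""End-to-end counting pipeline: ingest -> assign -> distribute -> correct.

Glue used by both the command-line interface and programmatic callers:
parse alignments, split unique/multimapped, count unique fragments against
the gapped annotation, distribute multimapped fragments proportionally,
background-correct nested genes and build the CPM/TPM table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from nestcount.alignments import FragmentAlignment, classify_fragments, parse_alignments
from nestcount.annotation import (
    NESTED_BIOTYPES,
    GappedAnnotation,
    GeneModel,
    parse_gtf,
)
from nestcount.assign import FeatureIndex, Strandedness, count_unique
from nestcount.background import build_background_model, correct_nested
from nestcount.multimap import collect_candidate_sets, distribute, total_counts
from nestcount.normalize import build_count_table

log = logging.getLogger(__name__)


def assemble_annotation(
    full: Sequence[GeneModel], hosting: Sequence[GeneModel] = ()
) -> GappedAnnotation:
    """Rebuild a GappedAnnotation from its two serialized GTF halves."""
    return GappedAnnotation(
        full=list(full), hosting_features=list(hosting), removed_regions={}
    )


@dataclass
class CountSummary:
    fragments: int = 0
    unique: int = 0
    multimapped: int = 0
    assigned_unique: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    multimapped_assigned: float = 0.0
    multimapped_dropped: int = 0
    background_fragments: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def correct_count(
    annotation: GappedAnnotation,
    fragments: Sequence[FragmentAlignment],
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
    bg_correction: bool = True,
    nested_biotypes: frozenset[str] = NESTED_BIOTYPES,
) -> tuple[pd.DataFrame, CountSummary]:
    """Run the full counting pipeline over parsed fragments.

    Returns the per-gene table (count/cpm/tpm) and a run summary with the
    assigned / ambiguous / unassigned / multimapped tallies.
    """
    index = FeatureIndex.from_annotation(annotation)
    unique, multi = classify_fragments(fragments)

    uc = count_unique(unique, index, strandedness, min_overlap)
    sets, dropped = collect_candidate_sets(multi, index, strandedness, min_overlap)
    dist = distribute(sets, uc.unique_counts)
    totals = total_counts(uc.unique_counts, dist)

    if bg_correction:
        if annotation.hosting_features:
            model = build_background_model(annotation, uc.hosting_counts)
            nested = [g for g in annotation.full if g.biotype in nested_biotypes]
            totals = correct_nested(totals, model, nested)
        else:
            log.warning("no hosting-feature annotation: background correction skipped")

    table = build_count_table(annotation.full, totals)
    summary = CountSummary(
        fragments=len(unique) + len(multi),
        unique=len(unique),
        multimapped=len(multi),
        assigned_unique=int(sum(uc.unique_counts.values())),
        ambiguous=uc.ambiguous_count,
        unassigned=uc.unassigned_count,
        multimapped_assigned=float(sum(dist.values())),
        multimapped_dropped=dropped,
        background_fragments=int(sum(uc.hosting_counts.values())),
    )
    return table, summary


def correct_count_files(
    full_gtf,
    sam_path,
    hosting_gtf=None,
    strandedness: Strandedness = "unstranded",
    min_overlap: int = 1,
    bg_correction: bool = True,
) -> tuple[pd.DataFrame, CountSummary]:
    """File-level wrapper: read the gapped GTF (plus optional hosting GTF)
    and a SAM/BAM, and run :func:`correct_count`."""
    full = parse_gtf(full_gtf)
    hosting = parse_gtf(hosting_gtf) if hosting_gtf else []
    annotation = assemble_annotation(full, hosting)
    fragments = list(parse_alignments(sam_path))
    return correct_count(
        annotation,
        fragments,
        strandedness=strandedness,
        min_overlap=min_overlap,
        bg_correction=bg_correction,
    )
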