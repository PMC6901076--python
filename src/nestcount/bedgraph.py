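"""Fragment-level coverage tracks and bedgraph output.

Depth at a base is the number of *fragments* with an aligned block covering
it: both mates' blocks are unioned per fragment, so mate overlap counts
once, and N gaps and inter-mate gaps contribute zero.  Output follows the
BED convention (0-based start, exclusive end); all internal coordinates
stay 1-based inclusive until serialization.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Literal

from nestcount.alignments import FragmentAlignment

#: contig -> sorted list of (start0, end0_exclusive, depth), maximal runs
CoverageTrack = dict[str, list[tuple[int, int, int]]]

Multimode = Literal["primary_only", "all_loci"]


def fragment_coverage(
    fragments: Iterable[FragmentAlignment],
    multimode: Multimode = "primary_only",
    strand: str | None = None,
) -> CoverageTrack:
    """Compute per-contig fragment depth.

    ``multimode`` selects whether multimapped fragments contribute at their
    primary locus only (default, matching typical genome-coverage runs on a
    BAM with secondaries ignored) or at every reported locus.  ``strand``
    restricts to loci on one strand ('+'/'-') for strand-split tracks.
    """
    # sweep-line over block boundaries: +1 at start, -1 past end
    deltas: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for frag in fragments:
        loci = frag.loci if multimode == "all_loci" else [frag.primary_locus()]
        for locus in loci:
            if strand is not None and locus.strand != strand:
                continue
            for block in locus.blocks:
                deltas[locus.contig][block.start - 1] += 1  # to 0-based
                deltas[locus.contig][block.end] -= 1
    track: CoverageTrack = {}
    for contig, dd in deltas.items():
        runs: list[tuple[int, int, int]] = []
        depth = 0
        prev = None
        for pos in sorted(dd):
            if prev is not None and depth != 0 and pos > prev:
                if runs and runs[-1][1] == prev and runs[-1][2] == depth:
                    runs[-1] = (runs[-1][0], pos, depth)
                else:
                    runs.append((prev, pos, depth))
            depth += dd[pos]
            prev = pos
        track[contig] = runs
    return track


def track_area(track: CoverageTrack) -> int:
    """Sum of (end - start) * depth over all intervals."""
    return sum((e - s) * d for runs in track.values() for s, e, d in runs)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a 4-column bedgraph; zero-depth intervals are omitted."""
    with open(path, "w") as fh:
        for contig in sorted(track):
            for start, end, depth in track[contig]:
                if depth:
                    fh.write(f"{contig}\t{start}\t{end}\t{depth}\n")


def read_bedgraph(path) -> CoverageTrack:
    """Parse a bedgraph back into a coverage track (round-trip aid)."""
    track: CoverageTrack = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            contig, s, e, d = line.split("\t")
            track[contig].append((int(s), int(e), int(float(d))))
    return dict(track)
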