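# Methods

## Problem and model

Gene-level RNA-seq quantification assigns each aligned fragment to the
annotated feature it overlaps. Two genomic configurations break this:

- **Nested genes.** A small non-coding RNA (snoRNA, scaRNA, snRNA, tRNA,
  miRNA) encoded inside an exon — typically a retained intron — of a host
  gene overlaps the host annotation base for base. A fragment inside the
  small RNA ties between the two features and is dropped as ambiguous; a
  fragment exceeding the (often imprecise) small-RNA annotation by even one
  base tips to the host.
- **Multi-copy genes.** Paralogs with identical mature sequences produce
  fragments that align to every copy; most counters discard them, leaving
  whole gene families invisible.

`nestcount` addresses the first by editing the annotation and the second by
redistributing fragments, with a background correction protecting nested
genes from inheriting their host's signal.

### Annotation gapping

Nested-biotype gene spans are subtracted from the exons of all other genes:
full containment splits an exon, edge overlap truncates it, full coverage
deletes it (the gene then remains in the output with an empty exon set and
a flag). Nested genes themselves are never modified, so after gapping any
base of a nested gene span is exonic for the nested gene alone — a fragment
there can no longer tie with the host. The subtraction ignores strand by
default, like interval-intersection tooling; `--stranded-subtraction`
restricts it to same-strand overlaps.

Before gapping, a redundancy filter removes genes that overlap a
same-biotype gene reciprocally over more than 90% of *both* spans
(strictly: 0.90 exactly keeps both). Overlap is measured on gene spans, not
exon unions — the affected biotypes are essentially single-exon. Within a
violating pair the lexicographically later gene_id is removed, greedily and
transitively in sorted order, so the result is deterministic and no kept
pair violates the rule.

The companion *hosting-feature* annotation records, per host, the feature
containing each nested gene, at intron granularity: each inter-exon gap of
the host's main transcript holding ≥1 nested gene becomes one record. A
nested gene inside a retained-intron **exon** of the main transcript falls
back to that exon — without the fallback the most important case (the
retained-intron snoRNA) would have no hosting feature and could never be
background-corrected.

### Fragment reconstruction and assignment

SAM/BAM records are regrouped by read name; mates are matched into loci by
the reciprocal POS/PNEXT fields, and a mate whose partner is unmapped or on
a different contig is kept as a single-end locus rather than discarded.
Aligned blocks are the M/=/X runs of the CIGAR (N and D gaps excluded);
both mates' blocks are unioned per locus so overlapping mates count once.
Multiplicity is the number of loci observed for the read name; the NH tag
is only a consistency check (mismatch logs a warning), which keeps the
ingest robust across aligners with different NH conventions.

A locus votes for each gene by the number of distinct bases overlapping the
gene's exonic intervals (union over transcripts — shared exons are not
double-counted). The unique strict maximum wins; an exact tie is ambiguous;
no votes is unassigned. The tie rule means a fragment overlapping a nested
gene over 60 bases and protruding 5 bases into the flanking gapped host
exon is assigned to the nested gene. Intronic (non-exonic) overlap never
votes; gene-body counting is deliberately not offered.

### Multimap distribution

Fragments are aggregated by candidate set — the set of genes their loci are
individually assigned to (ambiguous/unassigned loci contribute nothing; a
fragment whose loci all land in one gene counts 1.0 there). A set `S` with
`M` fragments gives gene `g` the share `M·u_g / Σ_{h∈S} u_h` of its mass,
where `u` are the **pre-correction** unique counts; if no member of `S` has
unique support the mass is split uniformly. This is a single proportional
pass, not an EM: per-set aggregation is mathematically identical to
per-fragment distribution and far cheaper. Consequences worth noting: mass
is conserved exactly, and a gene with zero unique counts sharing a set with
a supported gene receives exactly zero.

### Background correction

A nested gene inside a transcribed host feature accumulates host signal.
For each nested gene `n` inside hosting feature `h`:

    corrected(n) = max(0, total(n) − bg(h)/len(h) · len(n))

where `bg(h)` counts *pure background* fragments: uniquely mapped,
assigned to no gene, with every block inside `h`. Multimapped fragments
never contribute to the background (that would be circular with the
distribution step). If a nested gene overlaps hosting features of several
hosts, the densest one is used — the most conservative correction. The
correction order is distribute-then-correct; the proportions of the
distribution therefore use raw unique counts. `--no-bg-correction`
disables the step, as does omitting the `--introns` GTF (with a warning).

The precise background estimator of the original method is not publicly
specified; the density-times-length form above is this package's own
reconstruction of "subtracting the length-normalized average count of the
hosting feature", and is flagged as such.

### Normalization

CPM divides by the total assigned count (ambiguous and unassigned
fragments are excluded from the denominator). TPM divides each count by
the length of the gene's *main* transcript — greatest summed exon length,
ties to the smallest transcript_id, measured on the gapped annotation —
then renormalizes the rates to 1e6. Both columns sum to one million over
expressed genes. Counts stay fractional; no rounding is applied.

### Coverage

Bedgraph depth at a base is the number of fragments with an aligned block
covering it. Multimapped fragments contribute at their primary locus only
by default (`--multimode all_loci` counts every locus). Output is 0-based
half-open per the BED convention; everything internal is 1-based
inclusive GTF coordinates, converted only at serialization. `--split-strands`
additionally writes per-strand tracks (strand taken from mate 1), which
sum to the unstranded track at every base.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--biotypes` | miRNA,scaRNA,snRNA,snoRNA,tRNA | biotypes carved out of host exons |
| `--redundancy-threshold` | 0.9 | reciprocal span-overlap fraction (strict >) |
| `--stranded-subtraction` | off | only gap same-strand overlaps |
| `--strandedness` | unstranded | vote filter: forward/reverse vs mate-1 strand |
| `--min-overlap` | 1 base | smallest exonic overlap that may vote |
| `--no-bg-correction` | off | skip the background subtraction |
| `--multimode` | primary_only | bedgraph handling of secondary loci |

## Synthetic scenarios

The generator emits GTF+SAM pairs on one synthetic contig (`chrT`) with
ground-truth manifests; reads are 2×50-nt proper pairs with seeded
placement, byte-identical for identical scenario+seed. Fixture conditions:
the identical-paralog snoRNA scenario uses 87 unique flank-spanning pairs
(split between the loci by a seeded draw — the family total and the
distribution arithmetic are invariant to the split) and 2,314 dual-reported
body-only pairs; the miRNA paralog scenario uses 160 unique pairs on one
member and 5,335 dual-reported pairs; the background scenarios place a
100-nt miRNA in a 3,600-nt intron with 720 (hot) or 10 (low) intronic
background fragments. Fragment lengths (100 nt flank-spanning, 60–70 nt
body-only, 100–150 nt background) are fixed, realistic short-fragment
sizes.

What the scenarios do **not** emulate: sequencing errors and quality
modeling, aligner soft-clipping and indel CIGARs, chimeric/discordant
pairs, more than two alignment loci per fragment, and genome-scale
annotation density. Passing tests therefore demonstrate the correctness of
the assignment, distribution and correction arithmetic under clean
alignments — not robustness to aligner artifacts or the genome-wide
salvage rates achievable on real libraries.

## Numerical and design notes

- Distribution outputs are floats; mass conservation is exact to 1e-9
  relative tolerance in tests.
- The whole pipeline is deterministic; the only randomness is the seeded
  fixture generator.
- Coordinate-sorted input is regrouped by name in memory; extremely large
  BAMs would need an external name-sort first (not a concern at fixture
  scale).
- A read pair whose mates align to different contigs is treated as two
  single-end loci and logged.
- Degenerate inputs: empty GTF/SAM give empty (header-only) outputs; an
  all-zero count table raises on CPM rather than emitting NaNs; a gene
  whose exons were all subtracted away has length 0 and is excluded from
  the TPM denominator.

## Known limitations

- No transcript-level (isoform) quantification and no EM reweighting of
  multimappers; the proportional pass is intentionally single-shot.
- The background model is uniform along the hosting feature; positional
  (5'→3') bias is not modeled.
- GFF3 is not supported (Ensembl-dialect GTF only); CRAM is not supported.
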