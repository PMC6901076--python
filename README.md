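# nestcount

Read-assignment correction for **nested** and **multimapped** genes in
RNA-seq.

Standard gene-level counting pipelines systematically lose two classes of
reads. Fragments falling on a small non-coding RNA (snoRNA, scaRNA, snRNA,
tRNA, miRNA) that is nested inside an exon or retained intron of a longer
host gene overlap both annotations equally, get labelled *ambiguous* and
are discarded — or are handed to the host. Fragments from multi-copy genes
(paralogous snoRNAs, tRNAs, miRNAs with identical mature sequences) align
to several loci and are discarded as *multimapped*. `nestcount` recovers
both:

1. **Gapped annotation** (`correct-annotation`). Every exon position of a
   non-nested gene that overlaps a nested-biotype gene span is deleted:
   an exon containing a nested gene is split in two, an exon overlapped at
   its edge is truncated. Genes that reciprocally overlap a same-biotype
   gene over >90% of both spans are first removed (keeping both would make
   all their reads ambiguous). Two GTFs are written: the full gapped
   annotation and a companion *introns* GTF listing, per host gene, the
   intron (or retained-intron exon) that contains each nested gene.
2. **Counting** (`correct-count`). Aligned fragments (read pairs or single
   reads) are assigned to the gene with the largest exonic base overlap;
   exact ties are ambiguous. A fragment with `k > 1` alignment loci is
   *distributed* over its candidate genes `S` proportionally to their
   unique counts `u`:

       count(g) += M · u_g / Σ_{h∈S} u_h        (uniform if Σ u_h = 0)

   for each distinct candidate set `S` carrying `M` fragments. Totals are
   unique + distributed counts. Nested-gene totals are then
   background-corrected by subtracting the hosting feature's per-base
   density of pure-background fragments times the nested gene's length,
   floored at zero. The output table carries raw counts, CPM and TPM (TPM
   uses the length of each gene's main = longest-exonic transcript).
3. **Coverage** (`correct-bedgraph`). Fragment-level bedgraphs: both
   mates' aligned blocks are unioned per fragment, so mate overlap counts
   once and inter-mate gaps and intron (`N`) gaps contribute zero depth.

## Worked example

A synthetic scenario with two snoRNA paralogs whose 70-nt bodies are
identical but whose genomic flanks differ: 87 uniquely mapped
flank-spanning read pairs, plus 2,314 pairs aligning equally well to both
bodies (reported as primary + secondary alignments):

```sh
nestcount make-fixtures snord103 -o demo --seed 1
cd demo
nestcount correct-annotation snord103.gtf -o full.gtf --introns introns.gtf
nestcount correct-count full.gtf snord103.sam -o counts.tsv --introns introns.gtf
cat counts.tsv
```

```
gene_id     gene_name   count        cpm            tpm
SNORD103A   SNORD103A   1186.701149  494252.873563  494252.873563
SNORD103B   SNORD103B   1214.298851  505747.126437  505747.126437
```

The 2,314 multimapped pairs were split between the paralogs in the ratio
of their unique counts (43:44 under this seed) instead of being discarded:
the family total rises from 87 to 2,401 read pairs, of which 96% is
rescued multimapped mass. The run summary
(`counts.tsv.summary.json`) reports
`fragments=2401 unique=87 multimapped=2314 ambiguous=0 unassigned=0`.

The scenario catalogue (`nestcount make-fixtures --help`) also covers a
host gene with a snoRNA nested in a retained-intron exon
(`nested_basic`, `nested_exceeds`), a miRNA-style paralog pair where only
one member has unique reads (`mir101`), high- and low-background hosting
introns (`background_hot`, `background_low`) and redundant same-biotype
gene pairs (`redundancy_pairs`). Each scenario ships a
`<name>.truth.json` manifest with the expected pipeline output.

## Layout

- `src/nestcount/annotation.py` — GTF parsing, redundancy filter, exon gapping
- `src/nestcount/alignments.py` — SAM/BAM ingest, mate pairing, multiplicity
- `src/nestcount/assign.py` — interval index, largest-overlap assignment
- `src/nestcount/multimap.py` — proportional multimap distribution
- `src/nestcount/background.py` — hosting-feature background correction
- `src/nestcount/normalize.py` — CPM/TPM and the counts table
- `src/nestcount/bedgraph.py` — fragment coverage tracks
- `src/nestcount/fixtures.py` — synthetic GTF+SAM scenario generator
- `src/nestcount/cli.py` — the `nestcount` command

See `docs/methods.md` for the model, parameter defaults and limitations.
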