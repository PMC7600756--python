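# hybridalleles

Parental-allele inheritance, paralog and gene copy-number prediction for
hybrid genomes.

## The problem

Allopolyploid hybrids — lager-brewing *Saccharomyces pastorianus* (a
*S. cerevisiae* × *S. eubayanus* hybrid) being the canonical industrial
example — carry two or more parental sub-genomes, often with unbalanced
(aneuploid) copy numbers and with paralogs inherited from each parent or
created after hybridization. Generic annotation tools collapse this
redundancy: they transfer the same best homolog to every copy, or search
orthology across a wide taxon range instead of against the actual parents.
For functional annotation, cis/trans regulation studies and strain
engineering, what is needed per hybrid ORF is *which parent's allele it is*,
and per parental gene, *how many copies the hybrid kept*.

`hybridalleles` answers this when the parental genomes are known. Given ORF
nucleotide FASTA files for a hybrid and its 2–4 parents, it:

1. plans and runs the 3P+1 all-vs-all nucleotide alignment jobs (hybrid ↔
   each parent in both directions, every genome against itself), with an
   e-value save threshold of 0.05;
2. reduces hits to per-query **best hits** and detects **best bidirectional
   hits** (BBH): 1:1 orthologs between genomes, paralogs within a genome
   (after removing identity self-hits). A best hit qualifies only above a
   strict identity floor (> 80% by default);
3. assigns each hybrid ORF the parental allele whose ortholog shares the
   **strictly highest percent identity**; equal identities (e.g. perfectly
   conserved tRNAs) are declared ambiguous. Extra allele copies in the
   aneuploid hybrid — which strict 1:1 BBH cannot anchor — inherit the
   assignment of their nearest hybrid self-paralog twin;
4. classifies every hybrid ORF into one of the mutually exclusive outcome
   categories (assigned-per-parent, ambiguous equal identity, sub-threshold
   identity, no prediction — the categories always sum to the ORF total),
   counts **per-parental-gene copy numbers**, merges homology evidence into
   **homolog groups**, and reports which ancestral functions retain alleles
   from one or both parents;
5. tests predicted genome content against ploidy expectations with a
   chi-square goodness-of-fit, `X² = Σ (O−E)²/E` with `df = cells − 1`.

Alignment uses either NCBI `blastn` (if installed) or a built-in
k-mer-seeded aligner (edlib-powered, blastn-style scoring, Karlin–Altschul
e-values) so the pipeline has no hard external dependency.

A fully ground-truthed simulator (`hybridalleles.simulate`) generates
ancestor → diverged parents → aneuploid hybrid scenarios so that allele
assignment, copy numbers and grouping can be scored against known truth.

## Worked example

Simulate a small hybrid (60 ancestor genes, parents at 10% divergence,
hybrid ploidy parentA:1 / parentB:2, 10% copy loss) and run the pipeline:

```bash
hybridalleles simulate --outdir data --n-genes 60 --seed 7
# wrote 161 hybrid ORFs and 120 parent ORFs to data
hybridalleles run --hybrid data/hybrid.fasta \
    --parent parentA=data/parentA.fasta --parent parentB=data/parentB.fasta \
    --outdir out
cat out/summary.tsv
```

```
category	hybrid
total_genes	161
assigned_parentA	50
assigned_parentB	111
ambiguous_equal_identity	0
subthreshold_identity	0
no_prediction	0
distinct_paralogs	118
paralog_groups	59
paralog_pairs	59
```

All 161 hybrid ORFs received a parental allele: 50 from parent A and 111
from parent B — close to the 1:2 ratio the simulated ploidy implies, with
loss accounting for the deviation. The category counts sum to the total by
construction. 118 hybrid ORFs sit in 59 self-paralog groups: these are the
second parent-B copies, each paired with its twin and assigned the same
parental gene (visible as `copy_number 2` rows in `out/copy_number.tsv`).

Testing the predicted content against the expected 1:2 split:

```bash
hybridalleles gof --summary summary_strain.tsv --fractions fractions.tsv \
    --alpha 0.01 --out gof.tsv
# chi2=0.38 df=1 p=0.54 critical=6.63
```

The statistic 0.38 is far below the 1% critical value 6.63 (p = 0.54): the
predicted allele content is consistent with the simulated ploidy.

Other products in `out/`: per-parent ortholog tables, per-genome paralog
tables, `assignments.tsv` (per-ORF category and allele), `copy_number.tsv`,
`homolog_groups.tsv`, `venn_counts.tsv` (alleles retained from one or both
parents), a re-labelled `hybrid_annotated.fasta`, `id_mapping.tsv` (usable
with `hybridalleles rewrite-gff3` to annotate a structural annotation), and
`manifest.json` with a checksum of every product — reruns are
byte-identical.

## Documentation

See `docs/methods.md` for the model, parameter meanings, numerical
conventions, simulator scope and known limitations.
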