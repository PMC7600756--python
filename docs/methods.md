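# Methods

## Model and assumptions

The method treats parental-allele assignment in a hybrid genome as an
orthology problem restricted to the known parents. Its core assumptions:

* Divergence between a hybrid ORF and the parental gene it was inherited
  from is small relative to the divergence between the parental genomes
  themselves. Percent identity of a nucleotide alignment is then a
  sufficient statistic to pick the source parent.
* A 1:1 ortholog relationship is operationalized as a **best bidirectional
  hit** (BBH): x in genome X and y in genome Y are orthologs when y is x's
  best alignment hit in Y *and* x is y's best hit in X. Within one genome,
  the same criterion after removing identity self-hits yields paralog
  pairs.
* Homology is transitive for grouping purposes: pairs sharing a member are
  merged, so homolog groups are connected components of the pair graph.

## Pipeline stages and parameters

| parameter | default | meaning |
|---|---|---|
| `evalue_keep` | 0.05 | maximum e-value for saving a hit (stringent; BLAST's own default is 10) |
| `identity_min` | 80 (%) | best hits must share *strictly more* than this identity to qualify as ortholog candidates; a pair at exactly 80.0% is rejected |
| `match/mismatch` | +2 / −3 | blastn-style nucleotide scoring |
| `gap_open/gap_extend` | 5 / 2 | affine gap costs |
| `k` | 11 | seed length of the built-in aligner |
| `alpha` | 0.01 | significance level of the genome-content goodness-of-fit |

For P parents the alignment plan is 3P+1 jobs: hybrid→parent and
parent→hybrid for each parent, plus every genome against itself (7 jobs
for the standard two-parent run). Only the best-scoring HSP per
(query, subject) pair is kept — all downstream logic is pairwise.

**Best hits.** Per query, minimum e-value; ties broken by maximum percent
identity, then maximum alignment length, then lexicographically smallest
subject id. The tie chain is fixed so outputs are reproducible.

**Identity filter before reciprocity.** The >`identity_min` filter is
applied to best hits *before* BBH testing. A high-identity second-best hit
is therefore never promoted: if the best hit fails the filter the query
simply has no qualifying hit in that genome. Queries whose best hit existed
but failed only this filter are tracked separately — they become the
"sub-threshold identity" outcome rather than "no prediction".

**Assignment.** Each hybrid ORF with qualifying orthologs is assigned to
the parent with the strictly highest ortholog identity. Identities are
compared at two decimals (the precision alignment backends report); equal
maxima are declared `AMBIGUOUS_EQUAL_IDENTITY` — the motivating case is
perfectly conserved genes (tRNA-like) identical in both parents. A strict
sequence-equality notion of ambiguity would miss backend-level rounding and
is intentionally not the default. The four categories partition the ORF
set; the per-category counts must sum to the total, and
`classify_summary` enforces this.

**Copy propagation through paralog pairs.** Strict 1:1 BBH can anchor only
one hybrid copy per parental gene: with two near-identical copies, the
parent gene reciprocates with only one of them. The pipeline therefore
propagates assignments through the hybrid's own self-BBH paralog graph: an
unassigned (no-prediction or sub-threshold) ORF inherits the parental gene
of the nearest assigned ORF in its component (breadth-first distance, ties
broken by id). Ambiguous ORFs are never propagated into — their origin is
undecidable, not missing. Propagated assignments are marked
`via=paralog` in `assignments.tsv` and can be disabled
(`--no-propagate`). This step is what makes per-parental-gene copy numbers
greater than one observable in aneuploids.

**Copy numbers.** One record per parental gene with ≥1 assignment; copy
numbers sum to the number of assigned ORFs.

**Homolog groups.** Three configurable edge layers connect hybrid ORFs:
(i) hybrid self-BBH paralog pairs; (ii) pairs whose assigned parental genes
are a paralog pair within one parent; (iii) pairs whose assigned parental
genes are a 1:1 cross-parent ortholog pair. Connected components of the
layered graph are reported with per-member parental annotations. The
"distinct paralogs" tally in `summary.tsv` counts hybrid ORFs in ≥1
layer-(i) group; the number of groups and of pairs are reported alongside,
since "how many paralogs" admits all three readings.

**Genome-content test.** `X² = Σ (O−E)²/E` over strain × parent cells,
`E = strain total × expected fraction`. Degrees of freedom follow the
one-sample goodness-of-fit convention, **cells − 1**: four strains × two
parents gives df = 7, for which the 1% critical value is 18.48. (The
contingency-table rule (rows−1)(cols−1) would give df = 3 and a different
critical value; it is not what this test is.) Expected fractions are
always user-specifiable per strain; 1:1 (balanced tetraploid-like) and 2:1
(triploid-like) presets are provided. The survival function is evaluated
via scipy's regularized incomplete gamma, which stays accurate for extreme
statistics (p ≈ 1e-182 does not underflow).

## Built-in aligner

The external backend shells out to NCBI `makeblastdb`/`blastn`
(tabular output with an extra `gaps` column). The built-in backend makes
the pipeline self-contained:

* candidate pairs are found by shared k-mers (k = 11, both strands); a
  candidate must share at least `max(2, 0.01·min(length))` seeds — chance
  k-mer sharing between unrelated kilobase-scale sequences grows
  quadratically with length, and true homologs at ≥70% identity share an
  order of magnitude more seeds than chance pairs do;
* each candidate pair is globally aligned with edlib (unit-cost,
  bit-vector, C); the resulting alignment path is re-scored with
  blastn-style weights, identity = identical columns / alignment columns,
  gap percentage = gap columns / alignment columns. `N` never counts as an
  identity;
* e-values come from the Karlin–Altschul formula `E = K·m·n·exp(−λS)` with
  ungapped constants (λ = 0.625, K = 0.41), `m` the query length and `n`
  the total subject length. These e-values are approximate by
  construction; downstream stages consume only hit *ordering* and the save
  threshold, and on high-identity instances the built-in and blastn
  backends rank the same best subject per query (asserted in the tests).

Limitations of the built-in backend: global (not local) alignment per
candidate pair, so a short gene embedded in a much longer one scores
poorly; no multi-HSP chaining; e-values not comparable to BLAST's beyond
ordering.

## Simulator

`simulate_dataset` emulates the standard allopolyploid history: an
ancestor gene set (i.i.d. bases at configurable GC, lengths normal with a
150 nt floor); parents diverged by independent per-site substitution
(uniform over the three alternative bases, Jukes–Cantor-like) with
optional full-length small-scale duplications; and a hybrid that carries a
configurable number of copies per parent (ploidy), loses copies
independently, diverges slightly post-hybridization and may duplicate
again. Every surviving hybrid ORF records its source parent, source gene,
origin class and whether its origin is even decidable (it is not when
another parent carries an identical sequence). All randomness flows
through per-stage `numpy` generator streams keyed on the seed, so datasets
are fully reproducible.

Default conditions (500 ancestor genes, mean length 1000 nt at 40% GC,
10% parent divergence, ploidy parentA:1/parentB:2, 10% loss, 0.5%
post-hybridization divergence, seed 42) describe a yeast-like recovery
experiment in which parental origin is strongly identifiable; duplication
rates default to zero and are switched on explicitly where the duplication
machinery itself is under test. At these conditions the pipeline reaches
allele-origin precision = recall ≈ 0.996 and exact copy numbers for ≈ 99%
of parental genes.

What the simulator does *not* model — and what passing recovery tests
therefore cannot show: indels (alignment identity is exercised separately
through aligner fixtures), synteny and chromosome structure,
translocations, recombination between sub-genomes, the divergence spectrum
of whole-genome-duplication ohnolog pairs, and GC/length heterogeneity of
real genomes. Results on real hybrids also depend on the structural
annotation supplying comparable ORF sets for hybrid and parents.

## Numerical choices

* All orderings (job plan, hit tables, pairs, groups, output rows) are
  deterministic; identical inputs and configuration give byte-identical
  outputs (checksummed in `manifest.json`).
* Identity ties in assignment are detected after rounding to 2 decimals;
  best-hit ties use the fixed chain e-value → identity → alignment length
  → subject id.
* Degenerate inputs: empty query sets are errors; a simulation losing
  every copy warns and returns an empty hybrid; goodness-of-fit requires
  strictly positive expected counts.
* Test and acceptance problem sizes: unit tests use 25–60-gene scenarios;
  the end-to-end recovery experiment uses the 500-gene default (≈1350
  hybrid ORFs), which exercises every stage at a scale where binomial
  noise is small.

## Known limitations

* **Lost-allele misassignment.** If the hybrid lost its parent-A copy of a
  gene while keeping two parent-B copies, the "spare" B copy can form a
  reciprocal best hit with the parent-A gene (at roughly the inter-parent
  identity, just above the 80% floor) and be assigned to parent A. This is
  inherent to BBH-based assignment, rare at realistic divergences
  (≈0.4% of ORFs at the default conditions), and visible in output as
  assignments whose identity is far below the within-parent level.
* Ambiguity is resolved per ORF, not per homolog family; two tied parents
  with unequal gene content near an ORF are not disambiguated by synteny
  (not modeled at all).
* The goodness-of-fit compares marginal per-parent totals only; it does not
  localize which chromosomes or regions drive a deviation.
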