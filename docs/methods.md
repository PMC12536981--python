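# Methods

## Scope and model

`pedpaint` assigns parent-of-origin labels in settings where both parental
genotypes are known — controlled crosses, or hybrid analyses where two
representative reference VCFs stand in for parents. It targets haploid or
fully homozygous diploid systems: a homozygous offspring site matches one
parental allele unambiguously, so assignment is exact string matching with
no statistical inference, no phasing, and no confidence scores. The cost
is resolution: heterozygous sites are excluded outright, which in truly
diploid data removes many informative positions.

Every offspring SNP present in at least one parent lands in exactly one of
three categories — Parent1, Parent2, Unknown. Two conventions are worth
making explicit because they are genuinely open choices:

* A site where the offspring allele matches **both** parents is retained
  as Unknown rather than dropped, so uninformative-but-mappable sequence
  still counts toward the denominator of the contribution percentages.
* A site present in **one** parent only is labeled with that parent when
  the allele matches and Unknown when it does not; Unknown is the
  conservative reading for a mismatch the panel cannot explain.

## Genotype handling

`/` and `|` separators are treated identically (phase is irrelevant once
heterozygotes are gone). Haploid calls (`0`, `1`, …) and homozygous
diploid calls (`0/0`, `2|2`, …) resolve; heterozygous and missing calls
do not. Multi-allelic records are allowed — the genotype index selects
the allele. Indels and multi-nucleotide alleles are skipped and counted;
the pipeline is SNP-only. VCFs without a GT field are read as parental
consensus panels: every record is homozygous for its first ALT. Duplicate
(chrom, pos) records within one individual are a hard error rather than
last-wins, preserving determinism. Chromosome names are matched by exact
string equality between VCFs and GTF; no "chr" prefix normalization is
attempted. All coordinates are 1-based closed, end to end.

## Clustering

"Cluster length" always means nucleotide span (`end − start + 1`), never
SNP count — the thresholds are in nucleotides.

**Pass 1** groups maximal runs of same-label SNPs per chromosome and keeps
a run iff its span ≥ `min_cluster_len` (default **10 nt** — the scale of a
sporadic miscall, not of a real tract). The comparison is inclusive (≥);
runs break at chromosome and label changes, and the trailing run of each
chromosome passes through the same filter. Discarded runs are counted and
are not revisited later.

**Pass 2** rewrites each chromosome's cluster chain to a fixpoint,
applying the leftmost applicable rule each time:

1. *merge*: a cluster with span strictly `< max_gap_cluster_len` (default
   **1000 nt**) flanked by two clusters of one other label is deleted and
   its flanks joined from left start to right end. The deleted cluster's
   SNPs are dropped; the flanks' SNP counts are summed and their label is
   never changed. The strict `<` composes cleanly with pass 1's `≥`.
2. *coalesce*: two adjacent same-label clusters (left behind where pass 1
   discarded a short run between them) are joined into one.

Unknown runs are clustered and merged under exactly the same rules as
parental runs — a short Unknown cluster between two Parent1 blocks is
removable. The rewrite system is order-sensitive in corner cases (e.g.
`P1·p2·p1·P2` with both middles small), so the leftmost-first order *is*
the definition; the implementation resumes one position left of each
rewrite, which provably visits rewrites in leftmost order, and the test
suite checks it against a naive restart-from-scratch fixpoint oracle.
Merging never crosses an intervening cluster at or above the threshold,
whatever its label. After convergence, consecutive clusters on a
chromosome never share a label, and the pass is idempotent.

With both thresholds at 1 the two passes reduce to the pure run-length
encoding of the label sequence — a useful limit case for testing.

## Quantification

Genome-level percentages are per individual × chromosome:
`100 × (summed span of that label's clusters) / (summed span of all
clusters on the chromosome)`. The denominator is informative sequence
only — repetitive or invariant regions that produced no SNP clusters do
not dilute the percentages, and Unknown clusters do count. Pre-rounding,
the three percentages sum to exactly 100; TSVs round to one decimal.

Gene-level percentages intersect clusters with gene intervals. A gene
takes the label with the largest total overlapping span, summed across
that label's clusters, including partial and nested overlaps; no overlap
or a tie between the top two labels gives Unknown (ties have no
principled winner, and Unknown is deterministic). GTF `gene` rows are
used when present; otherwise the per-`gene_id` envelope of `exon` rows,
which tolerates minimal or pre-filtered annotations. Strand is ignored —
inheritance is strand-agnostic. Gene-level results are only as good as
the annotation; fragmented or misannotated genes propagate directly.

## Painting

Figures are pure consumers of the tidy TSVs: one horizontal track per
individual × chromosome with segments colored by label (Parent1 blue,
Parent2 red, Unknown gray, fixed across all panels of a figure), plus
stacked barplots for genome- and gene-percent tables. X-axes run from 1
to the maximum cluster end observed per chromosome unless explicit
chromosome lengths are supplied. Rendering is deterministic (Agg backend,
fixed DPI, no embedded timestamps); layouts stay readable to roughly 200
individuals × 40 chromosomes, beyond which the tool still renders but
warns. Colors, figure DPI and sizes are configurable.

## Synthetic crosses

The generator emulates the regime the pipeline is built for: two fully
homozygous parents differing at Poisson-placed SNP sites (positions
uniform, expected density `snp_density` per kb; each site gets distinct
non-reference alleles per parent, so every site is informative), and
offspring formed by piecewise copying of parental haplotypes switching at
crossover positions drawn uniformly without replacement — no crossover
interference, no mutation-spectrum realism, no selection or segregation
distortion. Optional noise: a fraction of offspring sites emitted as
heterozygous calls (which the caller drops) and a fraction flipped to a
fourth, non-parental base (which the caller labels Unknown). A truth
table records the exact parental segments tiling each chromosome.

Default conditions are a small fungal-scale genome: 3 chromosomes × 5 Mb,
1 SNP/kb, 4 offspring, 2 crossovers per chromosome, zero noise, seed 0.
Passing tests on this synthetic regime demonstrates correctness of the
bookkeeping — labeling, clustering, accounting — not robustness to
alignment artifacts, reference bias, copy-number variation or uneven SNP
density, none of which the generator models.

Accuracy against the truth set is evaluated over cluster-covered bases
only: chromosome ends beyond the terminal SNPs and the inter-SNP windows
around true breakpoints are below SNP resolution and are not counted
either way. Breakpoint recovery compares the number of label transitions
between consecutive clusters with the true crossover count; two
crossovers falling within one inter-SNP gap are undetectable in
principle, which is why recovery is asserted as a ≥95% rate over seeds
rather than exact equality.

## Problem sizes and numerical choices

The test suite exercises the full study scale (3 × 5 Mb, 20 seeds) in one
recovery test and otherwise uses 50–200 kb chromosomes with the same
density and crossover counts, which preserves every code path at a
fraction of the cost. Percentages are computed in double precision from
integer spans; the sum-to-100 invariant is asserted to 1e−9. There are no
tolerances anywhere else — every other comparison in the pipeline is
exact integer or string arithmetic, and identical inputs give
byte-identical outputs (the only RNG in the package lives in the
simulator, behind a fixed seed).

## Known limitations

Polyploids are untested and out of scope. BCF, INFO/FILTER-based quality
filtering, statistical changepoint or HMM smoothing, and significance
tests on recombination patterns are deliberately absent. Whether pass 2
should be allowed to merge across an intervening *large* Unknown cluster
is an open design point; this implementation does not.
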