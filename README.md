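# pedpaint

Deterministic parent-of-origin assignment, ancestry-block clustering,
quantification and chromosome painting for controlled crosses.

`pedpaint` is for experimentalists who know the pedigree — a yeast cross,
a common-garden hybrid, two representative reference genomes for a hybrid
zone — and want to see and measure which parent each part of an offspring
genome came from. That question is the opposite of population-level
ancestry *inference*: here the ancestries are given, so the tool uses no
statistical model at all. Every call is an exact allele match, every run
is reproducible byte-for-byte.

## Method

For each offspring VCF, sites are reduced to homozygous (or haploid)
single-nucleotide calls; heterozygous, missing and indel sites are dropped,
so no phasing is required. Each surviving site with allele *o* is compared
to the parental alleles *p₁*, *p₂* and labeled

- **Parent1** if *o = p₁* and *o ≠ p₂*,
- **Parent2** if *o = p₂* and *o ≠ p₁*,
- **Unknown** if *o* matches both (uninformative) or neither;

sites absent from both parents are discarded. Labeled SNPs are then
clustered in two passes. Pass 1 run-length groups consecutive same-label
SNPs (per chromosome, sorted by position) and keeps a run only if its
nucleotide span `end − start + 1` reaches the minimum cluster length
(`-C`, default 10 nt). Pass 2 smooths the chain: a cluster spanning less
than the small-cluster threshold (`--max-gap`, default 1000 nt) that sits
between two clusters of one other label is treated as a false positive —
a genuine double crossover within a few hundred nucleotides is
implausible in most systems — and is deleted, its flanks merged into one
block. For example, two 10 kb Parent1 clusters separated by a 100 nt
Parent2 cluster become a single ~20 kb Parent1 cluster.

Contributions are quantified over the *informative regions* only (the
union of cluster spans, Unknown included), never over the full chromosome
length; gene-level contributions intersect the blocks with a GTF and give
each gene the label with the largest summed overlap. Painted chromosomes
and stacked barplots are rendered from the same tidy TSVs the pipeline
writes, so custom plotting never requires a re-run.

## Worked example

Simulate a small cross with known crossovers (3 chromosomes × 200 kb,
1 SNP/kb between the parents, 2 crossovers per chromosome, 4 offspring),
run the pipeline, and paint:

```sh
pedpaint simulate -o sim --n-chroms 3 --chrom-len 200000 --n-offspring 4 --seed 11
pedpaint base -1 sim/parent1.vcf -2 sim/parent2.vcf -o run sim/offspring*.vcf
pedpaint paint run/clusters.tsv -o figs --gtf sim/genes.gtf --genes
```

`run/clusters.tsv` holds the ancestry blocks (1-based, closed intervals):

```
individual	chrom	start	end	label	n_snps	span
offspring1	chr1	802	139437	Parent1	122	138636
offspring1	chr1	142308	194420	Parent2	48	52113
offspring1	chr1	195640	199810	Parent1	11	4171
```

offspring1's chr1 is a Parent1 block of ~139 kb, a Parent2 block of
~52 kb, then Parent1 again — two recombination breakpoints, matching the
two simulated crossovers. `figs/genome_pct.tsv` turns the same blocks
into per-chromosome percentages of the informative sequence:

```
individual	chrom	label	pct
offspring1	chr1	Parent1	73.3
offspring1	chr1	Parent2	26.7
offspring1	chr1	Unknown	0.0
```

and `figs/gene_pct.tsv` the share of genes per ancestry (on chr1, 70%
Parent1, 25% Parent2, 5% Unknown — the Unknown gene straddles a
breakpoint with a tied overlap). `figs/painting.png` is the composite
painting, one colored track per individual × chromosome; the
`genome_pct` / `gene_pct` figures are the stacked barplots.

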