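# ebfunnel

Recessive-model disease-variant discovery for Mendelian traits, packaged as
a small, tested pipeline. It was built around a canine genetics use case —
finding the *COL7A1* nonsense variant behind recessive dystrophic
epidermolysis bullosa (RDEB) in Central Asian Shepherd dogs — but every
stage is generic: give it a case genome's variants, control genomes, gene
models, and a disease-gene panel, and it returns candidate causal variants
with full coding-consequence annotation.

## What it computes

**Filter funnel.** Starting from all called variants in one affected
("case") genome, four ordered stages shrink the list under a fully
penetrant autosomal recessive model:

1. *case homozygous* — keep sites where the case is homozygous for the
   alternate allele;
2. *control exclusion* — drop sites where any control genome is also
   homozygous for that allele (carriers are allowed: for a recessive
   allele, unaffected heterozygotes are expected in the population; a
   strict policy that also excludes carriers is available);
3. *coding* — keep variants overlapping a CDS, annotated against
   strand-aware gene models;
4. *panel* — keep variants in genes already known to cause the disease.

**Consequence annotation.** For a substitution at genomic position *g*, the
spliced-CDS coordinate *c* is computed by walking CDS exons in translation
order; the affected codon is ⌈*c*/3⌉ and the change is classified
(synonymous / missense / nonsense / stop-lost / start-lost) by translating
the reference and mutated codons under the standard genetic code. Results
are reported in HGVS nomenclature, e.g. `c.4579C>T` (CDS base 4579, C→T)
and `p.R1527*` (arginine 1527 → stop).

**Segregation.** A candidate is checked for complete co-segregation with
the phenotype through a pedigree: affected individuals must be homozygous,
unaffected ones must not be, parents of affecteds are obligate carriers,
and parent–offspring genotype pairs must be Mendelian-possible.

**Cohort screening.** Carrier frequency (heterozygotes / genotyped, with a
95% Wilson score interval), allele frequency, Hardy–Weinberg expected
homozygote fraction, and a breed-specificity verdict across cohorts.

**Synthetic study generator.** Because the pipeline is exercised end to end
on simulated data, the package includes a deterministic generator that
emulates the study design: a genome fragment with eight multi-exon genes,
a COL7A1-like gene whose CGA codon 1527 is mutated to TGA (so the planted
variant is literally `c.4579C>T` / `p.R1527*`), a carrier×carrier litter of
eight with Mendelian transmission, 31 unrelated control genomes with shared
background variation, a 19-gene EB panel, and a six-breed screening table
(13/47 carriers in the index breed, 143 allele-free dogs elsewhere).

## Worked example

```sh
ebfunnel run-all --seed 1 --out demo
```

simulates a dataset into `demo/data/` and runs filter → segregate →
cohorts, logging:

```
INFO ebfunnel: stage total             501 surviving
INFO ebfunnel: stage case_homozygous   49 surviving
INFO ebfunnel: stage control_exclusion 3 surviving
INFO ebfunnel: stage coding            2 surviving
INFO ebfunnel: stage panel             2 surviving
INFO ebfunnel: 2 candidate(s) written to demo/results
INFO ebfunnel: segregates: true
INFO ebfunnel: penetrance: 1.000
INFO ebfunnel: index cohort Central Asian Shepherd Dog: carrier frequency 27.7% (13/47)
INFO ebfunnel: verdict: breed-specific; non-index total 143
```

Reading the numbers: of 501 biallelic sites in the case genome, 49 are
homozygous in the case; only 3 of those are never homozygous in any of the
31 controls; 2 fall in coding sequence, both in the panel gene. The
candidate table (`demo/results/candidates.tsv`) shows why the first one is
the prime suspect:

```
chrom   pos    ref  alt  gene    transcript  effect    hgvs_c     hgvs_p
chr20   8598   G    A    COL7A1  COL7A1-t1   nonsense  c.4579C>T  p.R1527*
chr20   13191  A    T    COL7A1  COL7A1-t1   missense  c.299T>A   p.F100Y
```

The planted truncating variant (the gene is on the minus strand, so the
genomic G→A is a C→T change in the coding sequence) surfaces as a nonsense
change at codon 1527, it segregates perfectly through the simulated litter
(the two homozygous pups are the two affected ones), and the screening
table shows the allele confined to the index breed at 27.7% carrier
frequency with 143 clean dogs in related breeds.

Each step is also available on its own (`ebfunnel simulate / filter /
segregate / cohorts`; see `--help`) and as plain library functions
(`ebfunnel.run_funnel`, `ebfunnel.annotate_variant`,
`ebfunnel.check_recessive_segregation`, `ebfunnel.screen_summary`, ...).

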