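# Methods

## Model and scope

The pipeline assumes a fully penetrant autosomal recessive model: the
affected individual is homozygous for the causal allele, unaffected
individuals are not, and the allele is transmitted Mendelianly. All
coordinates are 1-based and fully closed, matching VCF `POS`. Genotypes
are diploid and unphased; phase separators are accepted on input and
discarded, since no stage uses phase. Multi-allelic records are split into
biallelic sites on read, one per ALT allele, with genotypes recoded
relative to the target allele; other ALT alleles count as non-target (not
missing), because the recessive filter only asks about the target allele's
dosage.

## Filter funnel

Stages run in a fixed order — total, case-homozygous, control exclusion,
coding, panel — and survivor counts are recorded after each, so the report
is monotonically non-increasing by construction of the set operations.
Decisions at the margins:

- A MISSING case genotype fails the homozygosity stage: the model demands
  an *observed* homozygote.
- A MISSING control genotype never excludes a site: absence of evidence is
  not a reference call.
- The default control policy excludes a site only when a control is
  homozygous for the same alternate allele. Unaffected carriers are
  expected for a recessive allele, so heterozygous controls are
  uninformative under the default. The strict policy (exclude on any
  carried alt allele) is provided for control panels drawn from populations
  where carriers are implausible, e.g. unrelated breeds.
- The default coding scope keeps any CDS-overlapping variant, synonymous
  included; a protein-altering-only scope is available. Both are exposed
  because reasonable analyses differ on whether synonymous changes belong
  in a "coding variants" count.
- The "total" stage counts sites after multi-allelic splitting, so it can
  exceed the raw record count of the input VCF.

## Consequence annotation

The spliced-CDS coordinate of a genomic position is obtained by walking CDS
exons in translation order: ascending genomic order on the plus strand,
descending from the highest CDS coordinate on the minus strand. Codon
number and offset follow from integer arithmetic
(codon = ⌊(c−1)/3⌋+1, offset = ((c−1) mod 3)+1). Reference codons are
extracted base-by-base through the inverse CDS→genome mapping and
complemented on the minus strand; translation uses the standard nuclear
genetic code only (both canine COL7A1 variants relevant to the use case
are nuclear). The stated reference allele is checked against the genome
FASTA on the genomic strand; a mismatch is a hard data-integrity error
rather than a warning, since it invalidates every downstream conclusion.

Classification: equal amino acids are synonymous; a new stop strictly
before the final codon is nonsense (a new stop *at* the natural stop is
synonymous-at-stop, not a truncation); a lost stop is stop_lost; a changed
initiator methionine at codon 1 is start_lost; everything else is
missense. Indels inside a CDS are carried as `coding_other` without codon
arithmetic — frameshift/in-frame p. nomenclature is out of scope, and the
use case's causal variant is a substitution. When a variant overlaps
several transcripts all annotations are returned, and filtering uses the
most severe under the order nonsense > stop_lost > start_lost > missense >
coding_other > synonymous > non_coding.

HGVS output uses CDS-relative c. numbering starting at the first base of
the start codon, and one-letter amino-acid codes with `*` for stop
(`c.4579C>T`, `p.R1527*`). UTR/intronic offset notation (`c.-`, `c.*`,
`c.+`) is not produced; variants outside every CDS exon are simply
non-coding here.

## Segregation checking

Four rules define complete segregation (see `segregation.RULES`): affected
⇒ homozygous alt; unaffected ⇒ not homozygous alt; parents of affecteds
are obligate carriers (a homozygous-reference parent is a violation); and
parent–offspring pairs must be Mendelian-possible. Full penetrance is a
hard assumption — an unaffected homozygote is a violation, not a penetrance
observation — because the modelled disease manifests at birth; a tolerant
mode is deliberately not provided. Untested individuals (no genotype, or
MISSING) are unconstrained by the phenotype rules but still participate in
Mendelian checks as parents; unknown-phenotype individuals likewise.
Penetrance is reported as the affected fraction of homozygotes with known
phenotype, or absent when there are none.

## Cohort statistics

"Carrier" means heterozygote only; affected homozygotes are tallied
separately, which is what makes 13 carriers among 47 genotyped dogs a
27.7% carrier frequency regardless of the 2 homozygotes in the cohort.
Percentages are rendered to one decimal, rounding half away from zero.
Intervals on the carrier frequency are 95% Wilson score intervals (via
statsmodels), chosen over Wald because they behave sensibly at zero
successes — exactly the situation in unaffected related breeds; the bounds
are clamped to exactly 0 at zero successes and 1 at full success, where
the closed form is exact but generic floating-point evaluation leaves
residue. No hypothesis tests are performed: the screening counts are small
and the scientific claim ("absent elsewhere") is a verdict, not a p-value;
only Hardy–Weinberg *expectations* (q²) are reported.

## Synthetic study generator

The generator's defaults encode the emulated study conditions: one case,
31 controls, a litter of eight from carrier×carrier parents, a causal gene
of 2,944 codons whose codon 1527 is CGA mutated to TGA (so the planted
variant's CDS coordinate is 3·1526+1 = 4579 and its annotation is
`c.4579C>T` / `p.R1527*`), seven 120-codon decoy genes, 500 background
sites with alt-allele frequencies uniform on [0.05, 0.5], a 19-gene
disease panel, and a six-breed cohort table (index breed 47/13/2; 143
allele-free dogs across five related breeds). Gene strands are random, so
the minus-strand bookkeeping (genomic G→A for a coding C>T) is exercised
routinely.

One seed feeds a hierarchical random stream split by purpose (genome /
pedigree / background), so changing the litter size does not perturb the
genome. Identical configurations yield byte-identical output files.

What the generator does *not* emulate, and hence what green tests do not
establish about real data: linkage disequilibrium (background sites are
independent), relatedness among controls, genotyping error and missingness
(all simulated genotypes are called), read-level artefacts, structural
variants, and realistic genome composition (GC content, repeats). The
funnel's behaviour under those features is untested here; the pipeline's
contracts (stage logic, coordinate arithmetic, Mendelian bookkeeping,
statistics) are what the suite verifies.

Problem sizes in the test suite are the generator defaults (60 kb genome,
8 genes, 32 genomes, 501 sites) for end-to-end checks, with a reduced
configuration (15 kb, 4 genes) for Monte-Carlo trend checks across many
seeds; both were chosen as the smallest sizes at which every structural
feature (multi-exon genes on both strands, coding and non-coding
background hits, carrier controls) occurs routinely.

## Numerical and degenerate-input choices

- Variant alleles are validated as non-empty uppercase ACGT; ref = alt is
  rejected at construction.
- An empty gene panel is an error (a panel matching nothing is a likely
  user mistake), as is an empty cohort table or a PED file with no rows.
- Chromosome names are matched by exact string equality across VCF, FASTA
  and GFF3; no "chr" normalization is attempted.
- VCF writing is bit-stable: records sorted by (chrom, pos, ref, alt),
  GT-only FORMAT, `.` in QUAL/FILTER/INFO.
- The funnel on an empty site list reports all-zero stages and no
  candidates; a panel-less configuration records the panel stage with the
  coding-stage count (skipped, all kept).

## Interfaces

The library is the primary interface; the `ebfunnel` CLI is a thin layer
over it with subcommands simulate / filter / segregate / cohorts /
run-all, YAML config files (CLI flags take precedence), logs to stderr,
results only to files, and exit codes 0 (success), 1 (usage), 2
(data/format error). `run-all` writes a manifest (version, seed, config
hash) for reproducibility.
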