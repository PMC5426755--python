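"""A self-contained synthetic study for exercising the whole pipeline:
genome fragment, multi-exon gene models, a planted CGA->TGA nonsense
variant, a two-generation pedigree with Mendelian transmission, unrelated
control genomes with shared background variation, and breed cohort tables.

The defaults mirror the emulated study design: one sequenced case from a
litter of eight born to carrier parents, 31 unrelated control genomes, a
COL7A1-like causal gene whose arginine codon 1527 (CGA, first base at
spliced-CDS position 4579) is mutated to a stop (TGA), a 19-gene disease
panel, and a six-breed screening table in which only the index breed
carries the allele (13 heterozygous carriers and 2 affected homozygotes
among 47 dogs).

Randomness is one hierarchical stream: the dataset seed is split by purpose
(genome / pedigree / background), so changing the litter size does not
perturb the genome.  Identical configurations produce byte-identical files.
Background variants are independent across sites — no linkage
disequilibrium — and controls are unrelated; both simplifications are
deliberate, as the funnel consumes genotypes site by site.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .consequence import genomic_position, reverse_complement
from .domain import (
    CohortCounts,
    Genotype,
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    Site,
    Variant,
)
from .errors import DomainError, LayoutError
from .io_formats import (
    GenomeSequence,
    Transcript,
    eb_panel_text,
    write_cohorts,
    write_fasta,
    write_gene_models,
    write_pedigree,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]

#: Screening-table shape of the emulated study: the index breed with 13
#: carriers and 2 affected homozygotes among 47 dogs; 143 allele-free dogs
#: across five related breeds.
DEFAULT_COHORTS: tuple[CohortCounts, ...] = (
    CohortCounts("Central Asian Shepherd Dog", 47, 13, 2),
    CohortCounts("Caucasian Shepherd Dog", 39, 0, 0),
    CohortCounts("South Russian Ovcharka", 3, 0, 0),
    CohortCounts("Kuvasz", 6, 0, 0),
    CohortCounts("Slovakian Chuvach", 19, 0, 0),
    CohortCounts("Tibetan Mastiff", 76, 0, 0),
)

DEFAULT_INDEX_COHORT = "Central Asian Shepherd Dog"


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults emulate the study design."""

    seed: int = 0
    chrom: str = "chr20"
    chrom_length: int = 60_000
    n_genes: int = 8
    exons_per_gene: int = 6
    causal_gene_index: int = 3
    #: codon count of the causal gene, natural stop included
    causal_codon_count: int = 2944
    #: the CGA codon mutated to TGA; its first base is CDS position 3k-2
    causal_codon_number: int = 1527
    decoy_codon_count: int = 120
    litter_size: int = 8
    n_controls: int = 31
    background_site_count: int = 500
    #: uniform bounds on background alt-allele frequency
    background_alt_freq: tuple[float, float] = (0.05, 0.5)
    #: controls carrying one causal allele (exercises the strict policy)
    carrier_controls: int = 0
    cohorts: tuple[CohortCounts, ...] = DEFAULT_COHORTS
    index_cohort: str = DEFAULT_INDEX_COHORT

    def __post_init__(self) -> None:
        if self.litter_size < 1:
            raise DomainError("litter_size must be >= 1")
        if not 1 < self.causal_codon_number < self.causal_codon_count:
            raise DomainError(
                "causal_codon_number must be interior to the causal CDS"
            )
        if not 0 <= self.causal_gene_index < self.n_genes:
            raise DomainError("causal_gene_index out of range")
        if min(
            self.n_genes, self.exons_per_gene, self.n_controls,
            self.background_site_count, self.chrom_length,
        ) <= 0:
            raise DomainError("all counts must be positive")
        if self.carrier_controls > self.n_controls:
            raise DomainError("carrier_controls exceeds n_controls")

    def rng(self, purpose: int) -> np.random.Generator:
        """One child stream per purpose: 0=genome, 1=pedigree, 2=background."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(purpose,))
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of an emitted dataset, for downstream verification."""

    causal_variant: Variant
    causal_gene: str
    causal_transcript: str
    hgvs_c: str
    hgvs_p: str
    family_genotypes: Mapping[str, Genotype]
    cohorts: tuple[CohortCounts, ...]


# --- genome and gene models -------------------------------------------------

def _random_cds(
    rng: np.random.Generator, codon_count: int, forced: Optional[tuple[int, str]]
) -> str:
    """A spliced CDS: ATG, random sense codons, one natural stop; optionally
    one codon forced to a given triplet."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=codon_count - 2)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in idx]
    codons.append(_STOPS[int(rng.integers(0, len(_STOPS)))])
    if forced is not None:
        number, triplet = forced
        codons[number - 1] = triplet
    return "".join(codons)


def _partition(
    rng: np.random.Generator, total: int, parts: int, minimum: int
) -> list[int]:
    """Random composition of ``total`` into ``parts`` chunks, each >= minimum."""
    if total < parts * minimum:
        raise LayoutError(
            f"cannot split {total} bases into {parts} exons of >= {minimum}"
        )
    cuts = np.sort(rng.choice(total - parts * minimum + 1, size=parts - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [total - parts * minimum]]))
    return [int(s) + minimum for s in sizes]


def build_genome_and_genes(
    config: SimConfig,
) -> tuple[GenomeSequence, list[Transcript]]:
    """A random genome fragment carrying ``n_genes`` valid multi-exon genes.

    Every CDS starts with ATG, ends with a stop and has no internal stop;
    the causal gene's configured codon is forced to CGA (arginine).  Genes
    are laid out left to right with random intergenic gaps and introns.
    """
    rng = config.rng(0)
    seq = _BASES[rng.integers(0, 4, size=config.chrom_length)]

    transcripts: list[Transcript] = []
    cursor = 1  # 1-based next free position
    for gene_i in range(config.n_genes):
        causal = gene_i == config.causal_gene_index
        codon_count = (
            config.causal_codon_count if causal else config.decoy_codon_count
        )
        cds_len = 3 * codon_count
        forced = (config.causal_codon_number, "CGA") if causal else None
        cds = _random_cds(rng, codon_count, forced)

        strand = "+" if rng.integers(0, 2) == 0 else "-"
        exon_sizes = _partition(rng, cds_len, config.exons_per_gene, 10)
        introns = rng.integers(50, 150, size=config.exons_per_gene - 1)
        gap = int(rng.integers(200, 500))

        start = cursor + gap
        exons = []
        pos = start
        for i, size in enumerate(exon_sizes):
            exons.append((pos, pos + size - 1))
            if i < len(introns):
                pos += size + int(introns[i])
        end = exons[-1][1]
        if end > config.chrom_length:
            raise LayoutError(
                f"chrom_length {config.chrom_length} too small for "
                f"{config.n_genes} genes (needed > {end})"
            )
        cursor = end

        # write the CDS into the exon intervals; on '-' the ascending genomic
        # sequence across exons is the reverse complement of the spliced CDS
        genomic_cds = cds if strand == "+" else reverse_complement(cds)
        offset = 0
        for s, e in exons:
            chunk = genomic_cds[offset: offset + e - s + 1]
            seq[s - 1: e] = list(chunk)
            offset += e - s + 1

        symbol = "COL7A1" if causal else f"GENE{gene_i + 1}"
        transcripts.append(
            Transcript(
                id=f"{symbol}-t1",
                gene_symbol=symbol,
                chrom=config.chrom,
                strand=strand,
                cds_exons=tuple(exons),
            )
        )

    genome = GenomeSequence({config.chrom: "".join(seq)})
    return genome, transcripts


def plant_causal_variant(
    genome: GenomeSequence,
    causal_transcript: Transcript,
    codon_number: int,
) -> Variant:
    """The C>T substitution at the first base of a CGA codon, in genomic
    coordinates (G>A on the genome when the gene is on the '-' strand)."""
    from .consequence import reference_codon

    codon = reference_codon(causal_transcript, codon_number, genome)
    if codon != "CGA":
        raise DomainError(
            f"codon {codon_number} of {causal_transcript.id} is {codon}, "
            "not CGA; cannot plant an arginine-to-stop change there"
        )
    c_pos = 3 * (codon_number - 1) + 1
    gpos = genomic_position(causal_transcript, c_pos)
    if causal_transcript.strand == "+":
        ref, alt = "C", "T"
    else:
        ref, alt = "G", "A"
    assert genome[causal_transcript.chrom][gpos - 1] == ref
    return Variant(chrom=causal_transcript.chrom, pos=gpos, ref=ref, alt=alt)


# --- pedigree ---------------------------------------------------------------

_DOSAGE_TO_STATE = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def simulate_pedigree_genotypes(
    config: SimConfig,
) -> tuple[Pedigree, dict[str, Genotype]]:
    """A carrier-by-carrier mating with a litter of ``litter_size`` pups.

    Each pup draws one allele per parent independently; phenotype is
    affected iff homozygous for the causal allele (full penetrance); sexes
    are assigned uniformly.
    """
    rng = config.rng(1)
    individuals = [
        Individual("SIRE", None, None, Sex.MALE, Phenotype.UNAFFECTED),
        Individual("DAM", None, None, Sex.FEMALE, Phenotype.UNAFFECTED),
    ]
    genotypes = {"SIRE": Genotype.HET, "DAM": Genotype.HET}
    for i in range(1, config.litter_size + 1):
        dosage = int(rng.integers(0, 2)) + int(rng.integers(0, 2))
        state = _DOSAGE_TO_STATE[dosage]
        pup = f"PUP{i:02d}"
        individuals.append(
            Individual(
                pup,
                sire="SIRE",
                dam="DAM",
                sex=Sex.MALE if rng.integers(0, 2) == 0 else Sex.FEMALE,
                phenotype=(
                    Phenotype.AFFECTED
                    if state is Genotype.HOM_ALT
                    else Phenotype.UNAFFECTED
                ),
            )
        )
        genotypes[pup] = state
    return Pedigree(individuals), genotypes


def archetype_family() -> tuple[Pedigree, dict[str, Genotype]]:
    """The deterministic family of the emulated study: carrier parents, two
    affected homozygous pups and six unaffected carrier littermates."""
    individuals = [
        Individual("SIRE", None, None, Sex.MALE, Phenotype.UNAFFECTED),
        Individual("DAM", None, None, Sex.FEMALE, Phenotype.UNAFFECTED),
    ]
    genotypes = {"SIRE": Genotype.HET, "DAM": Genotype.HET}
    for i, (sex, pheno, state) in enumerate(
        [
            (Sex.MALE, Phenotype.AFFECTED, Genotype.HOM_ALT),
            (Sex.FEMALE, Phenotype.AFFECTED, Genotype.HOM_ALT),
        ]
        + [(Sex.MALE if j % 2 else Sex.FEMALE, Phenotype.UNAFFECTED,
            Genotype.HET) for j in range(6)],
        start=1,
    ):
        pup = f"PUP{i:02d}"
        individuals.append(Individual(pup, "SIRE", "DAM", sex, pheno))
        genotypes[pup] = state
    return Pedigree(individuals), genotypes


# --- background variation and controls --------------------------------------

def simulate_background_and_controls(
    config: SimConfig,
    genome: GenomeSequence,
    causal_variant: Variant,
) -> tuple[list[str], list[Site]]:
    """Sites over {case} + controls: shared background variation under
    Hardy-Weinberg plus the causal site, where the case is homozygous and
    the causal allele is absent from controls (unless ``carrier_controls``
    asks for heterozygous carriers)."""
    rng = config.rng(2)
    chrom_seq = genome[config.chrom]
    n_available = len(chrom_seq) - 1
    if config.background_site_count > n_available:
        raise LayoutError(
            f"{config.background_site_count} background sites requested but "
            f"only {n_available} positions available"
        )
    samples = ["CASE"] + [f"CTRL{i:02d}" for i in range(1, config.n_controls + 1)]

    pool = np.delete(np.arange(1, len(chrom_seq) + 1), causal_variant.pos - 1)
    positions = np.sort(
        rng.choice(pool, size=config.background_site_count, replace=False)
    )

    lo, hi = config.background_alt_freq
    sites: list[Site] = []
    for pos in positions:
        ref = chrom_seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        af = float(rng.uniform(lo, hi))
        dosages = rng.binomial(2, af, size=len(samples))
        genotypes = {
            s: _DOSAGE_TO_STATE[int(d)] for s, d in zip(samples, dosages)
        }
        sites.append(
            Site(Variant(config.chrom, int(pos), ref, alt), genotypes)
        )

    causal_genotypes = {"CASE": Genotype.HOM_ALT}
    for i, sample in enumerate(samples[1:]):
        causal_genotypes[sample] = (
            Genotype.HET if i < config.carrier_controls else Genotype.HOM_REF
        )
    causal_site = Site(causal_variant, causal_genotypes)
    sites.append(causal_site)
    sites.sort(key=lambda s: (s.variant.chrom, s.variant.pos))
    return samples, sites


# --- dataset emission -------------------------------------------------------

def build_truth(
    config: SimConfig,
    causal_variant: Variant,
    causal_transcript: Transcript,
    family_genotypes: Mapping[str, Genotype],
) -> TruthRecord:
    """Ground truth assembled by construction arithmetic: the expected HGVS
    strings come straight from the configured codon number, independently of
    the annotation code they are later checked against."""
    k = config.causal_codon_number
    return TruthRecord(
        causal_variant=causal_variant,
        causal_gene=causal_transcript.gene_symbol,
        causal_transcript=causal_transcript.id,
        hgvs_c=f"c.{3 * (k - 1) + 1}C>T",
        hgvs_p=f"p.R{k}*",
        family_genotypes=dict(family_genotypes),
        cohorts=config.cohorts,
    )


def generate_dataset(config: SimConfig):
    """Build every in-memory piece of the synthetic study.

    Returns (genome, transcripts, samples, sites, pedigree,
    family_genotypes, truth).
    """
    genome, transcripts = build_genome_and_genes(config)
    causal_transcript = transcripts[config.causal_gene_index]
    causal_variant = plant_causal_variant(
        genome, causal_transcript, config.causal_codon_number
    )
    pedigree, family_genotypes = simulate_pedigree_genotypes(config)
    samples, sites = simulate_background_and_controls(
        config, genome, causal_variant
    )
    truth = build_truth(
        config, causal_variant, causal_transcript, family_genotypes
    )
    return genome, transcripts, samples, sites, pedigree, family_genotypes, truth


def emit_dataset(config: SimConfig, outdir: str | os.PathLike) -> TruthRecord:
    """Write the full dataset to ``outdir``.

    Files: genome.fasta, genes.gff3, variants.vcf (case + controls),
    pedigree.ped, pedigree.vcf (family genotypes at the causal site),
    panel.txt, cohorts.tsv, truth.tsv.  Re-running with the same config is
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (genome, transcripts, samples, sites, pedigree, family_genotypes,
     truth) = generate_dataset(config)

    write_fasta(genome, outdir / "genome.fasta")
    write_gene_models(transcripts, outdir / "genes.gff3")
    write_vcf(samples, sites, outdir / "variants.vcf")
    write_pedigree(pedigree, outdir / "pedigree.ped")
    family_site = Site(truth.causal_variant, family_genotypes)
    write_vcf(
        [ind.id for ind in pedigree], [family_site], outdir / "pedigree.vcf"
    )
    (outdir / "panel.txt").write_text(eb_panel_text())
    write_cohorts(config.cohorts, outdir / "cohorts.tsv")

    with open(outdir / "truth.tsv", "w") as fh:
        v = truth.causal_variant
        fh.write(f"causal_chrom\t{v.chrom}\n")
        fh.write(f"causal_pos\t{v.pos}\n")
        fh.write(f"causal_ref\t{v.ref}\n")
        fh.write(f"causal_alt\t{v.alt}\n")
        fh.write(f"causal_gene\t{truth.causal_gene}\n")
        fh.write(f"causal_transcript\t{truth.causal_transcript}\n")
        fh.write(f"hgvs_c\t{truth.hgvs_c}\n")
        fh.write(f"hgvs_p\t{truth.hgvs_p}\n")
        for ind in pedigree:
            fh.write(
                f"genotype\t{ind.id}\t{family_genotypes[ind.id].value}\n"
            )
        for c in truth.cohorts:
            fh.write(
                f"cohort\t{c.label}\t{c.n_total}\t{c.n_het}\t{c.n_hom_alt}\n"
            )
    return truth
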