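"""Independent oracles and small constructors used across the test suite.

The oracles deliberately take a different route from the library code they
check: consequence annotation is verified against a splice-the-whole-CDS
oracle (the library extracts single codons by inverse coordinate mapping),
Wilson intervals against the textbook closed form (the library calls
statsmodels), and segregation against clause-by-clause scans.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Seq import Seq

from ebfunnel import Genotype, Phenotype, Site, Transcript, Variant
from ebfunnel.io_formats import GenomeSequence

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def splice_cds(transcript: Transcript, genome: GenomeSequence) -> str:
    """Full spliced CDS in translation order, by brute concatenation."""
    chrom = genome[transcript.chrom]
    parts = [chrom[s - 1: e] for s, e in transcript.cds_exons]
    cds = "".join(parts)
    return revcomp(cds) if transcript.strand == "-" else cds


def oracle_cds_index(transcript: Transcript, genomic_pos: int) -> int | None:
    """1-based spliced-CDS position of a genomic position, by enumerating
    every CDS base in translation order."""
    order = []
    if transcript.strand == "+":
        for s, e in transcript.cds_exons:
            order.extend(range(s, e + 1))
    else:
        for s, e in reversed(transcript.cds_exons):
            order.extend(range(e, s - 1, -1))
    try:
        return order.index(genomic_pos) + 1
    except ValueError:
        return None


def oracle_annotation(
    transcript: Transcript, genome: GenomeSequence, variant: Variant
) -> dict | None:
    """Codon-level annotation by splicing the whole CDS, substituting the
    base, chunking into triplets and translating with Biopython."""
    c_pos = oracle_cds_index(transcript, variant.pos)
    if c_pos is None:
        return None
    cds = splice_cds(transcript, genome)
    alt_base = (
        variant.alt
        if transcript.strand == "+"
        else COMPLEMENT[variant.alt]
    )
    mutated = cds[: c_pos - 1] + alt_base + cds[c_pos:]
    codon_number = (c_pos - 1) // 3 + 1
    lo, hi = 3 * (codon_number - 1), 3 * codon_number
    ref_codon, alt_codon = cds[lo:hi], mutated[lo:hi]
    return {
        "c_pos": c_pos,
        "codon_number": codon_number,
        "ref_codon": ref_codon,
        "alt_codon": alt_codon,
        "ref_aa": str(Seq(ref_codon).translate()),
        "alt_aa": str(Seq(alt_codon).translate()),
    }


def oracle_wilson(successes: int, n: int, confidence: float = 0.95):
    """Textbook Wilson score interval."""
    from scipy.stats import norm

    z = norm.ppf(1 - (1 - confidence) / 2)
    p = successes / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(0.0, centre - half), min(1.0, centre + half)


def oracle_segregation_violations(pedigree, genotypes):
    """Rule-by-rule scan; each clause tested independently of the others."""
    def geno(i):
        g = genotypes.get(i)
        return None if g is Genotype.MISSING else g

    violations = set()
    # (a) affected not hom-alt
    for ind in pedigree:
        if (
            ind.phenotype is Phenotype.AFFECTED
            and geno(ind.id) is not None
            and geno(ind.id) is not Genotype.HOM_ALT
        ):
            violations.add((ind.id, "a"))
    # (b) unaffected hom-alt
    for ind in pedigree:
        if (
            ind.phenotype is Phenotype.UNAFFECTED
            and geno(ind.id) is Genotype.HOM_ALT
        ):
            violations.add((ind.id, "b"))
    # (c) parent of an affected is hom-ref
    for ind in pedigree:
        if ind.phenotype is Phenotype.AFFECTED:
            for parent in (ind.sire, ind.dam):
                if parent is not None and geno(parent) is Genotype.HOM_REF:
                    violations.add((parent, "c"))
    # (d) parent-offspring impossibility
    for ind in pedigree:
        g = geno(ind.id)
        if g is None:
            continue
        for parent in (ind.sire, ind.dam):
            pg = geno(parent) if parent is not None else None
            if pg is None:
                continue
            if (g is Genotype.HOM_ALT and pg is Genotype.HOM_REF) or (
                g is Genotype.HOM_REF and pg is Genotype.HOM_ALT
            ):
                violations.add((ind.id, "d"))
    return violations


def random_transcript_and_genome(rng: np.random.Generator):
    """A random valid transcript (<= 10 exons, CDS <= 999 bases) embedded in
    a random genome fragment, for oracle-equivalence testing."""
    n_exons = int(rng.integers(1, 11))
    codon_count = int(rng.integers(max(2, n_exons), 334))
    cds_len = 3 * codon_count
    # random composition of cds_len into n_exons parts each >= 1
    if n_exons == 1:
        sizes = [cds_len]
    else:
        cuts = np.sort(
            rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False)
        )
        sizes = np.diff(np.concatenate([[0], cuts, [cds_len]])).tolist()
    exons = []
    pos = int(rng.integers(1, 50))
    for size in sizes:
        exons.append((pos, pos + size - 1))
        pos += size + int(rng.integers(5, 40))
    genome_len = exons[-1][1] + int(rng.integers(0, 30))
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=genome_len))
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    transcript = Transcript(
        id="tx", gene_symbol="G", chrom="chrR", strand=strand,
        cds_exons=tuple(exons),
    )
    return transcript, GenomeSequence({"chrR": seq})


def random_coding_variant(
    rng: np.random.Generator, transcript: Transcript, genome: GenomeSequence
) -> Variant:
    """A substitution at a uniformly chosen CDS position of the transcript."""
    cds_positions = [
        p for s, e in transcript.cds_exons for p in range(s, e + 1)
    ]
    pos = int(rng.choice(cds_positions))
    ref = genome[transcript.chrom][pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return Variant(chrom=transcript.chrom, pos=pos, ref=ref, alt=alt)


def make_site(variant: Variant, **genotypes: Genotype) -> Site:
    return Site(variant, genotypes)
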