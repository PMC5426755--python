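"""Coding-consequence annotation: map genomic substitutions to spliced-CDS
coordinates, derive codon and amino-acid changes, classify the effect, and
emit HGVS c./p. nomenclature.

c. positions count spliced CDS bases from the first base of the start
codon, the convention behind names like ``c.4579C>T`` / ``p.R1527*``.
UTR/intronic offset notation (c.-, c.*, c.+) is out of scope: variants
outside every CDS exon are simply not coding here.  Only the standard
nuclear genetic code (translation table 1) is used.

Severity, most to least, for picking a representative annotation when a
variant overlaps several transcripts:
nonsense > stop_lost > start_lost > missense > coding_other > synonymous
> non_coding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table

from .domain import Variant
from .errors import DataIntegrityError, DomainError, FormatError
from .io_formats import GenomeSequence, Transcript

EFFECT_SEVERITY = (
    "nonsense",
    "stop_lost",
    "start_lost",
    "missense",
    "coding_other",
    "synonymous",
    "non_coding",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CdsPosition:
    """A 1-based position within a transcript's spliced CDS."""

    transcript_id: str
    c_pos: int


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """The derived codon change, amino-acid change, class and HGVS strings
    for one variant on one transcript.

    Codon fields are None for non-substitution (coding_other) annotations,
    where no single codon change is defined.
    """

    transcript_id: str
    gene_symbol: str
    effect: str
    c_pos: Optional[int] = None
    codon_number: Optional[int] = None
    codon_offset: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None


def cds_position(transcript: Transcript, genomic_pos: int) -> Optional[CdsPosition]:
    """Map a genomic position to its spliced-CDS coordinate, or None when
    the position lies outside every CDS exon.

    On '+' transcripts counting walks exons in ascending genomic order; on
    '-' it starts at the highest CDS coordinate and walks downward.
    """
    if genomic_pos < 1:
        raise DomainError(f"genomic position must be >= 1, got {genomic_pos}")
    if transcript.strand == "+":
        offset = 0
        for start, end in transcript.cds_exons:
            if start <= genomic_pos <= end:
                return CdsPosition(transcript.id, offset + genomic_pos - start + 1)
            offset += end - start + 1
    else:
        offset = 0
        for start, end in reversed(transcript.cds_exons):
            if start <= genomic_pos <= end:
                return CdsPosition(transcript.id, offset + end - genomic_pos + 1)
            offset += end - start + 1
    return None


def genomic_position(transcript: Transcript, c_pos: int) -> int:
    """Inverse of :func:`cds_position`: the genomic coordinate of spliced-CDS
    base ``c_pos``."""
    if not 1 <= c_pos <= transcript.cds_length:
        raise DomainError(
            f"c_pos {c_pos} outside CDS of length {transcript.cds_length}"
        )
    remaining = c_pos
    if transcript.strand == "+":
        for start, end in transcript.cds_exons:
            size = end - start + 1
            if remaining <= size:
                return start + remaining - 1
            remaining -= size
    else:
        for start, end in reversed(transcript.cds_exons):
            size = end - start + 1
            if remaining <= size:
                return end - remaining + 1
            remaining -= size
    raise AssertionError("unreachable: c_pos within validated CDS length")


def codon_index(c_pos: int) -> tuple[int, int]:
    """(codon_number, codon_offset) for a spliced-CDS position; both 1-based,
    offset in {1,2,3}."""
    if c_pos < 1:
        raise DomainError(f"c_pos must be >= 1, got {c_pos}")
    return (c_pos - 1) // 3 + 1, (c_pos - 1) % 3 + 1


def cds_base(transcript: Transcript, c_pos: int, genome: GenomeSequence) -> str:
    """The reference base at spliced-CDS position ``c_pos`` in translation
    order (complemented for '-' strand transcripts)."""
    gpos = genomic_position(transcript, c_pos)
    base = genome[transcript.chrom][gpos - 1]
    if transcript.strand == "-":
        base = base.translate(_COMPLEMENT)
    return base


def reference_codon(
    transcript: Transcript, codon_number: int, genome: GenomeSequence
) -> str:
    """The three reference CDS bases of a codon, in translation order."""
    if not 1 <= codon_number <= transcript.codon_count:
        raise DomainError(
            f"codon {codon_number} outside CDS of {transcript.codon_count} "
            "codons"
        )
    first = 3 * (codon_number - 1) + 1
    return "".join(
        cds_base(transcript, c, genome) for c in (first, first + 1, first + 2)
    )


def translate_codon(triplet: str) -> str:
    """Standard genetic code, single-letter amino acids, '*' for stop.
    Ambiguity codes (including N) are rejected."""
    if len(triplet) != 3 or not set(triplet) <= set("ACGT"):
        raise DomainError(f"not an unambiguous DNA triplet: {triplet!r}")
    if triplet in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[triplet]


def classify_substitution(
    ref_aa: str, alt_aa: str, codon_number: int, cds_codon_count: int
) -> str:
    """Classify an amino-acid change.

    The CDS's final codon is its natural stop: a new stop there is
    synonymous-at-stop, not nonsense; only a stop arising strictly before
    the last codon truncates the protein.
    """
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*" and codon_number < cds_codon_count:
        return "nonsense"
    if ref_aa == "*":
        return "stop_lost"
    if codon_number == 1 and ref_aa == "M":
        return "start_lost"
    return "missense"


def annotate_variant(
    variant: Variant,
    transcripts: Sequence[Transcript],
    genome: GenomeSequence,
) -> list[ConsequenceAnnotation]:
    """Annotate a variant against every overlapping transcript.

    Returns one annotation per transcript whose CDS the variant touches;
    an empty list means no CDS overlap.  Substitutions get the full codon /
    amino-acid / HGVS treatment; indels inside a CDS are labelled
    ``coding_other`` without codon arithmetic.
    """
    annotations = []
    for transcript in transcripts:
        if transcript.chrom != variant.chrom:
            continue
        if not variant.is_substitution:
            # indel: flag CDS overlap anywhere within the ref span
            span = range(variant.pos, variant.pos + len(variant.ref))
            if any(transcript.contains(p) for p in span):
                annotations.append(
                    ConsequenceAnnotation(
                        transcript_id=transcript.id,
                        gene_symbol=transcript.gene_symbol,
                        effect="coding_other",
                    )
                )
            continue
        cpos = cds_position(transcript, variant.pos)
        if cpos is None:
            continue
        chrom_seq = genome.get(transcript.chrom)
        if chrom_seq is None:
            raise DataIntegrityError(
                f"chromosome {transcript.chrom!r} absent from the genome; "
                f"available: {sorted(genome)}"
            )
        genome_base = chrom_seq[variant.pos - 1]
        if genome_base != variant.ref:
            raise DataIntegrityError(
                f"reference mismatch at {variant.chrom}:{variant.pos}: "
                f"variant says {variant.ref}, genome says {genome_base}"
            )
        ref_cds = variant.ref
        alt_cds = variant.alt
        if transcript.strand == "-":
            ref_cds = ref_cds.translate(_COMPLEMENT)
            alt_cds = alt_cds.translate(_COMPLEMENT)
        codon_number, codon_offset = codon_index(cpos.c_pos)
        ref_codon = reference_codon(transcript, codon_number, genome)
        alt_codon = (
            ref_codon[: codon_offset - 1] + alt_cds + ref_codon[codon_offset:]
        )
        ref_aa = translate_codon(ref_codon)
        alt_aa = translate_codon(alt_codon)
        effect = classify_substitution(
            ref_aa, alt_aa, codon_number, transcript.codon_count
        )
        annotations.append(
            ConsequenceAnnotation(
                transcript_id=transcript.id,
                gene_symbol=transcript.gene_symbol,
                effect=effect,
                c_pos=cpos.c_pos,
                codon_number=codon_number,
                codon_offset=codon_offset,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                hgvs_c=format_hgvs_c(cpos.c_pos, ref_cds, alt_cds),
                hgvs_p=f"p.{ref_aa}{codon_number}{alt_aa}",
            )
        )
    return annotations


def best_annotation(
    annotations: Sequence[ConsequenceAnnotation],
) -> Optional[ConsequenceAnnotation]:
    """The most severe annotation, or None for an empty list."""
    if not annotations:
        return None
    return min(annotations, key=lambda a: EFFECT_SEVERITY.index(a.effect))


# --- HGVS c. strings --------------------------------------------------------

_HGVS_C_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")


def format_hgvs_c(c_pos: int, ref_base: str, alt_base: str) -> str:
    if c_pos < 1:
        raise DomainError(f"c_pos must be >= 1, got {c_pos}")
    for base in (ref_base, alt_base):
        if base not in "ACGT" or len(base) != 1:
            raise DomainError(f"not a single ACGT base: {base!r}")
    return f"c.{c_pos}{ref_base}>{alt_base}"


def parse_hgvs_c(text: str) -> tuple[int, str, str]:
    m = _HGVS_C_RE.match(text)
    if m is None:
        raise FormatError(f"not a c.<pos><ref>><alt> HGVS string: {text!r}")
    return int(m.group(1)), m.group(2), m.group(3)
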