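"""Readers and writers for the five file formats the pipeline touches:
VCF (v4.2 subset), FASTA, GFF3 (gene/mRNA/CDS subset), PED, and the
plain-text gene panel / TSV cohort table.

VCF dialect: only CHROM/POS/REF/ALT/GT are semantic.  QUAL/FILTER/INFO are
ignored on read and written as ".", because the analysis consumes genotypes
only.  Chromosome-name matching across files is exact string equality — no
"chr" normalization is attempted; a mismatch surfaces downstream as a hard
error.

All readers either return values satisfying the domain-type invariants or
raise; round-trips through the corresponding writers are exact on the
supported subset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain import (
    CohortCounts,
    Genotype,
    Individual,
    Pedigree,
    Phenotype,
    Sex,
    Site,
    split_multiallelic,
)
from .errors import ConsistencyError, FormatError, ModelError

_GENOME_ALPHABET = frozenset("ACGTN")

_GT_OUT = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


class GenomeSequence(dict):
    """Mapping from chromosome name to an uppercase DNA string (A/C/G/T/N)."""

    def __init__(self, sequences: dict[str, str]):
        cleaned = {}
        for name, seq in sequences.items():
            if not seq:
                raise FormatError(f"sequence {name!r} is empty")
            seq = seq.upper()
            if not set(seq) <= _GENOME_ALPHABET:
                bad = sorted(set(seq) - _GENOME_ALPHABET)
                raise FormatError(
                    f"sequence {name!r} contains non-ACGTN characters: {bad}"
                )
            cleaned[name] = seq
        super().__init__(cleaned)


@dataclass(frozen=True)
class Transcript:
    """Strand-aware CDS exon structure used for c.-coordinate mapping.

    ``cds_exons`` are 1-based closed genomic intervals, stored in ascending
    genomic order regardless of strand; strand decides translation order.
    """

    id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(
                f"transcript {self.id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.cds_exons:
            raise ModelError(f"transcript {self.id!r} has no CDS exons")
        object.__setattr__(self, "cds_exons", tuple(map(tuple, self.cds_exons)))
        prev_end = 0
        for start, end in self.cds_exons:
            if start > end:
                raise ModelError(
                    f"transcript {self.id!r}: exon ({start},{end}) has "
                    "start > end"
                )
            if start <= prev_end:
                raise ModelError(
                    f"transcript {self.id!r}: CDS exons overlap or are "
                    "unsorted"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise ModelError(
                f"transcript {self.id!r}: CDS length {self.cds_length} is "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)

    @property
    def codon_count(self) -> int:
        return self.cds_length // 3

    def contains(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.cds_exons)


# --- FASTA ------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence({rec.id: str(rec.seq) for rec in records})


def write_fasta(genome: GenomeSequence, path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# --- VCF --------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[Site]]:
    """Read a VCF v4.2-like file into sample ids and biallelic Sites.

    Multi-allelic records are split on read, so the returned list can be
    longer than the record count.  GT must be the first FORMAT key.
    """
    samples: list[str] | None = None
    sites: list[Site] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10:
                    raise FormatError(
                        f"{path}:{lineno}: #CHROM header has no sample columns"
                    )
                samples = fields[9:]
                continue
            if samples is None:
                raise FormatError(
                    f"{path}: record encountered before #CHROM header "
                    f"(line {lineno})"
                )
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise FormatError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, _id, ref, alt = fields[0:5]
            fmt = fields[8]
            if fmt.split(":")[0] != "GT":
                raise FormatError(
                    f"{path}:{lineno}: GT is not the first FORMAT key"
                )
            gt_tokens = {
                sample: value.split(":")[0]
                for sample, value in zip(samples, fields[9:])
            }
            try:
                sites.extend(
                    split_multiallelic(
                        chrom, int(pos), ref.upper(), alt.upper().split(","),
                        gt_tokens,
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if samples is None:
        raise FormatError(f"{path}: missing #CHROM header line")
    return samples, sites


def write_vcf(
    samples: Sequence[str],
    sites: Iterable[Site],
    path: str | os.PathLike,
) -> None:
    """Write biallelic Sites as a minimal, bit-stable VCF v4.2 file.

    Records are sorted by (chrom, pos, ref, alt); FORMAT is GT only;
    QUAL/FILTER/INFO are '.'.  Every site must genotype exactly the given
    samples (MISSING allowed).
    """
    samples = list(samples)
    sample_set = set(samples)
    ordered = sorted(
        sites, key=lambda s: (s.variant.chrom, s.variant.pos, s.variant.ref,
                              s.variant.alt)
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for site in ordered:
            extra = set(site.genotypes) - sample_set
            if extra:
                raise ConsistencyError(
                    f"site {site.variant.chrom}:{site.variant.pos} genotypes "
                    f"samples not in the sample list: {sorted(extra)}"
                )
            gts = "\t".join(_GT_OUT[site.genotype_of(s)] for s in samples)
            v = site.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# --- GFF3 -------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike) -> list[Transcript]:
    """Assemble one Transcript per mRNA from a gene/mRNA/CDS GFF3 subset.

    The gene symbol comes from the gene feature's Name attribute, falling
    back to its ID.  CDS rows are linked to their mRNA via Parent.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"cannot parse GFF3 file {path}: {exc}") from exc

    transcripts: list[Transcript] = []
    for mrna in db.features_of_type("mRNA", order_by="start"):
        parents = list(db.parents(mrna, featuretype="gene"))
        if not parents:
            raise FormatError(
                f"mRNA {mrna.id!r} has no gene parent in {path}"
            )
        gene = parents[0]
        symbol = gene.attributes.get("Name", [gene.id])[0]
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            raise ModelError(f"mRNA {mrna.id!r} has no CDS features")
        exons = tuple((c.start, c.end) for c in cds)
        transcripts.append(
            Transcript(
                id=mrna.id,
                gene_symbol=symbol,
                chrom=mrna.seqid,
                strand=mrna.strand,
                cds_exons=exons,
            )
        )
    # orphan CDS rows (Parent missing or dangling) are a linkage error
    for c in db.features_of_type("CDS"):
        if not list(db.parents(c, featuretype="mRNA")):
            raise FormatError(
                f"CDS feature at {c.seqid}:{c.start}-{c.end} has no mRNA "
                f"parent in {path}"
            )
    return transcripts


def write_gene_models(
    transcripts: Sequence[Transcript], path: str | os.PathLike
) -> None:
    """Write transcripts as a minimal gene/mRNA/CDS GFF3 file (one gene per
    transcript), stable for fixed input."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.cds_exons[0])):
            start = t.cds_exons[0][0]
            end = t.cds_exons[-1][1]
            gene_id = f"gene:{t.gene_symbol}"
            fh.write(
                f"{t.chrom}\tebfunnel\tgene\t{start}\t{end}\t.\t{t.strand}\t."
                f"\tID={gene_id};Name={t.gene_symbol}\n"
            )
            fh.write(
                f"{t.chrom}\tebfunnel\tmRNA\t{start}\t{end}\t.\t{t.strand}\t."
                f"\tID={t.id};Parent={gene_id}\n"
            )
            # phase = CDS bases of the codon left incomplete by prior exons
            exons = (
                t.cds_exons if t.strand == "+" else tuple(reversed(t.cds_exons))
            )
            consumed = 0
            phases = {}
            for s, e in exons:
                phases[(s, e)] = (3 - consumed % 3) % 3
                consumed += e - s + 1
            for i, (s, e) in enumerate(t.cds_exons, start=1):
                fh.write(
                    f"{t.chrom}\tebfunnel\tCDS\t{s}\t{e}\t.\t{t.strand}\t"
                    f"{phases[(s, e)]}\tID={t.id}.cds{i};Parent={t.id}\n"
                )


# --- PED --------------------------------------------------------------------

_SEX_IN = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_IN = {
    "2": Phenotype.AFFECTED,
    "1": Phenotype.UNAFFECTED,
    "0": Phenotype.UNKNOWN,
    "-9": Phenotype.UNKNOWN,
}
_PHENO_OUT = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNKNOWN: "0",
}


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a whitespace-separated 6-column PED file.

    Columns: family, id, sire, dam, sex (1=male, 2=female, 0=unknown),
    phenotype (2=affected, 1=unaffected, 0/-9=unknown).  "0" parents become
    absent.
    """
    individuals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 PED columns, got "
                    f"{len(fields)}"
                )
            _fam, ind_id, sire, dam, sex, pheno = fields
            if sex not in _SEX_IN:
                raise FormatError(f"{path}:{lineno}: bad sex code {sex!r}")
            if pheno not in _PHENO_IN:
                raise FormatError(
                    f"{path}:{lineno}: bad phenotype code {pheno!r}"
                )
            individuals.append(
                Individual(
                    id=ind_id,
                    sire=None if sire == "0" else sire,
                    dam=None if dam == "0" else dam,
                    sex=_SEX_IN[sex],
                    phenotype=_PHENO_IN[pheno],
                )
            )
    if not individuals:
        raise FormatError(f"{path}: PED file has no individuals")
    return Pedigree(individuals)


def write_pedigree(
    pedigree: Pedigree, path: str | os.PathLike, family: str = "FAM1"
) -> None:
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                "\t".join(
                    [
                        family,
                        ind.id,
                        ind.sire or "0",
                        ind.dam or "0",
                        _SEX_OUT[ind.sex],
                        _PHENO_OUT[ind.phenotype],
                    ]
                )
                + "\n"
            )


# --- gene panel -------------------------------------------------------------

def _parse_panel_text(text: str, source: str) -> set[str]:
    symbols = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.add(line)
    if not symbols:
        raise FormatError(f"panel {source} contains no gene symbols")
    return symbols


def read_panel(path: str | os.PathLike) -> set[str]:
    """Read a one-symbol-per-line gene panel; '#' comments and blank lines
    are ignored; symbols are deduplicated, case preserved.

    An empty effective panel is an error: a panel that silently matches
    nothing is almost certainly a user mistake.
    """
    with open(path) as fh:
        return _parse_panel_text(fh.read(), str(path))


def load_eb_panel() -> set[str]:
    """The built-in panel of 19 known epidermolysis bullosa genes."""
    from importlib.resources import files

    text = files("ebfunnel").joinpath("data/eb_panel.txt").read_text()
    return _parse_panel_text(text, "builtin:eb_panel")


def eb_panel_text() -> str:
    """Raw text of the built-in EB panel, for copying into datasets."""
    from importlib.resources import files

    return files("ebfunnel").joinpath("data/eb_panel.txt").read_text()


def write_panel(symbols: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for symbol in sorted(symbols):
            fh.write(symbol + "\n")


# --- cohort TSV -------------------------------------------------------------

_COHORT_HEADER = ["label", "n_total", "n_het", "n_hom_alt"]


def read_cohorts(path: str | os.PathLike) -> list[CohortCounts]:
    """Read a cohort genotype-count table (TSV with header
    ``label	n_total	n_het	n_hom_alt``)."""
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
    except Exception as exc:
        raise FormatError(f"cannot read cohort TSV {path}: {exc}") from exc
    if list(df.columns) != _COHORT_HEADER:
        raise FormatError(
            f"{path}: expected header {_COHORT_HEADER}, got {list(df.columns)}"
        )
    if df.empty:
        raise FormatError(f"{path}: cohort table has no rows")
    return [
        CohortCounts(
            label=row.label,
            n_total=int(row.n_total),
            n_het=int(row.n_het),
            n_hom_alt=int(row.n_hom_alt),
        )
        for row in df.itertuples()
    ]


def write_cohorts(
    cohorts: Sequence[CohortCounts], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COHORT_HEADER) + "\n")
        for c in cohorts:
            fh.write(f"{c.label}\t{c.n_total}\t{c.n_het}\t{c.n_hom_alt}\n")
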