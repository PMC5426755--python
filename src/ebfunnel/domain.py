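"""Core semantic types shared by every stage, plus genotype parsing and
multi-allelic normalization.

Coordinates are 1-based and fully closed throughout the package, matching
VCF POS.  Genotypes are unphased internally: phase separators are accepted
on parse and discarded, because nothing downstream uses phase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import (
    ConsistencyError,
    DomainError,
    GenotypeParseError,
    PloidyError,
)

_DNA = frozenset("ACGT")


class Genotype(Enum):
    """Diploid genotype state relative to a single alternate allele."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Sex(Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class Variant:
    """A normalized biallelic variant with 1-based genomic coordinates.

    ``ref`` and ``alt`` are non-empty uppercase DNA strings; single-base
    ref and alt of equal length 1 make a substitution, anything longer is
    carried as an indel (never classified as a substitution).
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DomainError(f"variant position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele:
                raise DomainError(f"{name} allele must be non-empty")
            if not set(allele) <= _DNA:
                raise DomainError(
                    f"{name} allele {allele!r} contains non-ACGT characters"
                )
        if self.ref == self.alt:
            raise DomainError(
                f"ref and alt alleles are identical ({self.ref!r}) at "
                f"{self.chrom}:{self.pos}"
            )

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class Site:
    """A variant together with the genotype of every sample at it."""

    variant: Variant
    genotypes: Mapping[str, Genotype]

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ConsistencyError(
                f"site {self.variant.chrom}:{self.variant.pos} has no samples"
            )
        object.__setattr__(self, "genotypes", dict(self.genotypes))

    def genotype_of(self, sample: str) -> Genotype:
        try:
            return self.genotypes[sample]
        except KeyError:
            raise ConsistencyError(
                f"sample {sample!r} not genotyped at "
                f"{self.variant.chrom}:{self.variant.pos}"
            ) from None


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``sire``/``dam`` are ids or None when unknown."""

    id: str
    sire: Optional[str] = None
    dam: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN


class Pedigree:
    """An ordered, acyclic collection of individuals with resolved parents."""

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = list(individuals)
        self._by_id = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ConsistencyError(f"duplicate individual id {ind.id!r}")
            self._by_id[ind.id] = ind
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None and parent not in self._by_id:
                    raise ConsistencyError(
                        f"parent {parent!r} of {ind.id!r} is not in the pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS with colouring; a back edge means someone is their own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i.id: WHITE for i in self.individuals}

        def visit(ind_id: str) -> None:
            colour[ind_id] = GREY
            ind = self._by_id[ind_id]
            for parent in (ind.sire, ind.dam):
                if parent is None:
                    continue
                if colour[parent] == GREY:
                    raise ConsistencyError(
                        f"cyclic parentage involving {parent!r}"
                    )
                if colour[parent] == WHITE:
                    visit(parent)
            colour[ind_id] = BLACK

        for ind in self.individuals:
            if colour[ind.id] == WHITE:
                visit(ind.id)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def offspring_of(self) -> Mapping[str, list]:
        """Map each parent id to the individuals it parented."""
        out: dict[str, list] = {}
        for ind in self.individuals:
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    out.setdefault(parent, []).append(ind)
        return out


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts for one screened cohort (e.g. a breed)."""

    label: str
    n_total: int
    n_het: int
    n_hom_alt: int = 0

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_het, self.n_hom_alt) < 0:
            raise DomainError(f"negative count in cohort {self.label!r}")
        if self.n_het + self.n_hom_alt > self.n_total:
            raise DomainError(
                f"cohort {self.label!r}: n_het + n_hom_alt exceeds n_total"
            )


# --- genotype parsing -------------------------------------------------------

_GT_RE = re.compile(r"^(\.|\d+)([/|])(\.|\d+)$")
_GT_SHAPE_RE = re.compile(r"^[\d.]+(?:[/|][\d.]+)*$")


def parse_genotype(gt_string: str) -> Genotype:
    """Parse a diploid VCF GT token into a :class:`Genotype` state.

    Phased ("0|1") and unphased ("0/1") separators are equivalent.  Any
    allele index greater than 1 raises: multi-allelic records must be split
    with :func:`split_multiallelic` first.  A token with any missing allele
    is MISSING.
    """
    m = _GT_RE.match(gt_string)
    if m is None:
        if _GT_SHAPE_RE.match(gt_string):
            n = len(re.split(r"[/|]", gt_string))
            if n != 2:
                raise PloidyError(
                    f"GT token {gt_string!r} has ploidy {n}; only diploid "
                    "genotypes are supported"
                )
        raise GenotypeParseError(f"malformed GT token {gt_string!r}")
    a, _, b = m.groups()
    if "." in (a, b):
        return Genotype.MISSING
    ia, ib = int(a), int(b)
    if max(ia, ib) > 1:
        raise GenotypeParseError(
            f"GT token {gt_string!r} uses allele index > 1; split "
            "multi-allelic records before parsing"
        )
    dosage = ia + ib
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[dosage]


def _recode_token(gt_string: str, target_allele: int) -> Genotype:
    """Genotype state of ``gt_string`` relative to one alt allele index.

    Non-target alt alleles count as non-target (ref-like), not missing: the
    recessive filter only asks about the target allele's dosage.
    """
    if not _GT_SHAPE_RE.match(gt_string):
        raise GenotypeParseError(f"malformed GT token {gt_string!r}")
    alleles = re.split(r"[/|]", gt_string)
    if len(alleles) != 2:
        raise PloidyError(
            f"GT token {gt_string!r} has ploidy {len(alleles)}; only diploid "
            "genotypes are supported"
        )
    if "." in alleles:
        return Genotype.MISSING
    dosage = sum(1 for a in alleles if int(a) == target_allele)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[dosage]


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    gt_tokens: Mapping[str, str],
) -> list[Site]:
    """Split a raw VCF record with k alt alleles into k biallelic Sites.

    Output order follows ALT order.  Per-sample genotypes are recoded
    relative to each alt in turn; see :func:`_recode_token` for how other
    alts are treated.  On a biallelic record this is content-equal to
    direct parsing.
    """
    if not alts:
        raise DomainError(f"record {chrom}:{pos} has no alt alleles")
    sites = []
    for i, alt in enumerate(alts, start=1):
        variant = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt)
        genotypes = {
            sample: _recode_token(tok, i) for sample, tok in gt_tokens.items()
        }
        sites.append(Site(variant=variant, genotypes=genotypes))
    return sites
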