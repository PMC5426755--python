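"""Pedigree segregation checking under a fully penetrant autosomal
recessive model.

"Complete segregation" means no individual violates any of four rules:

a. an affected individual is not HOM_ALT;
b. an unaffected individual is HOM_ALT (full penetrance is assumed — a
   tolerant mode is deliberately not provided, since the modelled disease
   manifests at birth);
c. a genotyped parent of an affected individual is HOM_REF (the
   obligate-carrier rule);
d. a Mendelian impossibility: offspring HOM_ALT with a HOM_REF parent, or
   offspring HOM_REF with a HOM_ALT parent.

Only genotyped individuals are constrained; unknown-phenotype individuals
take part in the Mendelian rule (d) but not the phenotype rules (a, b).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .domain import Genotype, Pedigree, Phenotype
from .errors import ConsistencyError, DomainError

_GENO_STATES = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)
_PHENO_STATES = (Phenotype.AFFECTED, Phenotype.UNAFFECTED, Phenotype.UNKNOWN)

RULES = {
    "a": "affected individual is not homozygous for the alt allele",
    "b": "unaffected individual is homozygous for the alt allele",
    "c": "parent of an affected individual is homozygous reference",
    "d": "genotype impossible given a parent's genotype",
}


@dataclass(frozen=True)
class SegregationReport:
    segregates: bool
    violations: tuple[tuple[str, str], ...]  # (individual id, rule key)
    counts: Mapping[Genotype, Mapping[Phenotype, int]]
    penetrance: Optional[float]

    def summary(self) -> str:
        lines = [f"segregates: {str(self.segregates).lower()}"]
        if self.penetrance is not None:
            lines.append(f"penetrance: {self.penetrance:.3f}")
        for ind, rule in self.violations:
            lines.append(f"violation\t{ind}\trule {rule}: {RULES[rule]}")
        return "\n".join(lines)


def check_recessive_segregation(
    pedigree: Pedigree, genotypes: Mapping[str, Genotype]
) -> SegregationReport:
    """Check complete segregation of a variant with the phenotype.

    ``genotypes`` maps individual ids to genotype states; individuals
    missing from the mapping (or MISSING) are untested and unconstrained,
    mirroring pedigrees where no sample was available for some members.
    """
    for ind_id in genotypes:
        if ind_id not in pedigree:
            raise ConsistencyError(
                f"genotype given for unknown individual {ind_id!r}"
            )

    def geno(ind_id: str) -> Optional[Genotype]:
        g = genotypes.get(ind_id)
        return None if g is Genotype.MISSING else g

    violations: list[tuple[str, str]] = []
    counts = {g: {p: 0 for p in _PHENO_STATES} for g in _GENO_STATES}

    for ind in pedigree:
        g = geno(ind.id)
        if g is not None:
            counts[g][ind.phenotype] += 1
            if ind.phenotype is Phenotype.AFFECTED and g is not Genotype.HOM_ALT:
                violations.append((ind.id, "a"))
            if ind.phenotype is Phenotype.UNAFFECTED and g is Genotype.HOM_ALT:
                violations.append((ind.id, "b"))
        for parent_id in (ind.sire, ind.dam):
            if parent_id is None:
                continue
            pg = geno(parent_id)
            if pg is None:
                continue
            if ind.phenotype is Phenotype.AFFECTED and pg is Genotype.HOM_REF:
                violations.append((parent_id, "c"))
            if g is not None:
                impossible = (
                    g is Genotype.HOM_ALT and pg is Genotype.HOM_REF
                ) or (g is Genotype.HOM_REF and pg is Genotype.HOM_ALT)
                if impossible:
                    violations.append((ind.id, "d"))

    hom_alt_known = sum(
        counts[Genotype.HOM_ALT][p]
        for p in (Phenotype.AFFECTED, Phenotype.UNAFFECTED)
    )
    penetrance = (
        counts[Genotype.HOM_ALT][Phenotype.AFFECTED] / hom_alt_known
        if hom_alt_known
        else None
    )
    violations = tuple(dict.fromkeys(violations))  # dedupe, keep order
    return SegregationReport(
        segregates=not violations,
        violations=violations,
        counts=counts,
        penetrance=penetrance,
    )


def expected_offspring_distribution(
    sire_genotype: Genotype, dam_genotype: Genotype
) -> tuple[float, float, float]:
    """Mendelian offspring genotype probabilities (HOM_REF, HET, HOM_ALT)
    from two parental genotypes, by gamete union."""
    alt_gamete_p = {
        Genotype.HOM_REF: 0.0,
        Genotype.HET: 0.5,
        Genotype.HOM_ALT: 1.0,
    }
    for g in (sire_genotype, dam_genotype):
        if g not in alt_gamete_p:
            raise DomainError(
                f"parental genotype must be observed, got {g}"
            )
    p, q = alt_gamete_p[sire_genotype], alt_gamete_p[dam_genotype]
    hom_alt = p * q
    hom_ref = (1 - p) * (1 - q)
    het = 1 - hom_alt - hom_ref
    return (hom_ref, het, hom_alt)


def write_segregation_tsv(report: SegregationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"segregates\t{str(report.segregates).lower()}\n")
        fh.write(
            "penetrance\t"
            + ("." if report.penetrance is None else f"{report.penetrance:.6g}")
            + "\n"
        )
        for g in _GENO_STATES:
            for p in _PHENO_STATES:
                fh.write(f"count_{g.value}_{p.value}\t{report.counts[g][p]}\n")
        for ind, rule in report.violations:
            fh.write(f"violation\t{ind}\t{rule}\n")
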