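"""The staged filtering funnel: from all called variants in the case genome
to candidate causal variants under a recessive model.

Stage order is fixed: total -> case_homozygous -> control_exclusion ->
coding -> panel.  Counts are recorded after each stage and are monotonically
non-increasing.  "Total" is counted after multi-allelic splitting, so it can
exceed the raw VCF record count.

Control policies reflect the recessive model: by default a site survives
unless some control is homozygous for the same alt allele — unaffected
carriers are permitted, as expected for a recessive disease allele
segregating in a population.  The strict policy additionally excludes sites
where any control carries the allele at all, appropriate when controls are
drawn from breeds where carriers are implausible.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

from .consequence import (
    ConsequenceAnnotation,
    annotate_variant,
    best_annotation,
)
from .domain import Genotype, Site, Variant
from .errors import DomainError
from .io_formats import GenomeSequence, Transcript

PROTEIN_ALTERING = frozenset(
    {"missense", "nonsense", "stop_lost", "start_lost", "coding_other"}
)

STAGE_NAMES = ("total", "case_homozygous", "control_exclusion", "coding", "panel")


class ControlPolicy(Enum):
    #: remove a site iff >= 1 control is HOM_ALT for the same alt allele
    EXCLUDE_IF_ANY_CONTROL_HOM_ALT = "exclude_if_any_control_hom_alt"
    #: remove a site iff >= 1 control carries the alt allele at all
    EXCLUDE_IF_ANY_CONTROL_HAS_ALT = "exclude_if_any_control_has_alt"


class CodingScope(Enum):
    #: keep any variant overlapping a CDS, synonymous included
    ANY_CDS_OVERLAP = "any_cds_overlap"
    #: additionally require a protein-altering best effect
    PROTEIN_ALTERING_ONLY = "protein_altering_only"


@dataclass
class FilterConfig:
    case_sample: str
    control_samples: Sequence[str] = ()
    control_policy: ControlPolicy = ControlPolicy.EXCLUDE_IF_ANY_CONTROL_HOM_ALT
    coding_scope: CodingScope = CodingScope.ANY_CDS_OVERLAP
    panel: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        self.control_samples = tuple(self.control_samples)
        if self.case_sample in self.control_samples:
            raise DomainError(
                f"case sample {self.case_sample!r} also listed as a control"
            )
        if self.panel is not None:
            self.panel = frozenset(self.panel)
            if not self.panel:
                raise DomainError("panel, when given, must be non-empty")


@dataclass(frozen=True)
class Candidate:
    variant: Variant
    annotation: ConsequenceAnnotation
    gene_symbol: str


@dataclass(frozen=True)
class FilterFunnelReport:
    """Ordered per-stage survivor counts plus the final candidate list."""

    stages: tuple[tuple[str, int], ...]
    candidates: tuple[Candidate, ...]

    def count(self, stage: str) -> int:
        for name, n in self.stages:
            if name == stage:
                return n
        raise KeyError(stage)


GenotypeLookup = Callable[[str, Site], Genotype]


def _site_lookup(control: str, site: Site) -> Genotype:
    return site.genotype_of(control)


def stage_case_homozygous(sites: Iterable[Site], case_sample: str) -> list[Site]:
    """Keep sites where the case is homozygous for the alt allele.

    HET is excluded by the recessive model; MISSING is excluded
    conservatively — the model demands an observed homozygote.
    """
    out = []
    for site in sites:
        if site.genotype_of(case_sample) is Genotype.HOM_ALT:
            out.append(site)
    return out


def stage_control_exclusion(
    sites: Iterable[Site],
    control_samples: Sequence[str],
    policy: ControlPolicy = ControlPolicy.EXCLUDE_IF_ANY_CONTROL_HOM_ALT,
    lookup: GenotypeLookup = _site_lookup,
) -> list[Site]:
    """Remove sites where control genotypes contradict the recessive model.

    A MISSING control genotype never excludes: absence of evidence is not a
    reference call.
    """
    if policy is ControlPolicy.EXCLUDE_IF_ANY_CONTROL_HOM_ALT:
        excluding = (Genotype.HOM_ALT,)
    else:
        excluding = (Genotype.HOM_ALT, Genotype.HET)
    out = []
    for site in sites:
        if not any(
            lookup(control, site) in excluding for control in control_samples
        ):
            out.append(site)
    return out


def stage_coding(
    sites: Iterable[Site],
    transcripts: Sequence[Transcript],
    genome: GenomeSequence,
    scope: CodingScope = CodingScope.ANY_CDS_OVERLAP,
) -> list[tuple[Site, list[ConsequenceAnnotation]]]:
    """Annotate and keep coding sites.

    Under ``ANY_CDS_OVERLAP`` any site with at least one CDS annotation
    survives; under ``PROTEIN_ALTERING_ONLY`` the best (most severe) effect
    must alter the protein.
    """
    out = []
    for site in sites:
        annotations = annotate_variant(site.variant, transcripts, genome)
        if not annotations:
            continue
        if scope is CodingScope.PROTEIN_ALTERING_ONLY:
            best = best_annotation(annotations)
            if best.effect not in PROTEIN_ALTERING:
                continue
        out.append((site, annotations))
    return out


def stage_panel(
    pairs: Iterable[tuple[Site, list[ConsequenceAnnotation]]],
    panel: frozenset[str],
) -> list[tuple[Site, list[ConsequenceAnnotation]]]:
    """Keep sites whose best annotation's gene symbol is on the panel
    (exact string match)."""
    out = []
    for site, annotations in pairs:
        if any(a.gene_symbol in panel for a in annotations):
            out.append((site, annotations))
    return out


def run_funnel(
    sites: Sequence[Site],
    config: FilterConfig,
    transcripts: Sequence[Transcript],
    genome: GenomeSequence,
) -> FilterFunnelReport:
    """Run the full funnel and report per-stage survivor counts.

    The panel stage runs only when ``config.panel`` is set; otherwise it is
    recorded with the same count as the coding stage (stage skipped, all
    kept).
    """
    stages: list[tuple[str, int]] = [("total", len(sites))]

    surviving = stage_case_homozygous(sites, config.case_sample)
    stages.append(("case_homozygous", len(surviving)))

    if config.control_samples:
        surviving = stage_control_exclusion(
            surviving, config.control_samples, config.control_policy
        )
    stages.append(("control_exclusion", len(surviving)))

    pairs = stage_coding(surviving, transcripts, genome, config.coding_scope)
    stages.append(("coding", len(pairs)))

    if config.panel is not None:
        pairs = stage_panel(pairs, config.panel)
    stages.append(("panel", len(pairs)))

    candidates = []
    for site, annotations in pairs:
        if config.panel is not None:
            annotations = [a for a in annotations if a.gene_symbol in config.panel]
        best = best_annotation(annotations)
        candidates.append(
            Candidate(
                variant=site.variant,
                annotation=best,
                gene_symbol=best.gene_symbol,
            )
        )
    return FilterFunnelReport(stages=tuple(stages), candidates=tuple(candidates))


# --- report serialization ---------------------------------------------------

def write_funnel_tsv(report: FilterFunnelReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tsurviving\n")
        for name, n in report.stages:
            fh.write(f"{name}\t{n}\n")


def write_candidates_tsv(report: FilterFunnelReport, path) -> None:
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "transcript", "effect",
        "hgvs_c", "hgvs_p",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for cand in report.candidates:
            v, a = cand.variant, cand.annotation
            fh.write(
                "\t".join(
                    [
                        v.chrom, str(v.pos), v.ref, v.alt, cand.gene_symbol,
                        a.transcript_id, a.effect, a.hgvs_c or ".",
                        a.hgvs_p or ".",
                    ]
                )
                + "\n"
            )
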