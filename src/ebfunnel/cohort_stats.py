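"""Cohort screening statistics: carrier and allele frequencies with Wilson
score intervals, Hardy-Weinberg expectations, and a multi-breed specificity
summary.

"Carrier" means heterozygote only: affected homozygotes are tallied
separately from carriers, so a cohort of 47 dogs with 13 heterozygotes has
a carrier frequency of 13/47 = 27.7% regardless of how many homozygotes it
contains.  Wilson (not Wald) intervals are used because they behave well at
zero successes — the typical situation in unaffected related breeds.  No
hypothesis tests are performed; only Hardy-Weinberg expectations are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

from .domain import CohortCounts
from .errors import ConsistencyError, DomainError


@dataclass(frozen=True)
class CohortSummary:
    label: str
    n_total: int
    n_het: int
    n_hom_alt: int
    carrier_frequency: float
    carrier_percent: str
    allele_frequency: float
    carrier_ci: tuple[float, float]
    hwe_expected_hom_alt: float


@dataclass(frozen=True)
class ScreenResult:
    cohorts: tuple[CohortSummary, ...]
    index_label: str
    non_index_total: int
    breed_specific: bool

    @property
    def verdict(self) -> str:
        return "breed-specific" if self.breed_specific else "not breed-specific"


def percent_string(proportion: float) -> str:
    """Render a proportion as a percentage with one decimal, rounding half
    away from zero (0.27659... -> "27.7%")."""
    quantized = Decimal(repr(proportion * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{quantized}%"


def carrier_frequency(counts: CohortCounts) -> tuple[float, str]:
    """Heterozygote fraction of the genotyped cohort, as a proportion and a
    one-decimal percent string."""
    if counts.n_total == 0:
        raise DomainError(
            f"cohort {counts.label!r} has no genotyped individuals"
        )
    p = counts.n_het / counts.n_total
    return p, percent_string(p)


def allele_frequency(counts: CohortCounts) -> float:
    """Alt-allele fraction: (het + 2 * hom_alt) / (2 * total)."""
    if counts.n_total == 0:
        raise DomainError(
            f"cohort {counts.label!r} has no genotyped individuals"
        )
    return (counts.n_het + 2 * counts.n_hom_alt) / (2 * counts.n_total)


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1].

    The lower bound is exactly 0 at zero successes and the upper bound
    exactly 1 at n successes.
    """
    if n <= 0 or not 0 <= successes <= n:
        raise DomainError(f"invalid counts: {successes} successes out of {n}")
    lower, upper = proportion_confint(
        successes, n, alpha=1 - confidence, method="wilson"
    )
    # at 0 (or n) successes the bound is exactly 0 (or 1) in closed form;
    # clamp away the floating-point residue of the generic evaluation
    lower = 0.0 if successes == 0 else max(0.0, float(lower))
    upper = 1.0 if successes == n else min(1.0, float(upper))
    return lower, upper


def summarize_cohort(counts: CohortCounts) -> CohortSummary:
    p, percent = carrier_frequency(counts)
    q = allele_frequency(counts)
    return CohortSummary(
        label=counts.label,
        n_total=counts.n_total,
        n_het=counts.n_het,
        n_hom_alt=counts.n_hom_alt,
        carrier_frequency=p,
        carrier_percent=percent,
        allele_frequency=q,
        carrier_ci=wilson_interval(counts.n_het, counts.n_total),
        hwe_expected_hom_alt=q * q,
    )


def screen_summary(
    cohorts: Sequence[CohortCounts], index_label: str
) -> ScreenResult:
    """Summarize a multi-cohort screen around one index cohort.

    The verdict is "breed-specific" iff every non-index cohort is free of
    the allele (no heterozygotes, no homozygotes); a single-cohort screen is
    vacuously breed-specific.
    """
    labels = [c.label for c in cohorts]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ConsistencyError(f"duplicate cohort labels: {dupes}")
    if index_label not in labels:
        raise ConsistencyError(
            f"index cohort {index_label!r} not among {labels}"
        )
    summaries = tuple(summarize_cohort(c) for c in cohorts)
    non_index = [c for c in cohorts if c.label != index_label]
    return ScreenResult(
        cohorts=summaries,
        index_label=index_label,
        non_index_total=sum(c.n_total for c in non_index),
        breed_specific=all(
            c.n_het == 0 and c.n_hom_alt == 0 for c in non_index
        ),
    )


def write_screen_tsv(result: ScreenResult, path) -> None:
    cols = [
        "label", "n_total", "n_het", "n_hom_alt", "carrier_frequency",
        "carrier_percent", "carrier_ci_low", "carrier_ci_high",
        "allele_frequency", "hwe_expected_hom_alt",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in result.cohorts:
            fh.write(
                "\t".join(
                    [
                        c.label, str(c.n_total), str(c.n_het),
                        str(c.n_hom_alt), f"{c.carrier_frequency:.6g}",
                        c.carrier_percent, f"{c.carrier_ci[0]:.6g}",
                        f"{c.carrier_ci[1]:.6g}", f"{c.allele_frequency:.6g}",
                        f"{c.hwe_expected_hom_alt:.6g}",
                    ]
                )
                + "\n"
            )
        fh.write(
            f"# verdict: {result.verdict}; non-index total "
            f"{result.non_index_total}\n"
        )
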