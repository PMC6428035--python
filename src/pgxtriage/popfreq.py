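"""Cohort allele frequencies, carrier statistics, and per-gene CADD summaries.

The cohort alt-allele frequency ("MAF" by the field's loose convention) is
(het + 2*hom) / (2*N) with N the fixed cohort size — every sample contributes
two alleles to the denominator regardless of per-site call rate. Frequencies
are *not* folded to <= 0.5: for several pharmacogenetic variants the alternate
allele is the major one and the reported frequency exceeds 50%.

Reporting conventions: frequencies are rounded to 3 significant figures,
carrier fractions to integer percent in narrative output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from statistics import median
from typing import Optional

from .model import AnnotatedVariant, CohortGenotypeSummary

log = logging.getLogger(__name__)


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


def cohort_maf(summary: CohortGenotypeSummary) -> Fraction:
    """Exact alt-allele frequency (het + 2*hom) / (2*n) as a rational number.

    Round with :func:`round_sig` only at the reporting boundary.
    """
    return Fraction(summary.het_count + 2 * summary.hom_count, 2 * summary.n_samples)


def carrier_fraction(summary: CohortGenotypeSummary) -> Fraction:
    """Fraction of samples carrying at least one alternate allele."""
    return Fraction(summary.het_count + summary.hom_count, summary.n_samples)


def het_hom_fractions(summary: CohortGenotypeSummary) -> tuple[Fraction, Fraction]:
    """Separate het-carrier and hom-carrier fractions, for narrative text."""
    n = summary.n_samples
    return Fraction(summary.het_count, n), Fraction(summary.hom_count, n)


def percent(fraction) -> int:
    """Integer-percent rendering used in narrative output (half-up)."""
    return int(Fraction(fraction) * 100 + Fraction(1, 2))


@dataclass(frozen=True)
class FrequencyRecord:
    variant_key: object
    maf_cohort: float
    maf_reference: Optional[float]
    het_count: int
    hom_count: int
    n_samples: int
    carrier_fraction: float

    @classmethod
    def from_summary(
        cls, summary: CohortGenotypeSummary, maf_reference: Optional[float] = None
    ) -> "FrequencyRecord":
        return cls(
            variant_key=summary.variant_key,
            maf_cohort=float(cohort_maf(summary)),
            maf_reference=maf_reference,
            het_count=summary.het_count,
            hom_count=summary.hom_count,
            n_samples=summary.n_samples,
            carrier_fraction=float(carrier_fraction(summary)),
        )


@dataclass(frozen=True)
class Discordance:
    """Cohort-vs-reference frequency comparison for one variant."""

    variant_key: object
    abs_difference: float
    ratio: Optional[float]  # cohort / reference; None when reference is 0
    flagged: bool


def compare_to_reference(record: FrequencyRecord, flag_threshold: float = 0.03):
    """Absolute difference and ratio of cohort vs reference frequency.

    Records whose absolute difference exceeds ``flag_threshold`` (default
    0.03, the scale of known cross-database discrepancies for common
    pharmacogenetic variants) are flagged. Returns ``None`` (with a logged
    notice) when the variant has no reference frequency.
    """
    if record.maf_reference is None:
        log.info("no reference frequency for %s; comparison skipped", record.variant_key)
        return None
    diff = abs(record.maf_cohort - record.maf_reference)
    ratio = record.maf_cohort / record.maf_reference if record.maf_reference > 0 else None
    return Discordance(
        variant_key=record.variant_key,
        abs_difference=diff,
        ratio=ratio,
        flagged=diff > flag_threshold,
    )


@dataclass(frozen=True)
class GeneCaddSummary:
    gene: str
    median_cadd_rare: Optional[float]
    median_cadd_common: Optional[float]
    n_rare: int
    n_common: int


def median_cadd_by_gene(variants: list) -> list:
    """Per-gene median CADD Phred, separately for rare and common variants.

    ``variants`` is a list of ``(AnnotatedVariant, rare: bool)`` pairs.
    Medians run over scored variants only (an even-length list takes the
    midpoint mean); a gene with no scored variants in a stratum carries an
    absent median. Output is sorted by gene symbol.
    """
    by_gene: dict[str, dict[bool, list]] = {}
    counts: dict[str, dict[bool, int]] = {}
    for variant, rare in variants:
        scores = by_gene.setdefault(variant.gene, {True: [], False: []})
        tally = counts.setdefault(variant.gene, {True: 0, False: 0})
        tally[bool(rare)] += 1
        if variant.cadd_phred is not None:
            scores[bool(rare)].append(variant.cadd_phred)
    out = []
    for gene in sorted(by_gene):
        rare_scores, common_scores = by_gene[gene][True], by_gene[gene][False]
        out.append(
            GeneCaddSummary(
                gene=gene,
                median_cadd_rare=median(rare_scores) if rare_scores else None,
                median_cadd_common=median(common_scores) if common_scores else None,
                n_rare=counts[gene][True],
                n_common=counts[gene][False],
            )
        )
    return out
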