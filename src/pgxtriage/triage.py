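"""The variant triage cascade.

Each variant is classified along independent axes:

* **rarity** — gnomAD allele frequency at most 1% (absence from gnomAD counts
  as rare) AND at most 19 heterozygous AND at most 15 homozygous carriers in
  the cohort (19/1904 ~ 1%);
* **actionability** — PharmGKB evidence tiers attached to the rsID, and the
  ClinVar drug-response code;
* **consensus pathogenic missense** — all four predictors (SIFT, PolyPhen-2,
  MutationTaster, MetaSVM) call damaging and CADD Phred strictly above 20
  (the top-1% deleteriousness percentile); an unknown predictor call breaks
  the consensus;
* **protein truncation** — frameshift, stop gain/lost, start lost, or an
  essential splice-site change (splice_region alone does not qualify);
* **novelty** — presence in gnomAD, else dbSNP, else ClinVar, else novel
  (fixed precedence, so the categories partition any variant set);
* **gene superfamily** — CYP / ABC / SLC (incl. SLCO) / UGT by symbol prefix.

:func:`cascade_counts` tabulates these axes into the standard category-by-
membership count matrix for a cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .knowledgebase import ACTIONABLE_LEVELS, KnowledgeBase, has_drug_response_code
from .model import (
    TRUNCATING_EFFECTS,
    AnnotatedVariant,
    CohortGenotypeSummary,
    Effect,
    PredictorCall,
)


class Novelty(str, enum.Enum):
    in_gnomad = "in_gnomad"
    in_dbsnp = "in_dbsnp"
    in_clinvar = "in_clinvar"
    novel = "novel"


class GeneGroup(str, enum.Enum):
    CYP = "CYP"
    ABC = "ABC"
    SLC = "SLC"
    UGT = "UGT"
    other = "other"


@dataclass(frozen=True)
class RarityThresholds:
    """Defaults follow the 1%-of-cohort convention for N = 1904 samples."""

    max_gnomad_af: float = 0.01
    max_het: int = 19
    max_hom: int = 15

    def __post_init__(self):
        if self.max_gnomad_af < 0 or self.max_het < 0 or self.max_hom < 0:
            raise ValueError("rarity thresholds must be nonnegative")


@dataclass(frozen=True)
class TriageResult:
    variant_key: object
    is_rare: bool
    actionability: frozenset  # of (level, drugs-tuple)
    clinvar_drug_response: bool
    consensus_missense: bool
    truncating: bool
    novelty: Novelty
    gene_group: GeneGroup


def is_rare(
    variant: AnnotatedVariant,
    summary: CohortGenotypeSummary,
    thresholds: RarityThresholds = RarityThresholds(),
) -> bool:
    """Rare = (not in gnomAD, or gnomAD AF <= max) and few cohort carriers."""
    if isinstance(summary.variant_key, tuple) and summary.variant_key != variant.key:
        raise ValueError(
            f"summary key {summary.variant_key} does not match variant {variant.key}"
        )
    af_ok = variant.gnomad_af is None or variant.gnomad_af <= thresholds.max_gnomad_af
    return af_ok and summary.het_count <= thresholds.max_het and summary.hom_count <= thresholds.max_hom


def consensus_pathogenic_missense(variant: AnnotatedVariant) -> bool:
    """Missense with four damaging predictor calls and CADD Phred > 20.

    The CADD cutoff is strict; a missing score or any non-damaging
    (including unknown) predictor call fails the consensus.
    """
    if variant.effect is not Effect.missense:
        return False
    if any(c is not PredictorCall.damaging for c in variant.predictor_calls.values()):
        return False
    return variant.cadd_phred is not None and variant.cadd_phred > 20.0


def is_truncating(variant: AnnotatedVariant) -> bool:
    """Protein-truncating: frameshift, stop gain/lost, start lost, or an
    essential splice-site (acceptor/donor) change."""
    return variant.effect in TRUNCATING_EFFECTS


def novelty_category(variant: AnnotatedVariant) -> Novelty:
    if variant.gnomad_af is not None:
        return Novelty.in_gnomad
    if variant.rsid is not None:
        return Novelty.in_dbsnp
    if variant.clinvar_codes is not None:
        return Novelty.in_clinvar
    return Novelty.novel


def gene_group(gene: str) -> GeneGroup:
    g = gene.upper()
    for prefix in ("CYP", "ABC", "SLC", "UGT"):
        if g.startswith(prefix):
            return GeneGroup(prefix)
    return GeneGroup.other


def triage_variant(
    variant: AnnotatedVariant,
    summary: CohortGenotypeSummary,
    thresholds: RarityThresholds = RarityThresholds(),
    kb: KnowledgeBase = None,
) -> TriageResult:
    actionability = kb.lookup_actionability(variant.rsid) if kb is not None else set()
    return TriageResult(
        variant_key=variant.key,
        is_rare=is_rare(variant, summary, thresholds),
        actionability=frozenset(actionability),
        clinvar_drug_response=has_drug_response_code(variant.clinvar_codes),
        consensus_missense=consensus_pathogenic_missense(variant),
        truncating=is_truncating(variant),
        novelty=novelty_category(variant),
        gene_group=gene_group(variant.gene),
    )


# ---------------------------------------------------------------------------
# Category-by-membership count matrix


#: Effect classes broken out as their own rare-variant rows.
EFFECT_ROWS = (
    Effect.intronic,
    Effect.upstream,
    Effect.downstream,
    Effect.utr3,
    Effect.utr5,
    Effect.missense,
    Effect.frameshift,
    Effect.synonymous,
    Effect.splice_acceptor,
    Effect.splice_donor,
    Effect.stop_gain,
    Effect.splice_region,
)

#: Fixed row order of the cascade matrix.
CASCADE_CATEGORIES = (
    ("all", "All variants"),
    ("rare", "Rare variants"),
    *((f"rare_{e.value}", f"{e.value.replace('_', ' ').capitalize()} rare") for e in EFFECT_ROWS),
    ("rare_cadd_gt20", "Rare CADD > 20"),
    ("rare_consensus_missense", "Missense rare 4xD + CADD > 20"),
    ("rare_truncating", "HIGH impact rare (truncating variants)"),
    ("clinvar6_all", "ClinVar at least one 6 (all)"),
    ("clinvar6_rare", "ClinVar at least one 6 (rare)"),
    ("level_1a1b_all", "PharmGKB Level 1A/1B (all)"),
    ("level_1a1b_rare", "PharmGKB Level 1A/1B (rare)"),
    ("level_2a2b_all", "PharmGKB Level 2A/2B (all)"),
    ("level_2a2b_rare", "PharmGKB Level 2A/2B (rare)"),
)

#: Column order: cohort total, non-exclusive database memberships, and the
#: exclusive "novel" category (absent everywhere).
CASCADE_COLUMNS = ("cohort_total", "in_gnomad", "in_dbsnp", "in_clinvar", "novel")


def _in_category(category: str, result: TriageResult, variant: AnnotatedVariant) -> bool:
    if category == "all":
        return True
    if category == "rare":
        return result.is_rare
    if category.startswith("rare_"):
        tail = category[len("rare_"):]
        if tail == "cadd_gt20":
            return result.is_rare and variant.cadd_phred is not None and variant.cadd_phred > 20.0
        if tail == "consensus_missense":
            return result.is_rare and result.consensus_missense
        if tail == "truncating":
            return result.is_rare and result.truncating
        return result.is_rare and variant.effect is Effect(tail)
    levels = {level for level, _ in result.actionability}
    if category.startswith("clinvar6"):
        member = result.clinvar_drug_response
    elif category.startswith("level_1a1b"):
        member = bool(levels & {"1A", "1B"})
    elif category.startswith("level_2a2b"):
        member = bool(levels & {"2A", "2B"})
    else:
        raise ValueError(f"unknown cascade category {category!r}")
    return member and (result.is_rare if category.endswith("_rare") else True)


@dataclass
class CascadeCounts:
    """Count matrix: cascade category rows x database-membership columns.

    The membership columns ``in_gnomad``/``in_dbsnp``/``in_clinvar`` are
    *non-exclusive* (a variant may sit in all three); ``novel`` is the
    exclusive remainder (absent from all databases). Every cell is bounded
    by its row's ``cohort_total``.
    """

    matrix: dict = field(default_factory=dict)  # (category, column) -> int

    def __getitem__(self, key):
        return self.matrix[key]

    def row(self, category: str) -> dict:
        return {col: self.matrix[(category, col)] for col in CASCADE_COLUMNS}


def cascade_counts(results: list) -> CascadeCounts:
    """Tabulate ``(TriageResult, AnnotatedVariant)`` pairs into the matrix."""
    if not results:
        raise ValueError("cascade_counts requires a nonempty input")
    matrix = {
        (category, col): 0 for category, _ in CASCADE_CATEGORIES for col in CASCADE_COLUMNS
    }
    for result, variant in results:
        membership = {
            "cohort_total": True,
            "in_gnomad": variant.gnomad_af is not None,
            "in_dbsnp": variant.rsid is not None,
            "in_clinvar": variant.clinvar_codes is not None,
            "novel": result.novelty is Novelty.novel,
        }
        for category, _ in CASCADE_CATEGORIES:
            if _in_category(category, result, variant):
                for col in CASCADE_COLUMNS:
                    if membership[col]:
                        matrix[(category, col)] += 1
    return CascadeCounts(matrix=matrix)


def novelty_partition(results: list) -> dict:
    """Exclusive novelty-category counts (sums to the number of variants)."""
    counts = {n: 0 for n in Novelty}
    for result, _ in results:
        counts[result.novelty] += 1
    return counts
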