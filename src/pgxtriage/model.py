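"""Core domain types for pharmacogenetic variant triage.

The unit of analysis is a single alternate allele at a single site
(multi-allelic VCF records are split upstream), carrying the annotation
fields the triage cascade consumes: effect/impact class, reference
population frequency (gnomAD), four in-silico pathogenicity predictor
calls, CADD Phred and GERP++ RS scores, ClinVar significance codes, and
per-site sequencing depth and quality. Cohort genotype evidence for the
same allele is held separately as het/hom carrier counts over a fixed
number of diploid samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Effect(str, enum.Enum):
    """Variant effect class (snpEff-style sequence-ontology buckets)."""

    missense = "missense"
    synonymous = "synonymous"
    frameshift = "frameshift"
    stop_gain = "stop_gain"
    stop_lost = "stop_lost"
    start_lost = "start_lost"
    splice_acceptor = "splice_acceptor"
    splice_donor = "splice_donor"
    splice_region = "splice_region"
    inframe_deletion = "inframe_deletion"
    intronic = "intronic"
    utr5 = "utr5"
    utr3 = "utr3"
    upstream = "upstream"
    downstream = "downstream"
    other = "other"


class Impact(str, enum.Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


class PredictorCall(str, enum.Enum):
    damaging = "damaging"
    tolerated = "tolerated"
    unknown = "unknown"


#: The four missense predictors entering the consensus rule.
PREDICTORS = ("SIFT", "PolyPhen2", "MutationTaster", "MetaSVM")

#: Effect classes expected to abolish the protein product (HIGH impact).
TRUNCATING_EFFECTS = frozenset(
    {
        Effect.frameshift,
        Effect.stop_gain,
        Effect.stop_lost,
        Effect.start_lost,
        Effect.splice_acceptor,
        Effect.splice_donor,
    }
)


def harmonize_predictor_call(raw: Optional[str]) -> PredictorCall:
    """Map heterogeneous predictor output tokens onto damaging/tolerated/unknown.

    dbNSFP-style letter codes differ per tool (SIFT "D"/"T", PolyPhen-2
    "probably_damaging", MutationTaster "A"/"D"/"N"/"P", MetaSVM "D"/"T");
    anything unrecognized, empty or missing maps to ``unknown``, never to a
    damaging or tolerated call.
    """
    if raw is None:
        return PredictorCall.unknown
    token = str(raw).strip().lower().replace(" ", "_")
    if token in {
        "d",
        "damaging",
        "deleterious",
        "probably_damaging",
        "possibly_damaging",
        "disease_causing",
        "disease_causing_automatic",
        "a",
    }:
        return PredictorCall.damaging
    if token in {"t", "tolerated", "benign", "polymorphism", "polymorphism_automatic", "n", "p"}:
        return PredictorCall.tolerated
    return PredictorCall.unknown


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele at one site with its annotations.

    ``gnomad_af`` is ``None`` when the allele is absent from gnomAD (which
    is information, not zero); the same convention holds for every optional
    field. ``predictor_calls`` always carries all four predictor keys.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: str
    effect: Effect
    impact: Impact
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    rsid: Optional[str] = None
    gnomad_af: Optional[float] = None
    predictor_calls: dict = field(default_factory=dict)
    cadd_phred: Optional[float] = None
    gerp_rs: Optional[float] = None
    clinvar_codes: Optional[frozenset] = None
    site_depth: int = 0
    site_quality: float = 0.0

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be nonnegative: {self.cadd_phred}")
        if self.site_depth < 0 or self.site_quality < 0:
            raise ValueError("site depth and quality must be nonnegative")
        calls = {p: PredictorCall(self.predictor_calls.get(p, PredictorCall.unknown)) for p in PREDICTORS}
        object.__setattr__(self, "predictor_calls", calls)
        if self.clinvar_codes is not None:
            object.__setattr__(self, "clinvar_codes", frozenset(int(c) for c in self.clinvar_codes))

    def __hash__(self):
        # predictor_calls is a dict (unhashable); hash on the stable identity
        return hash((self.contig, self.position, self.ref_allele, self.alt_allele, self.gene))

    @property
    def key(self) -> tuple:
        return (self.contig, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class CohortGenotypeSummary:
    """Het/hom-alt carrier counts for one alternate allele over a cohort.

    ``n_samples`` is the fixed cohort size (every sample contributes two
    alleles to the frequency denominator regardless of per-site call rate);
    hemizygous calls count as homozygous-alternate.
    """

    variant_key: object
    het_count: int
    hom_count: int
    n_samples: int

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.het_count < 0 or self.hom_count < 0:
            raise ValueError("carrier counts must be nonnegative")
        if self.het_count + self.hom_count > self.n_samples:
            raise ValueError("het + hom carriers exceed cohort size")
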