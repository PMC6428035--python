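"""Synthetic cohorts with known truth, so every pipeline stage runs offline.

Three generators:

* :func:`generate_cohort` — a multi-sample VCF plus annotation and truth
  tables for a cohort of N diploid samples. Genotypes are drawn i.i.d. per
  sample under Hardy-Weinberg proportions (hom-ref (1-p)^2, het 2p(1-p),
  hom-alt p^2) at each variant's true allele frequency; no linkage or
  relatedness is modelled (the triage cascade is single-site).

* :func:`generate_rare_spectrum` — a labelled rare-variant annotation set
  whose triage class (consensus-pathogenic missense, protein-truncating,
  neutral; novel or known) is fixed by construction, for exact
  truth-recovery tests. CADD scores for deleterious classes are drawn
  uniformly on (20, 50] and for neutral classes on [0, 15]; the gap keeps
  class labels away from the decision boundary.

* :func:`actionable_fixture` — the bundled actionable-variant fixture (packaged
  data, not simulated): 24 level-1A/1B variants with published carrier
  counts over N = 1904 samples, the matching clinical-annotation and
  star-allele tables, and the published cohort frequencies.

All randomness flows through one ``numpy.random.Generator`` seeded from the
spec; a fixed seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .knowledgebase import KnowledgeBase, load_clinical_annotations, load_star_alleles
from .model import (
    PREDICTORS,
    AnnotatedVariant,
    CohortGenotypeSummary,
    Effect,
    Impact,
)
from .variant_io import write_annotation_tsv

_DEFAULT_N_SAMPLES = 1904

_NEUTRAL_EFFECTS = (Effect.synonymous, Effect.intronic, Effect.utr3, Effect.utr5)
_TRUNCATING_CHOICES = (
    Effect.frameshift,
    Effect.stop_gain,
    Effect.splice_acceptor,
    Effect.splice_donor,
)
_IMPACT_OF = {
    Effect.missense: Impact.MODERATE,
    Effect.inframe_deletion: Impact.MODERATE,
    Effect.synonymous: Impact.LOW,
    Effect.splice_region: Impact.LOW,
    Effect.intronic: Impact.MODIFIER,
    Effect.utr3: Impact.MODIFIER,
    Effect.utr5: Impact.MODIFIER,
    Effect.upstream: Impact.MODIFIER,
    Effect.downstream: Impact.MODIFIER,
}


def _impact_of(effect: Effect) -> Impact:
    return _IMPACT_OF.get(effect, Impact.HIGH)


@dataclass(frozen=True)
class VariantSpec:
    """Ground truth for one simulated variant."""

    true_maf: float
    gene: str = "CYP2D6"
    effect: Effect = Effect.missense
    impact: Optional[Impact] = None
    damaging: bool = False  # all four predictors damaging + high CADD
    in_gnomad: bool = True
    gnomad_af: Optional[float] = None  # defaults to true_maf when in_gnomad
    has_rsid: bool = True
    clinvar_codes: Optional[frozenset] = None

    def __post_init__(self):
        if not (0.0 <= self.true_maf <= 1.0):
            raise ValueError(f"true_maf out of [0,1]: {self.true_maf}")


@dataclass
class CohortSpec:
    n_samples: int = _DEFAULT_N_SAMPLES
    variant_specs: Sequence[VariantSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


def default_cohort_spec(
    n_variants: int = 500,
    n_samples: int = _DEFAULT_N_SAMPLES,
    rare_fraction: float = 0.9,
    seed: int = 0,
) -> CohortSpec:
    """A cohort spec emulating an exome pharmacogene screen: ~90% of variants
    rare (reference AF below 1%), effect classes dominated by intronic and
    other non-coding annotation, deleterious annotations enriched among the
    rare tail."""
    if not (0.0 <= rare_fraction <= 1.0):
        raise ValueError("rare_fraction out of [0,1]")
    rng = np.random.default_rng(seed)
    genes = _panel_genes()
    effects = list(Effect)
    weights = np.array(
        [
            {
                Effect.intronic: 0.55,
                Effect.missense: 0.10,
                Effect.synonymous: 0.06,
                Effect.utr3: 0.05,
                Effect.utr5: 0.03,
                Effect.upstream: 0.03,
                Effect.downstream: 0.02,
                Effect.splice_region: 0.02,
                Effect.frameshift: 0.01,
                Effect.stop_gain: 0.01,
                Effect.splice_acceptor: 0.005,
                Effect.splice_donor: 0.005,
            }.get(e, 0.002)
            for e in effects
        ]
    )
    weights = weights / weights.sum()
    specs = []
    n_rare = int(round(rare_fraction * n_variants))
    for i in range(n_variants):
        rare = i < n_rare
        maf = float(10 ** rng.uniform(-4, -2)) if rare else float(10 ** rng.uniform(-1.9, -0.3))
        effect = effects[rng.choice(len(effects), p=weights)]
        specs.append(
            VariantSpec(
                true_maf=maf,
                gene=str(rng.choice(genes)),
                effect=effect,
                damaging=bool(effect is Effect.missense and rare and rng.random() < 0.3),
                in_gnomad=bool(rng.random() < (0.15 if rare else 0.99)),
                has_rsid=bool(rng.random() < (0.2 if rare else 0.95)),
            )
        )
    return CohortSpec(n_samples=n_samples, variant_specs=list(specs), seed=seed)


def _panel_genes() -> list:
    text = resources.files("pgxtriage.data").joinpath("panel_genes.txt").read_text()
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]


@dataclass(frozen=True)
class GeneratedCohort:
    vcf: Path
    annotations: Path
    truth: Path


def _draw_variant(
    rng: np.random.Generator, spec: VariantSpec, index: int, n_samples: int
) -> tuple[AnnotatedVariant, CohortGenotypeSummary, np.ndarray]:
    p = spec.true_maf
    genotypes = rng.choice(3, size=n_samples, p=[(1 - p) ** 2, 2 * p * (1 - p), p * p])
    het = int(np.sum(genotypes == 1))
    hom = int(np.sum(genotypes == 2))
    damaging = spec.damaging
    cadd = float(rng.uniform(20, 50)) if damaging else float(rng.uniform(0, 15))
    # tiny epsilon keeps the deleterious draw strictly above the cutoff
    cadd = max(cadd, 20.000001) if damaging else min(cadd, 15.0)
    call = "damaging" if damaging else "tolerated"
    variant = AnnotatedVariant(
        contig="chr1",
        position=10_000 + 10 * index,
        ref_allele="A",
        alt_allele="G",
        gene=spec.gene,
        effect=spec.effect,
        impact=spec.impact or _impact_of(spec.effect),
        hgvs_c=f"c.{100 + index}A>G",
        rsid=f"rs9{index:07d}" if spec.has_rsid else None,
        gnomad_af=(spec.gnomad_af if spec.gnomad_af is not None else p) if spec.in_gnomad else None,
        predictor_calls={pred: call for pred in PREDICTORS},
        cadd_phred=round(cadd, 3),
        gerp_rs=round(float(rng.uniform(-3, 6)), 3),
        clinvar_codes=spec.clinvar_codes,
        site_depth=int(rng.integers(30, 200)),
        site_quality=float(rng.integers(400, 5000)),
    )
    summary = CohortGenotypeSummary(variant.key, het, hom, n_samples)
    return variant, summary, genotypes


def generate_cohort(spec: CohortSpec, out_dir) -> GeneratedCohort:
    """Simulate the cohort and write ``cohort.vcf``, ``annotations.tsv`` and
    ``truth.tsv`` under ``out_dir``; returns the three paths."""
    if not spec.variant_specs:
        raise ValueError("CohortSpec has no variants")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    records, gt_rows, truth_rows = [], [], []
    for i, vspec in enumerate(spec.variant_specs):
        variant, summary, genotypes = _draw_variant(rng, vspec, i, spec.n_samples)
        records.append((variant, summary))
        gt_rows.append(genotypes)
        truth_rows.append(
            {
                "contig": variant.contig,
                "position": variant.position,
                "rsid": variant.rsid or ".",
                "true_maf": vspec.true_maf,
                "empirical_maf": (summary.het_count + 2 * summary.hom_count)
                / (2 * spec.n_samples),
                "gene": vspec.gene,
                "effect": vspec.effect.value,
                "damaging": vspec.damaging,
                "in_gnomad": vspec.in_gnomad,
            }
        )
    vcf_path = out_dir / "cohort.vcf"
    _write_vcf(vcf_path, records, gt_rows, spec.n_samples)
    ann_path = out_dir / "annotations.tsv"
    write_annotation_tsv(records, ann_path)
    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return GeneratedCohort(vcf=vcf_path, annotations=ann_path, truth=truth_path)


_GT_STRINGS = ("0/0", "0/1", "1/1")

_VCF_INFO_HEADER = """\
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=A,Type=String,Description="Variant effect class">
##INFO=<ID=IMPACT,Number=A,Type=String,Description="Variant impact class">
##INFO=<ID=HGVS_C,Number=A,Type=String,Description="Transcript-level HGVS">
##INFO=<ID=HGVS_P,Number=A,Type=String,Description="Protein-level HGVS">
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="gnomAD allele frequency">
##INFO=<ID=CADD_PHRED,Number=A,Type=Float,Description="CADD Phred score">
##INFO=<ID=GERP_RS,Number=1,Type=Float,Description="GERP++ RS conservation score">
##INFO=<ID=SIFT,Number=A,Type=String,Description="SIFT call">
##INFO=<ID=PP2,Number=A,Type=String,Description="PolyPhen-2 call">
##INFO=<ID=MT,Number=A,Type=String,Description="MutationTaster call">
##INFO=<ID=METASVM,Number=A,Type=String,Description="MetaSVM call">
##INFO=<ID=CLNSIG,Number=.,Type=Integer,Description="ClinVar significance codes">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _write_vcf(path: Path, records, gt_rows, n_samples: int) -> None:
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write(_VCF_INFO_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (variant, _), genotypes in zip(records, gt_rows):
            info = [
                f"GENE={variant.gene}",
                f"EFFECT={variant.effect.value}",
                f"IMPACT={variant.impact.value}",
                f"DP={variant.site_depth}",
            ]
            if variant.hgvs_c:
                info.append(f"HGVS_C={variant.hgvs_c}")
            if variant.gnomad_af is not None:
                info.append(f"GNOMAD_AF={variant.gnomad_af:.6g}")
            if variant.cadd_phred is not None:
                info.append(f"CADD_PHRED={variant.cadd_phred:.6g}")
            if variant.gerp_rs is not None:
                info.append(f"GERP_RS={variant.gerp_rs:.6g}")
            for pred, key in (("SIFT", "SIFT"), ("PolyPhen2", "PP2"), ("MutationTaster", "MT"), ("MetaSVM", "METASVM")):
                call = variant.predictor_calls[pred].value
                info.append(f"{key}={'D' if call == 'damaging' else 'T'}")
            if variant.clinvar_codes:
                info.append("CLNSIG=" + ",".join(str(c) for c in sorted(variant.clinvar_codes)))
            fields = [
                variant.contig,
                str(variant.position),
                variant.rsid or ".",
                variant.ref_allele,
                variant.alt_allele,
                f"{variant.site_quality:.6g}",
                "PASS",
                ";".join(info),
                "GT",
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(_GT_STRINGS[g] for g in genotypes) + "\n")


# ---------------------------------------------------------------------------
# Labelled rare-variant spectrum


def generate_rare_spectrum(
    n_variants: int,
    novel_fraction: float = 0.3,
    truncating_fraction: float = 0.1,
    consensus_fraction: float = 0.1,
    seed: int = 0,
    n_samples: int = _DEFAULT_N_SAMPLES,
    out_dir=None,
):
    """Emit rare variants whose triage class is fixed by construction.

    The first ``round(consensus_fraction * n)`` variants are consensus-
    pathogenic missense (four damaging calls, CADD on (20, 50]), the next
    ``round(truncating_fraction * n)`` are protein-truncating, the rest are
    neutral. Independently, each variant is novel (no rsID, gnomAD or
    ClinVar record) with probability ``novel_fraction``. Carrier counts are
    drawn under Hardy-Weinberg at a rare true frequency, conditioned on
    staying under the rarity thresholds so the "rare" truth label is exact.

    Returns ``(records, truth)``: the ``(AnnotatedVariant,
    CohortGenotypeSummary)`` pairs and a truth-label DataFrame. When
    ``out_dir`` is given, also writes ``spectrum.tsv`` and
    ``spectrum_truth.tsv``.
    """
    for name, frac in (
        ("novel_fraction", novel_fraction),
        ("truncating_fraction", truncating_fraction),
        ("consensus_fraction", consensus_fraction),
    ):
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"{name} out of [0,1]: {frac}")
    if truncating_fraction + consensus_fraction > 1.0:
        raise ValueError("disjoint class fractions exceed 1")
    rng = np.random.default_rng(seed)
    genes = _panel_genes()
    n_consensus = int(round(consensus_fraction * n_variants))
    n_truncating = int(round(truncating_fraction * n_variants))
    records, truth_rows = [], []
    for i in range(n_variants):
        if i < n_consensus:
            klass, effect = "consensus_missense", Effect.missense
        elif i < n_consensus + n_truncating:
            klass = "truncating"
            effect = _TRUNCATING_CHOICES[rng.integers(len(_TRUNCATING_CHOICES))]
        else:
            klass = "neutral"
            effect = _NEUTRAL_EFFECTS[rng.integers(len(_NEUTRAL_EFFECTS))]
        novel = bool(rng.random() < novel_fraction)
        maf = float(10 ** rng.uniform(-4, -2.5))
        while True:  # HWE draw conditioned on the rare-carrier thresholds
            genotypes = rng.choice(
                3, size=n_samples, p=[(1 - maf) ** 2, 2 * maf * (1 - maf), maf * maf]
            )
            het, hom = int(np.sum(genotypes == 1)), int(np.sum(genotypes == 2))
            if het <= 19 and hom <= 15:
                break
        damaging = klass == "consensus_missense"
        cadd = float(rng.uniform(20, 50)) if damaging or klass == "truncating" else float(rng.uniform(0, 15))
        cadd = max(cadd, 20.000001) if (damaging or klass == "truncating") else min(cadd, 15.0)
        variant = AnnotatedVariant(
            contig="chr1",
            position=10_000 + 10 * i,
            ref_allele="A",
            alt_allele="G",
            gene=str(rng.choice(genes)),
            effect=effect,
            impact=_impact_of(effect),
            rsid=None if novel else f"rs8{i:07d}",
            gnomad_af=None if novel else min(maf, 0.01),
            predictor_calls={p: "damaging" if damaging else "tolerated" for p in PREDICTORS},
            cadd_phred=round(cadd, 3),
            clinvar_codes=None,
            site_depth=int(rng.integers(30, 200)),
            site_quality=float(rng.integers(400, 5000)),
        )
        summary = CohortGenotypeSummary(variant.key, het, hom, n_samples)
        records.append((variant, summary))
        truth_rows.append(
            {
                "contig": variant.contig,
                "position": variant.position,
                "class": klass,
                "consensus_missense": klass == "consensus_missense",
                "truncating": klass == "truncating",
                "novel": novel,
                "rare": True,
                "true_maf": maf,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_annotation_tsv(records, out_dir / "spectrum.tsv")
        truth.to_csv(out_dir / "spectrum_truth.tsv", sep="\t", index=False)
    return records, truth


# ---------------------------------------------------------------------------
# Bundled actionable-variant fixture


@dataclass(frozen=True)
class ActionableFixture:
    """The packaged actionable-variant fixture (not simulated)."""

    variants: tuple  # of AnnotatedVariant
    summaries: tuple  # of CohortGenotypeSummary, same order
    kb: KnowledgeBase
    printed_maf: dict  # rsid -> published 3-s.f. cohort MAF
    star_allele: dict  # rsid -> star-allele token or None
    n_samples: int = _DEFAULT_N_SAMPLES

    @property
    def records(self) -> list:
        return list(zip(self.variants, self.summaries))


def actionable_fixture() -> ActionableFixture:
    """Load the bundled 24-variant actionable fixture and knowledge base."""
    data = resources.files("pgxtriage.data")
    df = pd.read_csv(
        data.joinpath("actionable_variants.tsv"), sep="\t", dtype=str, comment="#", keep_default_na=False
    )
    variants, summaries, printed, stars = [], [], {}, {}
    for row in df.itertuples(index=False):
        variant = AnnotatedVariant(
            contig=row.contig,
            position=int(row.position),
            ref_allele=row.ref,
            alt_allele=row.alt,
            gene=row.gene,
            effect=Effect(row.effect),
            impact=Impact(row.impact),
            hgvs_c=row.hgvs_c if row.hgvs_c != "." else None,
            hgvs_p=row.hgvs_p if row.hgvs_p != "." else None,
            rsid=row.rsid,
            gnomad_af=float(row.gnomad_af) if row.gnomad_af != "." else None,
            # the published table does not carry per-variant predictor output
            predictor_calls={},
            site_depth=60,
            site_quality=1000.0,
        )
        variants.append(variant)
        summaries.append(
            CohortGenotypeSummary(
                variant.key, int(row.het_count), int(row.hom_count), _DEFAULT_N_SAMPLES
            )
        )
        printed[row.rsid] = float(row.maf_cohort_printed)
        stars[row.rsid] = row.star_allele if row.star_allele != "." else None
    kb = KnowledgeBase(
        annotations=load_clinical_annotations(data.joinpath("clinical_annotations.tsv")),
        star_alleles=load_star_alleles(data.joinpath("star_alleles.tsv")),
    )
    return ActionableFixture(
        variants=tuple(variants),
        summaries=tuple(summaries),
        kb=kb,
        printed_maf=printed,
        star_allele=stars,
    )
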