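"""The triage cascade: rarity, consensus pathogenicity, truncation, novelty,
gene grouping, and the count matrix against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxtriage.model import (
    PREDICTORS,
    AnnotatedVariant,
    CohortGenotypeSummary,
    Effect,
    Impact,
)
from pgxtriage.triage import (
    CASCADE_CATEGORIES,
    CASCADE_COLUMNS,
    GeneGroup,
    Novelty,
    RarityThresholds,
    cascade_counts,
    consensus_pathogenic_missense,
    gene_group,
    is_rare,
    is_truncating,
    novelty_category,
    novelty_partition,
    triage_variant,
)

ALL_DAMAGING = {p: "damaging" for p in PREDICTORS}


@pytest.mark.parametrize(
    "af, het, hom, expected",
    [
        (0.0636, 5, 0, False),  # common in the reference population
        (0.00152, 11, 0, True),
        (None, 20, 0, False),  # het boundary: more than 19 carriers
        (None, 19, 15, True),
        (0.01, 0, 16, False),  # hom boundary
        (None, 0, 0, True),  # absence from the reference counts as rare
    ],
)
def test_rarity_rule(make_variant, make_summary, af, het, hom, expected):
    v = make_variant(gnomad_af=af)
    assert is_rare(v, make_summary(v, het=het, hom=hom)) is expected


def test_rarity_rejects_mismatched_keys(make_variant, make_summary):
    v1, v2 = make_variant(), make_variant()
    with pytest.raises(ValueError):
        is_rare(v1, make_summary(v2))


@pytest.mark.parametrize(
    "effect, calls, cadd, expected",
    [
        (Effect.missense, ALL_DAMAGING, 25.0, True),
        (Effect.missense, {**ALL_DAMAGING, "SIFT": "tolerated"}, 30.0, False),
        (Effect.missense, ALL_DAMAGING, 20.0, False),  # strict cutoff
        (Effect.missense, ALL_DAMAGING, None, False),
        (Effect.missense, {**ALL_DAMAGING, "MetaSVM": "unknown"}, 30.0, False),
        (Effect.synonymous, ALL_DAMAGING, 30.0, False),
    ],
)
def test_consensus_pathogenic_missense_rule(make_variant, effect, calls, cadd, expected):
    v = make_variant(effect=effect, predictor_calls=calls, cadd_phred=cadd)
    assert consensus_pathogenic_missense(v) is expected


@pytest.mark.parametrize(
    "effect, expected",
    [
        (Effect.frameshift, True),
        (Effect.stop_gain, True),
        (Effect.splice_acceptor, True),
        (Effect.splice_donor, True),
        (Effect.start_lost, True),
        (Effect.stop_lost, True),
        (Effect.splice_region, False),  # tracked separately, not truncating
        (Effect.missense, False),
        (Effect.inframe_deletion, False),
    ],
)
def test_truncating_effect_set(make_variant, effect, expected):
    impact = Impact.HIGH if expected else Impact.MODERATE
    assert is_truncating(make_variant(effect=effect, impact=impact)) is expected


@pytest.mark.parametrize(
    "af, rsid, codes, expected",
    [
        (0.0028, "rs1", None, Novelty.in_gnomad),  # gnomAD takes precedence
        (None, "rs1", None, Novelty.in_dbsnp),
        (None, None, frozenset({6}), Novelty.in_clinvar),
        (None, None, None, Novelty.novel),
    ],
)
def test_novelty_precedence(make_variant, af, rsid, codes, expected):
    v = make_variant(gnomad_af=af, rsid=rsid, clinvar_codes=codes)
    assert novelty_category(v) is expected


@pytest.mark.parametrize(
    "gene, expected",
    [
        ("SLCO1B1", GeneGroup.SLC),
        ("SLC22A2", GeneGroup.SLC),
        ("CYP4F2", GeneGroup.CYP),
        ("ABCB1", GeneGroup.ABC),
        ("UGT1A1", GeneGroup.UGT),
        ("TPMT", GeneGroup.other),
        ("cyp2d6", GeneGroup.CYP),
    ],
)
def test_gene_superfamily_grouping(gene, expected):
    assert gene_group(gene) is expected


def test_triage_composition_on_fixture_row(fixture24):
    """The CYP2C19 *8 fixture record comes out rare with a 1A clopidogrel tier."""
    variant, summary = next(
        (v, s) for v, s in fixture24.records if v.rsid == "rs41291556"
    )
    result = triage_variant(variant, summary, kb=fixture24.kb)
    assert result.is_rare
    assert result.actionability == frozenset({("1A", ("clopidogrel",))})
    assert not result.truncating and result.novelty is Novelty.in_gnomad


def test_triage_of_novel_frameshift(make_variant, make_summary):
    v = make_variant(effect=Effect.frameshift, impact=Impact.HIGH, cadd_phred=35.0,
                     rsid=None, gnomad_af=None)
    result = triage_variant(v, make_summary(v, het=1))
    assert result.truncating and result.novelty is Novelty.novel
    assert result.actionability == frozenset()
    # structural invariants
    assert not result.consensus_missense  # consensus implies missense


def _random_records(rng, n, n_samples=200):
    effects = list(Effect)
    records = []
    for i in range(n):
        effect = effects[rng.integers(len(effects))]
        damaging = bool(rng.random() < 0.3)
        het = int(rng.integers(0, 40))
        hom = int(rng.integers(0, min(20, n_samples - het) + 1))
        v = AnnotatedVariant(
            contig="chr1",
            position=i + 1,
            ref_allele="A",
            alt_allele="G",
            gene=str(rng.choice(["CYP2D6", "ABCB1", "SLCO1B1", "UGT1A1", "TPMT", "F5"])),
            effect=effect,
            impact=Impact.HIGH if effect.value in ("frameshift", "stop_gain") else Impact.MODERATE,
            rsid=f"rs{i}" if rng.random() < 0.5 else None,
            gnomad_af=float(rng.uniform(0, 0.05)) if rng.random() < 0.5 else None,
            predictor_calls={p: "damaging" if damaging else "tolerated" for p in PREDICTORS},
            cadd_phred=float(rng.uniform(0, 40)) if rng.random() < 0.8 else None,
            clinvar_codes=frozenset({int(rng.integers(1, 8))}) if rng.random() < 0.3 else None,
            site_depth=60,
            site_quality=500.0,
        )
        records.append((v, CohortGenotypeSummary(v.key, het, hom, n_samples)))
    return records


def brute_force_tally(records):
    """Independent per-record tally over ``(variant, summary)`` pairs, with
    the category predicates restated from their documented definitions
    (never routed through the triage module)."""
    trunc = {"frameshift", "stop_gain", "stop_lost", "start_lost", "splice_acceptor", "splice_donor"}

    def rare(v, s):
        return (
            (v.gnomad_af is None or v.gnomad_af <= 0.01)
            and s.het_count <= 19
            and s.hom_count <= 15
        )

    def consensus(v):
        return (
            v.effect.value == "missense"
            and all(c.value == "damaging" for c in v.predictor_calls.values())
            and v.cadd_phred is not None
            and v.cadd_phred > 20
        )

    def predicate(category, v, s):
        if category == "all":
            return True
        if category == "rare":
            return rare(v, s)
        if category == "rare_cadd_gt20":
            return rare(v, s) and v.cadd_phred is not None and v.cadd_phred > 20
        if category == "rare_consensus_missense":
            return rare(v, s) and consensus(v)
        if category == "rare_truncating":
            return rare(v, s) and v.effect.value in trunc
        if category.startswith("rare_"):
            return rare(v, s) and v.effect.value == category[len("rare_"):]
        if category.startswith("clinvar6"):
            member = v.clinvar_codes is not None and 6 in v.clinvar_codes
        else:
            member = False  # random records carry no PharmGKB annotations
        return member and (rare(v, s) if category.endswith("_rare") else True)

    counts = {}
    for category, _ in CASCADE_CATEGORIES:
        for col in CASCADE_COLUMNS:
            total = 0
            for v, s in records:
                if not predicate(category, v, s):
                    continue
                in_col = {
                    "cohort_total": True,
                    "in_gnomad": v.gnomad_af is not None,
                    "in_dbsnp": v.rsid is not None,
                    "in_clinvar": v.clinvar_codes is not None,
                    "novel": v.gnomad_af is None and v.rsid is None and v.clinvar_codes is None,
                }[col]
                total += in_col
            counts[(category, col)] = total
    return counts


def test_cascade_counts_equal_bruteforce_tally():
    rng = np.random.default_rng(11)
    records = _random_records(rng, 300)
    triaged = [(triage_variant(v, s), v) for v, s in records]
    cascade = cascade_counts(triaged)
    assert cascade.matrix == brute_force_tally(records)


def test_cascade_all_equals_rare_when_everything_is_rare(make_variant, make_summary):
    vs = [make_variant(gnomad_af=0.001) for _ in range(10)]
    triaged = [(triage_variant(v, make_summary(v, het=1)), v) for v in vs]
    cascade = cascade_counts(triaged)
    for col in CASCADE_COLUMNS:
        assert cascade[("all", col)] == cascade[("rare", col)]


def test_removing_a_record_decrements_exactly_its_cells():
    rng = np.random.default_rng(7)
    records = _random_records(rng, 50)
    triaged = [(triage_variant(v, s), v) for v, s in records]
    full = cascade_counts(triaged)
    reduced = cascade_counts(triaged[:-1])
    for key, value in full.matrix.items():
        delta = value - reduced.matrix[key]
        assert delta in (0, 1)
    assert full[("all", "cohort_total")] - reduced[("all", "cohort_total")] == 1


def test_cascade_requires_nonempty_input():
    with pytest.raises(ValueError):
        cascade_counts([])


def test_cell_bounds_and_novelty_partition():
    rng = np.random.default_rng(3)
    records = _random_records(rng, 200)
    triaged = [(triage_variant(v, s), v) for v, s in records]
    cascade = cascade_counts(triaged)
    for category, _ in CASCADE_CATEGORIES:
        total = cascade[(category, "cohort_total")]
        for col in CASCADE_COLUMNS:
            assert 0 <= cascade[(category, col)] <= total
    partition = novelty_partition(triaged)
    assert sum(partition.values()) == len(triaged)


@settings(max_examples=30, derandomize=True)
@given(
    af=st.one_of(st.none(), st.floats(0, 0.2)),
    het=st.integers(0, 60),
    hom=st.integers(0, 40),
    d_af=st.floats(0, 0.05),
    d_het=st.integers(0, 10),
    d_hom=st.integers(0, 10),
)
def test_tightening_thresholds_never_enlarges_the_rare_set(af, het, hom, d_af, d_het, d_hom):
    v = AnnotatedVariant("chr1", 1, "A", "G", "CYP2D6", Effect.missense, Impact.MODERATE,
                         gnomad_af=af, site_depth=60, site_quality=500.0)
    s = CohortGenotypeSummary(v.key, het, hom, 200)
    loose = RarityThresholds(0.01 + d_af, 19 + d_het, 15 + d_hom)
    tight = RarityThresholds(max(0.01 - d_af, 0), max(19 - d_het, 0), max(15 - d_hom, 0))
    assert not (is_rare(v, s, tight) and not is_rare(v, s, loose))


def test_triage_is_order_independent():
    rng = np.random.default_rng(19)
    records = _random_records(rng, 100)
    triaged = {v.key: triage_variant(v, s) for v, s in records}
    shuffled = records[::-1]
    for v, s in shuffled:
        assert triage_variant(v, s) == triaged[v.key]
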