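import pytest

from pgxtriage.model import AnnotatedVariant, CohortGenotypeSummary, Effect, Impact
from pgxtriage.synthetic_data import actionable_fixture


@pytest.fixture(scope="session")
def fixture24():
    """The bundled 24-variant actionable fixture and knowledge base."""
    return actionable_fixture()


@pytest.fixture
def make_variant():
    """Factory for annotated variants with sensible defaults."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        defaults = dict(
            contig="chr1",
            position=1000 + counter["n"],
            ref_allele="A",
            alt_allele="G",
            gene="CYP2D6",
            effect=Effect.missense,
            impact=Impact.MODERATE,
            site_depth=60,
            site_quality=500.0,
        )
        defaults.update(kwargs)
        return AnnotatedVariant(**defaults)

    return _make


@pytest.fixture
def make_summary():
    def _make(variant, het=0, hom=0, n=1904):
        return CohortGenotypeSummary(variant.key, het, hom, n)

    return _make
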