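import pytest
from hypothesis import HealthCheck, settings

from fibropanel import classify_variants, paper_fixture
from fibropanel.model import (
    AlleleCount,
    Consequence,
    DatabaseAnnotation,
    OBSERVED_POPULATIONS,
    Population,
    VariantRecord,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_data():
    """The reconciled published-aggregate dataset."""
    return paper_fixture()


@pytest.fixture(scope="session")
def classified(reference_data):
    records, annotations = reference_data
    return classify_variants(records, annotations)


def make_record(
    gene="FGA",
    pos=155_505_000,
    consequence=Consequence.MISSENSE,
    counts=None,
    an=20_000,
    protein_change=None,
    **kwargs,
):
    """Small factory: counts given as {Population: ac}; one shared an."""
    counts = counts or {}
    full = {p: AlleleCount(counts.get(p, 0), an) for p in OBSERVED_POPULATIONS}
    ref, alt = "A", "G"
    return VariantRecord(
        variant_id=f"4-{pos}-{ref}-{alt}",
        gene=gene,
        chrom="4",
        pos=pos,
        ref=ref,
        alt=alt,
        consequence=consequence,
        counts=full,
        protein_change=protein_change,
        **kwargs,
    )
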