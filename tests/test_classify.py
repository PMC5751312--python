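"""Inclusion/exclusion rules, consensus calls and eligibility flags."""
import itertools

import pytest

from fibropanel.classify import (
    classify_variant,
    missense_consensus,
    splice_consensus,
    splice_tool_verdict,
)
from fibropanel.model import (
    MISSENSE_TOOLS,
    SPLICE_TOOLS,
    Consequence,
    DatabaseAnnotation,
    ExclusionReason,
    FilterStatus,
    InclusionRule,
    Population,
    PredictionProfile,
    SpliceScore,
    Verdict,
    parse_phenotypes,
)
from conftest import make_record


def _db(phenotypes=""):
    phenos = parse_phenotypes(phenotypes)
    return DatabaseAnnotation(reported=bool(phenos), phenotypes=phenos)


def _splice_profile(n_disrupting):
    scores = {}
    for i, tool in enumerate(SPLICE_TOOLS):
        mut = 3.0 if i < n_disrupting else 8.0
        scores[tool] = SpliceScore(10.0, mut, False, missing=False)
    return PredictionProfile({}, scores)


@pytest.mark.parametrize(
    "wt, mut, abolished, expected",
    [
        (10.0, 4.0, False, True),   # below half the wild-type score
        (10.0, 5.0, False, False),  # exactly half: strict inequality, kept
        (10.0, 9.0, True, True),    # site reported abolished wins
        (10.0, 10.0, False, False),
    ],
)
def test_splice_tool_verdict(wt, mut, abolished, expected):
    assert splice_tool_verdict(wt, mut, abolished) is expected


def test_splice_tool_verdict_rejects_bad_scores():
    with pytest.raises(ValueError):
        splice_tool_verdict(-1.0, 0.5, False)
    with pytest.raises(ValueError):
        splice_tool_verdict(0.0, 0.0, False)  # wt must be positive unless abolished


def test_missense_consensus_exhaustive():
    """Over all 3^7 verdict vectors exactly one (all damaging) passes."""
    n_true = 0
    for verdicts in itertools.product(
        [Verdict.DAMAGING, Verdict.TOLERATED, Verdict.MISSING], repeat=7
    ):
        profile = PredictionProfile(dict(zip(MISSENSE_TOOLS, verdicts)))
        if missense_consensus(profile):
            n_true += 1
            assert all(v is Verdict.DAMAGING for v in verdicts)
    assert n_true == 1


def test_splice_consensus_requires_all_three():
    assert splice_consensus(_splice_profile(3))
    assert not splice_consensus(_splice_profile(2))
    missing = PredictionProfile({}, {SPLICE_TOOLS[0]: SpliceScore()})
    assert not splice_consensus(missing)  # missing never counts as disrupting


def test_frameshift_is_null_mutation_and_recessive_eligible():
    rec = make_record(consequence=Consequence.FRAMESHIFT, exon_label="4",
                      counts={Population.NFE: 2})
    c = classify_variant(rec, PredictionProfile(), _db())
    assert c.deleterious and c.inclusion_rule is InclusionRule.NULL_MUTATION
    assert c.recessive_eligible and c.dominant_eligible


def test_excluded_exon_beats_predictor_consensus():
    rec = make_record(consequence=Consequence.MISSENSE, exon_label="6")
    c = classify_variant(rec, PredictionProfile.all_damaging(), _db())
    assert not c.deleterious
    assert c.exclusion_reason is ExclusionReason.EXCLUDED_EXON
    # the same variant in a non-excluded exon is included by consensus
    rec2 = make_record(consequence=Consequence.MISSENSE, exon_label="5")
    c2 = classify_variant(rec2, PredictionProfile.all_damaging(), _db())
    assert c2.inclusion_rule is InclusionRule.MISSENSE_CONSENSUS


def test_low_confidence_excluded_first_even_if_reported():
    rec = make_record(consequence=Consequence.NONSENSE,
                      filter_status=FilterStatus.LOW_CONFIDENCE)
    c = classify_variant(rec, PredictionProfile(), _db("a"))
    assert not c.deleterious
    assert c.exclusion_reason is ExclusionReason.LOW_CONFIDENCE


def test_alternative_transcript_intron_excluded():
    rec = make_record(consequence=Consequence.SPLICE_NEAR, intron_offset=5,
                      on_alternative_transcript_only=True)
    c = classify_variant(rec, _splice_profile(3), _db())
    assert not c.deleterious
    assert c.exclusion_reason is ExclusionReason.ALTERNATIVE_TRANSCRIPT_INTRON


def test_dominant_only_phenotype_blocks_recessive_eligibility():
    rec = make_record(consequence=Consequence.MISSENSE, exon_label="2")
    c = classify_variant(rec, PredictionProfile.all_tolerated(), _db("d"))
    assert c.deleterious and c.inclusion_rule is InclusionRule.DB_REPORTED_MISSENSE
    assert c.dominant_eligible and not c.recessive_eligible
    # multi-label: any dominant-only phenotype excludes from the recessive set
    c2 = classify_variant(rec, PredictionProfile.all_tolerated(), _db("d/h"))
    assert c2.dominant_eligible and not c2.recessive_eligible
    c3 = classify_variant(rec, PredictionProfile.all_tolerated(), _db("h"))
    assert c3.recessive_eligible


def test_splice_near_needs_three_of_three():
    rec = make_record(consequence=Consequence.SPLICE_NEAR, intron_offset=3)
    assert not classify_variant(rec, _splice_profile(2), _db()).deleterious
    c = classify_variant(rec, _splice_profile(3), _db())
    assert c.inclusion_rule is InclusionRule.SPLICE_NEAR_CONSENSUS


def test_splice_core_included_without_predictions():
    rec = make_record(consequence=Consequence.SPLICE_CORE, intron_offset=1)
    c = classify_variant(rec, PredictionProfile(), _db())
    assert c.inclusion_rule is InclusionRule.SPLICE_CORE


def test_synonymous_never_deleterious():
    rec = make_record(consequence=Consequence.SYNONYMOUS, exon_label="3")
    c = classify_variant(rec, PredictionProfile.all_damaging(), _db())
    assert not c.deleterious and c.inclusion_rule is InclusionRule.NONE


def test_inframe_indel_follows_missense_path():
    rec = make_record(consequence=Consequence.INFRAME_INDEL, exon_label="2")
    assert (
        classify_variant(rec, PredictionProfile.all_damaging(), _db()).inclusion_rule
        is InclusionRule.MISSENSE_CONSENSUS
    )
    assert (
        classify_variant(rec, PredictionProfile(), _db("a")).inclusion_rule
        is InclusionRule.DB_REPORTED_MISSENSE
    )


def test_classification_is_deterministic(reference_data):
    from fibropanel.classify import classify_variants

    records, annotations = reference_data
    a = classify_variants(records, annotations)
    b = classify_variants(records, annotations)
    assert a == b


def test_dominant_minus_recessive_alleles_equals_dominant_only_labels(classified):
    """Panel-wide, the dominant-eligible allele mass exceeds the
    recessive-eligible mass by exactly the alleles of variants labelled
    dysfibrinogenemia / hypo-dysfibrinogenemia / amyloidosis."""
    from fibropanel.model import DOMINANT_ONLY_PHENOTYPES

    dom = sum(v.record.total_ac for v in classified if v.dominant_eligible)
    rec = sum(v.record.total_ac for v in classified if v.recessive_eligible)
    labelled = sum(
        v.record.total_ac
        for v in classified
        if v.deleterious and (v.db.phenotypes & DOMINANT_ONLY_PHENOTYPES)
    )
    assert dom - rec == labelled == 283
    assert dom == 1524 and rec == 154 + 231 + 856
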