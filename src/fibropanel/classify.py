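"""Deleteriousness classification of fibrinogen-cluster variants.

A variant is called deleterious when it is (in order of precedence):

1. a null mutation (frameshift or nonsense);
2. a disruptive splice-site variant at the first two or last two intronic
   nucleotides (``splice_core``);
3. a near-splice variant (intronic −3, +3..+6) predicted disrupting by
   3 of 3 splice predictors, where "disrupting" means the predictor reports
   the wild-type site abolished or a mutant score below half the wild-type
   score (strict inequality; ties are not deleterious);
4. a missense or in-frame indel reported as disease-causing in
   fibrinogen-disorder databases; or
5. a missense or in-frame indel called damaging by 7 of 7 missense
   predictors (a missing verdict counts as not damaging).

Exclusions are applied before any inclusion rule: low-confidence calls;
variants in exons carrying only minor mRNA isoforms (by default FGA exon 6
and FGG exon 10); and intronic variants annotated only on alternative
transcripts of unknown significance.

Eligibility: every deleterious variant enters the dominant (cumulative)
carrier-rate calculation; variants whose database phenotype includes
dysfibrinogenemia, hypo-dysfibrinogenemia or amyloidosis — dominantly
inherited conditions that cannot produce afibrinogenemia in trans — are
excluded from the recessive calculation.
"""
from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

from .model import (
    DOMINANT_ONLY_PHENOTYPES,
    SPLICE_TOOLS,
    ClassifiedVariant,
    Consequence,
    DatabaseAnnotation,
    ExclusionReason,
    FilterStatus,
    InclusionRule,
    PanelConfig,
    PredictionProfile,
    SpliceScore,
    VariantRecord,
    Verdict,
)

logger = logging.getLogger("fibropanel")


def splice_tool_verdict(
    wt_score: float, mut_score: float, site_abolished: bool
) -> bool:
    """One splice predictor's call: disrupting or not.

    Disrupting iff the wild-type site is abolished or the mutant score falls
    strictly below half the wild-type score.
    """
    if wt_score < 0 or mut_score < 0:
        raise ValueError("splice scores must be non-negative")
    if site_abolished:
        return True
    if wt_score == 0:
        raise ValueError("wt_score must be positive unless the site is abolished")
    return mut_score < 0.5 * wt_score


def splice_consensus(profile: PredictionProfile) -> bool:
    """True iff all 3 splice predictors report the variant as disrupting.

    A missing predictor output never counts as disrupting.
    """
    for tool in SPLICE_TOOLS:
        score: SpliceScore = profile.splice_scores[tool]
        if score.missing:
            return False
        if not splice_tool_verdict(score.wt_score, score.mut_score, score.site_abolished):
            return False
    return True


def missense_consensus(profile: PredictionProfile) -> bool:
    """True iff all 7 missense predictors are present and call damaging."""
    return all(v is Verdict.DAMAGING for v in profile.missense_verdicts.values())


def classify_variant(
    record: VariantRecord,
    profile: PredictionProfile,
    db: DatabaseAnnotation,
    panel: Optional[PanelConfig] = None,
) -> ClassifiedVariant:
    """Apply the exclusion and inclusion rules to a single variant."""
    panel = panel if panel is not None else PanelConfig()
    if record.gene not in panel.genes:
        raise ValueError(f"gene {record.gene} not in panel {sorted(panel.genes)}")

    exclusion: Optional[ExclusionReason] = None
    if record.filter_status is FilterStatus.LOW_CONFIDENCE:
        exclusion = ExclusionReason.LOW_CONFIDENCE
        if db.reported:
            logger.info(
                "%s is database-reported but low-confidence in the call set; excluded",
                record.variant_id,
            )
    elif record.exon_label is not None and record.exon_label in panel.excluded_exons(record.gene):
        exclusion = ExclusionReason.EXCLUDED_EXON
    elif record.intron_offset is not None and record.on_alternative_transcript_only:
        exclusion = ExclusionReason.ALTERNATIVE_TRANSCRIPT_INTRON

    rule = InclusionRule.NONE
    if exclusion is None:
        csq = record.consequence
        if csq in (Consequence.FRAMESHIFT, Consequence.NONSENSE):
            rule = InclusionRule.NULL_MUTATION
        elif csq is Consequence.SPLICE_CORE:
            rule = InclusionRule.SPLICE_CORE
        elif csq is Consequence.SPLICE_NEAR and splice_consensus(profile):
            rule = InclusionRule.SPLICE_NEAR_CONSENSUS
        elif csq in (Consequence.MISSENSE, Consequence.INFRAME_INDEL):
            if db.reported:
                rule = InclusionRule.DB_REPORTED_MISSENSE
            elif missense_consensus(profile):
                rule = InclusionRule.MISSENSE_CONSENSUS
        # synonymous/other are never deleterious regardless of predictions

    deleterious = rule is not InclusionRule.NONE
    recessive = deleterious and not (db.phenotypes & DOMINANT_ONLY_PHENOTYPES)
    return ClassifiedVariant(
        record=record,
        db=db,
        deleterious=deleterious,
        inclusion_rule=rule,
        exclusion_reason=None if deleterious else exclusion,
        recessive_eligible=recessive,
        dominant_eligible=deleterious,
    )


def classify_variants(
    records: Iterable[VariantRecord],
    annotations: dict[str, tuple[PredictionProfile, DatabaseAnnotation]],
    panel: Optional[PanelConfig] = None,
) -> list[ClassifiedVariant]:
    """Classify every record; unannotated variants get empty profiles."""
    out = []
    for record in records:
        profile, db = annotations.get(
            record.variant_id, (PredictionProfile(), DatabaseAnnotation())
        )
        out.append(classify_variant(record, profile, db, panel))
    return out


def exclusion_tally(classified: Sequence[ClassifiedVariant]) -> dict[str, int]:
    """Machine-readable summary of classification outcomes."""
    tally: dict[str, int] = {
        "total": len(classified),
        "deleterious": sum(c.deleterious for c in classified),
        "recessive_eligible": sum(c.recessive_eligible for c in classified),
        "dominant_eligible": sum(c.dominant_eligible for c in classified),
    }
    for rule in InclusionRule:
        tally[f"rule_{rule.value}"] = sum(c.inclusion_rule is rule for c in classified)
    for reason in ExclusionReason:
        tally[f"excluded_{reason.value}"] = sum(
            c.exclusion_reason is reason for c in classified
        )
    return tally
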