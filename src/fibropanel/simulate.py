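"""Synthetic gnomAD-like variant tables with known truth.

The generator emulates the structure of a population allele-count repository
over the fibrinogen cluster: eight population groups with the release-2.0
sample sizes, per-site allele numbers that vary slightly with sequencing
success, a background of very rare (mostly singleton-scale) deleterious and
benign sites, optional high-frequency founder alleles restricted to subsets
of populations, predictor-verdict profiles, and database phenotype labels.

For every site and population, ``an`` is drawn as 2 × Binomial(N, call rate)
and ``ac`` as Binomial(an, true frequency); sites never observed (total
``ac`` = 0) are dropped from the output, as an allele-count repository would.
The truth (per-site frequencies and per-stratum collective frequencies) is
recorded before sampling, so estimator recovery can be tested against it.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    GENES,
    GNOMAD_SAMPLE_SIZES,
    MISSENSE_TOOLS,
    OBSERVED_POPULATIONS,
    SPLICE_TOOLS,
    AlleleCount,
    Consequence,
    DatabaseAnnotation,
    DOMINANT_ONLY_PHENOTYPES,
    Phenotype,
    Population,
    PredictionProfile,
    SpliceScore,
    VariantRecord,
    Verdict,
)

# deterministic genomic scaffolding for invented sites (GRCh37-like spans
# of the chromosome-4 fibrinogen cluster)
_GENE_BASE_POS = {"FGA": 155_504_000, "FGB": 155_484_000, "FGG": 155_525_000}
_GENE_EXONS = {"FGA": [str(i) for i in range(1, 6)],
               "FGB": [str(i) for i in range(1, 9)],
               "FGG": [str(i) for i in range(1, 10)]}
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class GeneSiteCounts:
    """Numbers of truly-deleterious sites per class, plus benign sites."""

    frameshift: int = 4
    nonsense: int = 4
    splice_core: int = 2
    splice_near: int = 2
    missense: int = 10
    inframe_indel: int = 1
    benign: int = 10


@dataclass(frozen=True)
class FounderSpec:
    """A single ancestral allele at elevated frequency in some populations."""

    gene: str
    populations: tuple[Population, ...]
    true_freq: float
    phenotypes: frozenset[Phenotype] = frozenset({Phenotype.HYPOFIBRINOGENEMIA})
    consequence: Consequence = Consequence.MISSENSE


def _default_founders() -> list[FounderSpec]:
    # emulates a recurrent hypofibrinogenemia founder allele spread across
    # all groups except East Asians (allele frequency ~3e-3 in carriers'
    # populations, the scale reported for the known FGG founder variant)
    pops = tuple(p for p in OBSERVED_POPULATIONS if p not in (Population.EAS, Population.OTH))
    return [FounderSpec("FGG", pops, 0.003)]


@dataclass
class SyntheticConfig:
    seed: int = 0
    populations: dict[Population, int] = field(
        default_factory=lambda: dict(GNOMAD_SAMPLE_SIZES)
    )
    call_rate_range: tuple[float, float] = (0.995, 1.0)
    genes: dict[str, GeneSiteCounts] = field(
        default_factory=lambda: {g: GeneSiteCounts() for g in GENES}
    )
    #: per-site true allele frequency of non-founder sites; None means the
    #: singleton scale 1/(2 * total sample size)
    background_freq: Optional[float] = None
    founders: list[FounderSpec] = field(default_factory=_default_founders)
    #: P(7/7 damaging) for truly-deleterious missense; same for benign
    predictor_consensus_rate: float = 0.8
    benign_consensus_rate: float = 0.001
    #: fraction of deleterious sites carrying each database label
    phenotype_label_rates: dict[Phenotype, float] = field(
        default_factory=lambda: {
            Phenotype.AFIBRINOGENEMIA: 0.15,
            Phenotype.HYPOFIBRINOGENEMIA: 0.08,
            Phenotype.DYSFIBRINOGENEMIA: 0.06,
            Phenotype.AMYLOIDOSIS: 0.01,
        }
    )

    def __post_init__(self) -> None:
        for p, n in self.populations.items():
            if n <= 0:
                raise ValueError(f"sample size for {p} must be positive")
        lo, hi = self.call_rate_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("call_rate_range must satisfy 0 <= lo <= hi <= 1")
        for rate in (self.predictor_consensus_rate, self.benign_consensus_rate,
                     *self.phenotype_label_rates.values()):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def total_alleles(self) -> int:
        return 2 * sum(self.populations.values())

    def site_background_freq(self) -> float:
        return (
            self.background_freq
            if self.background_freq is not None
            else 1.0 / self.total_alleles
        )


@dataclass
class TruthSet:
    """True frequencies recorded before sampling."""

    site_freqs: dict[str, dict[Population, float]]
    recessive_q: dict[tuple[str, Population], float]
    dominant_q: dict[Population, float]

    def recessive_prevalence_per_1e6(self, gene: str, pop: Population) -> float:
        return self.recessive_q[(gene, pop)] ** 2 * 1e6

    def panel_recessive_prevalence_per_1e6(self, pop: Population) -> float:
        return sum(self.recessive_q[(g, pop)] ** 2 for g in GENES) * 1e6

    def dominant_prevalence_per_1e3(self, pop: Population) -> float:
        return 2.0 * self.dominant_q[pop] * 1e3


@dataclass
class _Site:
    gene: str
    consequence: Consequence
    deleterious: bool
    freqs: dict[Population, float]
    phenotypes: frozenset[Phenotype] = frozenset()


def _plan_sites(config: SyntheticConfig, rng: np.random.Generator) -> list[_Site]:
    background = config.site_background_freq()
    if background > 0.5:
        raise ValueError(f"true allele frequency {background} > 0.5: the model is for rare variants")
    sites: list[_Site] = []
    label_items = sorted(config.phenotype_label_rates.items(), key=lambda kv: kv[0].value)
    for gene in sorted(config.genes):
        plan = config.genes[gene]
        classes = [
            (Consequence.FRAMESHIFT, plan.frameshift, True),
            (Consequence.NONSENSE, plan.nonsense, True),
            (Consequence.SPLICE_CORE, plan.splice_core, True),
            (Consequence.SPLICE_NEAR, plan.splice_near, True),
            (Consequence.MISSENSE, plan.missense, True),
            (Consequence.INFRAME_INDEL, plan.inframe_indel, True),
        ]
        for csq, count, deleterious in classes:
            for _ in range(count):
                phenos: frozenset[Phenotype] = frozenset()
                for label, rate in label_items:
                    if rng.random() < rate:
                        phenos = frozenset({label})
                        break
                sites.append(
                    _Site(gene, csq, deleterious,
                          {p: background for p in config.populations}, phenos)
                )
        for i in range(plan.benign):
            csq = Consequence.MISSENSE if i % 2 == 0 else Consequence.SYNONYMOUS
            sites.append(
                _Site(gene, csq, False, {p: background for p in config.populations})
            )
    for founder in config.founders:
        if founder.true_freq > 0.5:
            raise ValueError(
                f"founder true_freq {founder.true_freq} > 0.5: the model is for rare variants"
            )
        freqs = {
            p: (founder.true_freq if p in founder.populations else 0.0)
            for p in config.populations
        }
        sites.append(
            _Site(founder.gene, founder.consequence, True, freqs, founder.phenotypes)
        )
    return sites


def _profile_for(site: _Site, config: SyntheticConfig, rng: np.random.Generator) -> PredictionProfile:
    verdicts: dict[str, Verdict] = {}
    scores: dict[str, SpliceScore] = {}
    if site.consequence in (Consequence.MISSENSE, Consequence.INFRAME_INDEL, Consequence.SYNONYMOUS):
        rate = (
            config.predictor_consensus_rate if site.deleterious else config.benign_consensus_rate
        )
        if rng.random() < rate:
            verdicts = {t: Verdict.DAMAGING for t in MISSENSE_TOOLS}
        else:
            n_damaging = int(rng.integers(0, 7))  # never reaches 7/7
            shuffled = list(MISSENSE_TOOLS)
            rng.shuffle(shuffled)
            verdicts = {
                t: (Verdict.DAMAGING if i < n_damaging else Verdict.TOLERATED)
                for i, t in enumerate(shuffled)
            }
    if site.consequence is Consequence.SPLICE_NEAR:
        if site.deleterious and rng.random() < config.predictor_consensus_rate:
            scores = {t: SpliceScore(10.0, 3.0, False, missing=False) for t in SPLICE_TOOLS}
        else:
            scores = {t: SpliceScore(10.0, 8.0, False, missing=False) for t in SPLICE_TOOLS}
            first = SPLICE_TOOLS[0]
            scores[first] = SpliceScore(10.0, 3.0, False, missing=False)
    return PredictionProfile(verdicts, scores)


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[
    list[VariantRecord],
    dict[str, tuple[PredictionProfile, DatabaseAnnotation]],
    TruthSet,
]:
    """Draw one synthetic dataset; identical seeds give identical output."""
    rng = np.random.default_rng(config.seed)
    sites = _plan_sites(config, rng)

    # truth before sampling
    total_an_weights = {p: 2 * n for p, n in config.populations.items()}
    weight_sum = sum(total_an_weights.values())
    recessive_q: dict[tuple[str, Population], float] = {}
    dominant_q: dict[Population, float] = {}
    pops = list(config.populations)
    for pop in [*pops, Population.ALL]:
        def site_freq(s: _Site) -> float:
            if pop is Population.ALL:
                return sum(total_an_weights[p] * s.freqs[p] for p in pops) / weight_sum
            return s.freqs[pop]

        for gene in GENES:
            recessive_q[(gene, pop)] = sum(
                site_freq(s)
                for s in sites
                if s.gene == gene and s.deleterious and not (s.phenotypes & DOMINANT_ONLY_PHENOTYPES)
            )
        dominant_q[pop] = sum(site_freq(s) for s in sites if s.deleterious)

    records: list[VariantRecord] = []
    annotations: dict[str, tuple[PredictionProfile, DatabaseAnnotation]] = {}
    site_freqs: dict[str, dict[Population, float]] = {}
    pos_counter = {g: itertools.count(0) for g in GENES}
    residue_counter = {g: itertools.count(40) for g in GENES}
    lo, hi = config.call_rate_range

    for site in sites:
        call_rate = float(rng.uniform(lo, hi))
        counts: dict[Population, AlleleCount] = {}
        for pop, n_individuals in config.populations.items():
            an = 2 * int(rng.binomial(n_individuals, call_rate))
            freq = site.freqs[pop]
            ac = int(rng.binomial(an, freq)) if freq > 0 else 0
            counts[pop] = AlleleCount(ac, an)
        if sum(c.ac for c in counts.values()) == 0:
            continue  # unobserved in the sampled cohort

        i = next(pos_counter[site.gene])
        pos = _GENE_BASE_POS[site.gene] + 7 * i + 3
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        if site.consequence is Consequence.FRAMESHIFT:
            ref, alt = ref + alt, ref
        elif site.consequence is Consequence.INFRAME_INDEL:
            ref, alt = ref + "CGT", ref
        intron_offset = None
        exon_label: Optional[str] = None
        protein_change = None
        if site.consequence is Consequence.SPLICE_CORE:
            intron_offset = 1 if i % 2 == 0 else -2
        elif site.consequence is Consequence.SPLICE_NEAR:
            intron_offset = (3, 5, -3, 6)[i % 4]
        else:
            exons = _GENE_EXONS[site.gene]
            exon_label = exons[i % len(exons)]
            if site.consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS):
                residue = next(residue_counter[site.gene])
                aa_alt = "=" if site.consequence is Consequence.SYNONYMOUS else "Val"
                protein_change = f"p.Ala{residue}{aa_alt}"
        vid = f"4-{pos}-{ref}-{alt}"
        record = VariantRecord(
            variant_id=vid,
            gene=site.gene,
            chrom="4",
            pos=pos,
            ref=ref,
            alt=alt,
            consequence=site.consequence,
            counts=counts,
            protein_change=protein_change,
            intron_offset=intron_offset,
            exon_label=exon_label,
        )
        records.append(record)
        annotations[vid] = (
            _profile_for(site, config, rng),
            DatabaseAnnotation(reported=bool(site.phenotypes), phenotypes=site.phenotypes),
        )
        site_freqs[vid] = dict(site.freqs)

    truth = TruthSet(site_freqs, recessive_q, dominant_q)
    return records, annotations, truth
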