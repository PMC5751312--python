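"""Domain types for the fibrinogen gene-panel burden analysis.

The panel covers the three fibrinogen-chain genes (*FGA*, *FGB*, *FGG*,
clustered on chromosome 4q31.3-q32.1).  Variants arrive as one record per
alternate allele with per-population allele counts (``ac``) and allele
numbers (``an``) in the gnomAD v2 dialect; ``ac`` counts allele copies, not
carriers, so a homozygote contributes 2.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Population(str, enum.Enum):
    """gnomAD v2 population groups.

    ``ALL`` is a derived, panel-wide group: it is never read from input and
    its denominator is computed from the eight observed groups.
    """

    AFR = "AFR"  # Africans and African Americans
    AMR = "AMR"  # Admixed Americans
    ASJ = "ASJ"  # Ashkenazi Jewish
    EAS = "EAS"  # East Asians
    FIN = "FIN"  # Finnish
    NFE = "NFE"  # Non-Finnish Europeans
    SAS = "SAS"  # South Asians
    OTH = "OTH"  # Other (population not assigned)
    ALL = "ALL"  # derived union of the eight groups above

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The eight observed groups, in canonical (alphabetical) order.
OBSERVED_POPULATIONS: tuple[Population, ...] = (
    Population.AFR,
    Population.AMR,
    Population.ASJ,
    Population.EAS,
    Population.FIN,
    Population.NFE,
    Population.SAS,
    Population.OTH,
)

#: gnomAD release 2.0 diploid sample sizes per population (exomes + genomes).
GNOMAD_SAMPLE_SIZES: dict[Population, int] = {
    Population.AFR: 12020,
    Population.AMR: 17210,
    Population.ASJ: 5076,
    Population.EAS: 9435,
    Population.FIN: 12897,
    Population.NFE: 63369,
    Population.SAS: 15391,
    Population.OTH: 3234,
}

GENES = ("FGA", "FGB", "FGG")


class Consequence(str, enum.Enum):
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SPLICE_CORE = "splice_core"  # first two / last two intronic nucleotides
    SPLICE_NEAR = "splice_near"  # intronic positions -3 and +3..+6
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Intron offsets (donor side positive, acceptor side negative) per class.
SPLICE_CORE_OFFSETS = frozenset({-2, -1, 1, 2})
SPLICE_NEAR_OFFSETS = frozenset({-3, 3, 4, 5, 6})


class FilterStatus(str, enum.Enum):
    PASS = "pass"
    LOW_CONFIDENCE = "low_confidence"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AlleleCount:
    """Alternate-allele count and allele number for one population.

    ``an == 0`` means the site was not called in that population; the site is
    then skipped when forming that population's denominator.
    """

    ac: int
    an: int

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0:
            raise ValueError(f"negative allele count/number: ac={self.ac}, an={self.an}")
        if self.ac > self.an:
            raise ValueError(f"ac={self.ac} exceeds an={self.an}")


@dataclass
class VariantRecord:
    """One alternate allele at one site (GRCh37, 1-based coordinates)."""

    variant_id: str  # chrom-pos-ref-alt
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    counts: dict[Population, AlleleCount]
    rsid: Optional[str] = None
    protein_change: Optional[str] = None  # native-protein HGVS, e.g. p.Ala108Gly
    hgvs_c: Optional[str] = None
    intron_offset: Optional[int] = None
    exon_label: Optional[str] = None  # canonical-transcript exon number
    on_alternative_transcript_only: bool = False
    filter_status: FilterStatus = FilterStatus.PASS

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; allowed: {', '.join(GENES)}")
        if Population.ALL in self.counts:
            raise ValueError("counts must not contain the derived ALL group")
        off = self.intron_offset
        if self.consequence is Consequence.SPLICE_CORE and off not in SPLICE_CORE_OFFSETS:
            raise ValueError(f"splice_core requires intron offset ±1/±2, got {off}")
        if self.consequence is Consequence.SPLICE_NEAR and off not in SPLICE_NEAR_OFFSETS:
            raise ValueError(f"splice_near requires intron offset in -3,+3..+6, got {off}")
        if (
            off is not None
            and self.consequence not in (Consequence.SPLICE_CORE, Consequence.SPLICE_NEAR)
            and (off in SPLICE_CORE_OFFSETS or off in SPLICE_NEAR_OFFSETS)
        ):
            raise ValueError(
                f"intron offset {off} implies a splice consequence, got {self.consequence}"
            )

    def ac(self, population: Population) -> int:
        if population is Population.ALL:
            return sum(c.ac for c in self.counts.values())
        entry = self.counts.get(population)
        return entry.ac if entry is not None else 0

    def an(self, population: Population) -> int:
        if population is Population.ALL:
            return sum(c.an for c in self.counts.values())
        entry = self.counts.get(population)
        return entry.an if entry is not None else 0

    @property
    def total_ac(self) -> int:
        return self.ac(Population.ALL)


class Verdict(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Missense predictors (the dbNSFP set used for the 7/7 consensus rule).
MISSENSE_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "MutationTaster",
    "MutationAssessor",
    "LRT",
    "FATHMM",
)

#: Splice-site predictors (the 3/3 consensus rule for near-splice variants).
SPLICE_TOOLS: tuple[str, ...] = ("HSF", "NetGene2", "NNSplice")


@dataclass(frozen=True)
class SpliceScore:
    """Wild-type vs mutant splice-site strength from one predictor."""

    wt_score: float = 0.0
    mut_score: float = 0.0
    site_abolished: bool = False
    missing: bool = True

    def __post_init__(self) -> None:
        if self.missing:
            return
        if self.wt_score < 0 or self.mut_score < 0:
            raise ValueError("splice scores must be non-negative")
        if self.wt_score == 0 and not self.site_abolished:
            raise ValueError("wt_score must be positive unless the site is abolished")


@dataclass
class PredictionProfile:
    """In-silico verdicts for one variant: 7 missense slots, 3 splice slots."""

    missense_verdicts: dict[str, Verdict] = field(default_factory=dict)
    splice_scores: dict[str, SpliceScore] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool in MISSENSE_TOOLS:
            self.missense_verdicts.setdefault(tool, Verdict.MISSING)
        for tool in SPLICE_TOOLS:
            self.splice_scores.setdefault(tool, SpliceScore())
        extra = set(self.missense_verdicts) - set(MISSENSE_TOOLS)
        if extra:
            raise ValueError(f"unknown missense tools: {sorted(extra)}")
        extra = set(self.splice_scores) - set(SPLICE_TOOLS)
        if extra:
            raise ValueError(f"unknown splice tools: {sorted(extra)}")

    @classmethod
    def all_damaging(cls) -> "PredictionProfile":
        return cls({t: Verdict.DAMAGING for t in MISSENSE_TOOLS})

    @classmethod
    def all_tolerated(cls) -> "PredictionProfile":
        return cls({t: Verdict.TOLERATED for t in MISSENSE_TOOLS})


class Phenotype(str, enum.Enum):
    """Database phenotype labels (codes follow the field's shorthand)."""

    AFIBRINOGENEMIA = "a"
    DYSFIBRINOGENEMIA = "d"
    HYPOFIBRINOGENEMIA = "h"
    HYPODYSFIBRINOGENEMIA = "hd"
    AMYLOIDOSIS = "m"
    FSD = "fsd"  # fibrinogen storage disease

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Phenotypes whose variants are dominantly inherited and therefore excluded
#: from the recessive (afibrinogenemia) carrier-rate calculation.
DOMINANT_ONLY_PHENOTYPES = frozenset(
    {Phenotype.DYSFIBRINOGENEMIA, Phenotype.HYPODYSFIBRINOGENEMIA, Phenotype.AMYLOIDOSIS}
)


@dataclass(frozen=True)
class DatabaseAnnotation:
    """Whether a variant is reported in fibrinogen-disorder databases."""

    reported: bool = False
    phenotypes: frozenset[Phenotype] = frozenset()

    def __post_init__(self) -> None:
        if self.reported != bool(self.phenotypes):
            raise ValueError("phenotypes must be nonempty iff reported is true")


@dataclass(frozen=True)
class GeneDescriptor:
    name: str
    chrom: str = "4"
    excluded_exon_labels: frozenset[str] = frozenset()


#: Signal-peptide lengths (residues) of the three chains; native-protein
#: numbering = legacy mature-chain numbering + offset.
DEFAULT_SIGNAL_PEPTIDE_OFFSETS: dict[str, int] = {"FGA": 19, "FGB": 30, "FGG": 26}

#: Exons harbouring only low-abundance mRNA isoforms of the relevant chain
#: (FGA exon 6 = alpha-E isoform, FGG exon 10 = gamma' isoform); variants
#: there are excluded from the deleterious set.
DEFAULT_EXCLUDED_EXONS: dict[str, frozenset[str]] = {
    "FGA": frozenset({"6"}),
    "FGB": frozenset(),
    "FGG": frozenset({"10"}),
}


@dataclass
class PanelConfig:
    """Gene panel configuration: genes, excluded exons, numbering offsets."""

    genes: dict[str, GeneDescriptor] = field(default_factory=dict)
    signal_peptide_offsets: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_PEPTIDE_OFFSETS)
    )
    population_sizes: dict[Population, int] = field(
        default_factory=lambda: dict(GNOMAD_SAMPLE_SIZES)
    )

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = {
                g: GeneDescriptor(g, "4", DEFAULT_EXCLUDED_EXONS[g]) for g in GENES
            }

    def excluded_exons(self, gene: str) -> frozenset[str]:
        return self.genes[gene].excluded_exon_labels


class InclusionRule(str, enum.Enum):
    NULL_MUTATION = "null_mutation"
    SPLICE_CORE = "splice_core"
    SPLICE_NEAR_CONSENSUS = "splice_near_consensus"
    DB_REPORTED_MISSENSE = "db_reported_missense"
    MISSENSE_CONSENSUS = "missense_consensus"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ExclusionReason(str, enum.Enum):
    LOW_CONFIDENCE = "low_confidence"
    EXCLUDED_EXON = "excluded_exon"
    ALTERNATIVE_TRANSCRIPT_INTRON = "alternative_transcript_intron"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ClassifiedVariant:
    """A variant plus its deleteriousness decision and eligibility flags."""

    record: VariantRecord
    db: DatabaseAnnotation
    deleterious: bool
    inclusion_rule: InclusionRule
    exclusion_reason: Optional[ExclusionReason]
    recessive_eligible: bool
    dominant_eligible: bool

    def __post_init__(self) -> None:
        if self.deleterious and self.exclusion_reason is not None:
            raise ValueError("a deleterious variant cannot carry an exclusion reason")
        if self.recessive_eligible and not self.dominant_eligible:
            raise ValueError("recessive eligibility implies dominant eligibility")

    @property
    def variant_id(self) -> str:
        return self.record.variant_id

    @property
    def gene(self) -> str:
        return self.record.gene


@dataclass(frozen=True)
class GenePopulationSummary:
    """Collective frequency and recessive prevalence for one (gene, population).

    ``q`` is the collective frequency (summed alternate-allele counts over
    eligible variants divided by the allele-number denominator), ``het_freq``
    the carrier frequency, and the recessive prevalence q^2 * 1e6 counts
    homozygotes plus compound heterozygotes under Hardy-Weinberg equilibrium.
    """

    gene: str
    population: Population
    allele_number: int
    mutated_alleles: int
    q: float
    het_freq: float
    recessive_prevalence_per_1e6: float


@dataclass(frozen=True)
class PanelSummary:
    """Panel-wide summary for one population."""

    population: Population
    recessive_prevalence_per_1e6: float = 0.0
    dominant_allele_number: int = 0
    dominant_alleles: int = 0
    dominant_q: float = 0.0
    dominant_het_freq: float = 0.0
    dominant_prevalence_per_1e3: float = 0.0


def parse_phenotypes(text: str) -> frozenset[Phenotype]:
    """Parse a phenotype cell such as ``"a"`` or ``"d/h"`` into a label set."""
    text = text.strip()
    if not text or text == "-":
        return frozenset()
    labels = set()
    for token in text.replace(",", "/").split("/"):
        token = token.strip().lower()
        if not token:
            continue
        try:
            labels.add(Phenotype(token))
        except ValueError:
            raise ValueError(
                f"unknown phenotype code {token!r}; allowed: "
                f"{', '.join(p.value for p in Phenotype)}"
            ) from None
    return frozenset(labels)


def format_phenotypes(phenotypes: frozenset[Phenotype]) -> str:
    if not phenotypes:
        return ""
    return "/".join(sorted(p.value for p in phenotypes))
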