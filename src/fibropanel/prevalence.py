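"""Carrier rates and prevalence of inherited fibrinogen disorders.

For a gene *g* and population *p*, the collective frequency is

    q = (sum of alternate-allele counts over eligible variants) / AN

where the allele-number denominator AN is the maximum allele number among
the eligible variants of the gene in that population (allele numbers vary
slightly by site with sequencing success; the maximum is the number of
chromosomes the best-covered site saw).  Under Hardy-Weinberg equilibrium:

* carrier (heterozygote) frequency = 2q;
* recessive prevalence (homozygotes plus compound heterozygotes for the
  same gene) = q^2, reported per 10^6 individuals, summed over the three
  genes for the panel-wide rate;
* dominant prevalence pools the eligible variants of all three genes into a
  single collective frequency and reports 2q per 10^3 individuals.

The 2q carrier frequency (rather than 2q(1-q)) is the module default; the
exact Hardy-Weinberg form is available via ``hw_exact=True``.
"""
from __future__ import annotations

import logging
import math
from typing import Callable, Iterable, Optional, Sequence

from .model import (
    GENES,
    OBSERVED_POPULATIONS,
    ClassifiedVariant,
    GenePopulationSummary,
    PanelSummary,
    Population,
)

logger = logging.getLogger("fibropanel")

Mode = str  # "recessive" | "dominant"


def _eligible(
    variants: Sequence[ClassifiedVariant], mode: Mode, gene: Optional[str] = None
) -> list[ClassifiedVariant]:
    if mode == "recessive":
        pool = [v for v in variants if v.recessive_eligible]
    elif mode == "dominant":
        pool = [v for v in variants if v.dominant_eligible]
    else:
        raise ValueError(f"mode must be 'recessive' or 'dominant', got {mode!r}")
    if gene is not None:
        pool = [v for v in pool if v.gene == gene]
    return pool


def gene_population_denominator(
    variants: Sequence[ClassifiedVariant],
    gene: str,
    population: Population,
    mode: Mode = "recessive",
) -> int:
    """Allele-number denominator: the maximum AN over eligible variants.

    Sites with ``an == 0`` in the population (not called there) are skipped.
    For the derived ALL group the per-variant total AN (summed over the
    eight observed groups) is maximised.
    """
    pool = _eligible(variants, mode, gene)
    ans = [v.record.an(population) for v in pool]
    ans = [a for a in ans if a > 0]
    if not ans:
        logger.warning("no eligible variant with an>0 for %s/%s; denominator 0", gene, population)
        return 0
    return max(ans)


def pooled_denominator(
    variants: Sequence[ClassifiedVariant], population: Population, mode: Mode = "dominant"
) -> int:
    """Denominator for the pooled (cross-gene) dominant calculation."""
    pool = _eligible(variants, mode)
    ans = [v.record.an(population) for v in pool]
    ans = [a for a in ans if a > 0]
    if not ans:
        logger.warning("no eligible variant with an>0 pooled in %s; denominator 0", population)
        return 0
    return max(ans)


def mutated_alleles(
    variants: Sequence[ClassifiedVariant],
    gene: Optional[str],
    population: Population,
    mode: Mode = "recessive",
) -> int:
    return sum(v.record.ac(population) for v in _eligible(variants, mode, gene))


def collective_frequency(
    variants: Sequence[ClassifiedVariant],
    gene: str,
    population: Population,
    mode: Mode = "recessive",
) -> float:
    """Summed allele count of eligible variants over the denominator."""
    denom = gene_population_denominator(variants, gene, population, mode)
    if denom == 0:
        return 0.0
    q = mutated_alleles(variants, gene, population, mode) / denom
    assert 0.0 <= q <= 1.0, f"collective frequency {q} outside [0, 1]"
    return q


def heterozygote_frequency(q: float, hw_exact: bool = False) -> float:
    """Carrier frequency: 2q, or 2q(1-q) with ``hw_exact``."""
    if not 0.0 <= q <= 0.5:
        raise ValueError(f"q must lie in [0, 0.5], got {q}")
    return 2.0 * q * (1.0 - q) if hw_exact else 2.0 * q


def recessive_prevalence(q: float) -> float:
    """Expected biallelic-carrier frequency q^2, per 10^6 individuals."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return q * q * 1e6


def gene_population_summary(
    variants: Sequence[ClassifiedVariant],
    gene: str,
    population: Population,
    mode: Mode = "recessive",
    hw_exact: bool = False,
) -> GenePopulationSummary:
    denom = gene_population_denominator(variants, gene, population, mode)
    alleles = mutated_alleles(variants, gene, population, mode)
    q = alleles / denom if denom else 0.0
    return GenePopulationSummary(
        gene=gene,
        population=population,
        allele_number=denom,
        mutated_alleles=alleles,
        q=q,
        het_freq=heterozygote_frequency(q, hw_exact),
        recessive_prevalence_per_1e6=recessive_prevalence(q),
    )


def recessive_summaries(
    variants: Sequence[ClassifiedVariant],
    genes: Sequence[str] = GENES,
    populations: Optional[Sequence[Population]] = None,
    hw_exact: bool = False,
) -> list[GenePopulationSummary]:
    """Per-gene, per-population recessive summaries (ALL group first)."""
    pops = list(populations) if populations is not None else [Population.ALL, *OBSERVED_POPULATIONS]
    return [
        gene_population_summary(variants, g, p, "recessive", hw_exact)
        for g in genes
        for p in pops
    ]


def panel_recessive_prevalence(summaries: Sequence[GenePopulationSummary]) -> float:
    """Panel-wide recessive prevalence: sum of per-gene q^2 * 1e6.

    All summaries must refer to the same population, one per gene.
    """
    seen: set[str] = set()
    pops = {s.population for s in summaries}
    if len(pops) > 1:
        raise ValueError(f"summaries span several populations: {sorted(p.value for p in pops)}")
    total = 0.0
    for s in summaries:
        if s.gene in seen:
            raise ValueError(f"duplicate gene {s.gene} for population {s.population}")
        seen.add(s.gene)
        total += s.recessive_prevalence_per_1e6
    return total


def dominant_summary(
    variants: Sequence[ClassifiedVariant],
    population: Population,
    hw_exact: bool = False,
) -> PanelSummary:
    """Pooled dominant carrier rate for one population (2q per 10^3)."""
    denom = pooled_denominator(variants, population, "dominant")
    alleles = mutated_alleles(variants, None, population, "dominant")
    q = alleles / denom if denom else 0.0
    het = heterozygote_frequency(q, hw_exact)
    rec_summaries = [
        gene_population_summary(variants, g, population, "recessive", hw_exact) for g in GENES
    ]
    return PanelSummary(
        population=population,
        recessive_prevalence_per_1e6=panel_recessive_prevalence(rec_summaries),
        dominant_allele_number=denom,
        dominant_alleles=alleles,
        dominant_q=q,
        dominant_het_freq=het,
        dominant_prevalence_per_1e3=het * 1e3,
    )


def panel_summaries(
    variants: Sequence[ClassifiedVariant], hw_exact: bool = False
) -> dict[Population, PanelSummary]:
    return {
        pop: dominant_summary(variants, pop, hw_exact)
        for pop in (Population.ALL, *OBSERVED_POPULATIONS)
    }


# ---------------------------------------------------------------------------
# sensitivity recomputations
# ---------------------------------------------------------------------------

def exclude_by_name(*names: str) -> Callable[[ClassifiedVariant], bool]:
    """Predicate dropping variants named ``GENE:p.Xxx123Yyy``, a bare
    protein change, a variant_id, or an rsid."""

    def predicate(v: ClassifiedVariant) -> bool:
        for name in names:
            gene, _, rest = name.partition(":")
            if rest:
                if v.gene == gene and v.record.protein_change == rest:
                    return False
            elif name in (v.variant_id, v.record.protein_change, v.record.rsid):
                return False
        return True

    return predicate


def exclude_unreported() -> Callable[[ClassifiedVariant], bool]:
    """Predicate keeping only database-reported variants."""
    return lambda v: v.db.reported


def sensitivity_exclude(
    variants: Sequence[ClassifiedVariant],
    predicate: Callable[[ClassifiedVariant], bool],
    hw_exact: bool = False,
) -> dict:
    """Recompute every summary on the variants passing ``predicate``.

    Returns baseline and filtered panel summaries per population, plus the
    prevalence deltas (filtered minus baseline).
    """
    kept = [v for v in variants if predicate(v)]
    baseline = panel_summaries(variants, hw_exact)
    filtered = panel_summaries(kept, hw_exact)
    deltas = {
        pop: {
            "recessive_per_1e6": filtered[pop].recessive_prevalence_per_1e6
            - baseline[pop].recessive_prevalence_per_1e6,
            "dominant_per_1e3": filtered[pop].dominant_prevalence_per_1e3
            - baseline[pop].dominant_prevalence_per_1e3,
        }
        for pop in baseline
    }
    return {
        "n_excluded": len(variants) - len(kept),
        "kept": kept,
        "baseline": baseline,
        "filtered": filtered,
        "deltas": deltas,
    }


# ---------------------------------------------------------------------------
# presentation (rounding happens only here; internal math is unrounded)
# ---------------------------------------------------------------------------

def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def format_frequency(q: float) -> str:
    """Table style: 3 significant figures, '-' for zero."""
    if q == 0:
        return "-"
    return f"{round_sig(q, 3):g}"


def format_prevalence_1e6(x: float) -> str:
    """Per-10^6 style: two decimals, two significant figures below 0.095."""
    if x == 0:
        return "-"
    if x < 0.095:
        return f"{round_sig(x, 2):g}"
    return f"{x:.2f}"


def rounded_prevalence_1e6(x: float) -> float:
    return round_sig(x, 2) if 0 < x < 0.095 else round(x, 2)


def format_prevalence_1e3(x: float) -> str:
    """Per-10^3 style: nearest integer, '-' for zero."""
    return "-" if x == 0 else f"{round(x):d}"


def panel_recessive_table(
    variants: Sequence[ClassifiedVariant], sum_rounded: bool = True
) -> dict[Population, float]:
    """Panel-wide recessive prevalence per population.

    With ``sum_rounded`` the per-gene prevalences are rounded to table
    precision before summing, matching the presentation convention of the
    per-gene table; otherwise the unrounded q^2 values are summed.
    """
    out: dict[Population, float] = {}
    for pop in (Population.ALL, *OBSERVED_POPULATIONS):
        per_gene = [
            gene_population_summary(variants, g, pop, "recessive").recessive_prevalence_per_1e6
            for g in GENES
        ]
        if sum_rounded:
            out[pop] = round(sum(rounded_prevalence_1e6(x) for x in per_gene), 3)
        else:
            out[pop] = sum(per_gene)
    return out
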