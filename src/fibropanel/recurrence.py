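"""Recurrent and ethnic-specific mutations; hotspot lookup by residue.

For each (gene, population) stratum the *share* of a variant is its
alternate-allele count divided by the stratum's total mutated alleles; the
*allele frequency* divides by the stratum's allele-number denominator.
Shares over all eligible variants of a stratum sum to one.

By default shares are computed on the recessive-eligible set (the set behind
the per-gene carrier-rate tables); ``mode="dominant"`` recomputes them on the
full deleterious set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .model import ClassifiedVariant, Population
from .nomenclature import ResidueName, parse_protein_change
from .prevalence import Mode, _eligible, gene_population_denominator, mutated_alleles

logger = logging.getLogger("fibropanel")


@dataclass(frozen=True)
class RecurrenceRow:
    gene: str
    population: Population
    variant_id: str
    rsid: Optional[str]
    protein_change: Optional[str]
    share_of_mutated_alleles: float
    allele_freq: float


def mutation_share(
    classified: Sequence[ClassifiedVariant],
    gene: str,
    population: Population,
    variant_id: str,
    mode: Mode = "recessive",
) -> tuple[float, float]:
    """(share of mutated alleles, allele frequency) for one variant."""
    total = mutated_alleles(classified, gene, population, mode)
    if total == 0:
        raise ValueError(f"no mutated alleles for {gene} in {population.value}")
    matches = [v for v in _eligible(classified, mode, gene) if v.variant_id == variant_id]
    if not matches:
        raise ValueError(f"variant {variant_id} not eligible in {gene} under mode {mode!r}")
    ac = sum(v.record.ac(population) for v in matches)
    denom = gene_population_denominator(classified, gene, population, mode)
    return ac / total, (ac / denom if denom else 0.0)


def recurrence_report(
    classified: Sequence[ClassifiedVariant],
    min_share: float = 0.10,
    mode: Mode = "recessive",
    populations: Optional[Sequence[Population]] = None,
) -> list[RecurrenceRow]:
    """Rows with share >= ``min_share``, sorted by gene, population,
    then descending share."""
    from .model import GENES, OBSERVED_POPULATIONS

    pops = list(populations) if populations is not None else list(OBSERVED_POPULATIONS)
    rows: list[RecurrenceRow] = []
    for gene in GENES:
        pool = _eligible(classified, mode, gene)
        for pop in pops:
            total = sum(v.record.ac(pop) for v in pool)
            if total == 0:
                continue
            denom = gene_population_denominator(classified, gene, pop, mode)
            for v in pool:
                ac = v.record.ac(pop)
                if ac == 0:
                    continue
                share = ac / total
                if share >= min_share:
                    rows.append(
                        RecurrenceRow(
                            gene=gene,
                            population=pop,
                            variant_id=v.variant_id,
                            rsid=v.record.rsid,
                            protein_change=v.record.protein_change,
                            share_of_mutated_alleles=share,
                            allele_freq=ac / denom if denom else 0.0,
                        )
                    )
    pop_order = {p: i for i, p in enumerate(pops)}
    rows.sort(
        key=lambda r: (r.gene, pop_order[r.population], -r.share_of_mutated_alleles)
    )
    return rows


def hotspot_lookup(
    classified: Sequence[ClassifiedVariant],
    hotspots: Sequence[Union[ResidueName, str]],
    offsets: Optional[dict[str, int]] = None,
    mode: Mode = "dominant",
) -> dict[str, int]:
    """World-wide (ALL group) mutated-allele counts for named hotspots.

    Hotspots may be given as :class:`ResidueName` objects in either numbering
    scheme (legacy names are converted through the signal-peptide offsets) or
    as ``"GENE:p.Xxx123Yyy"`` strings in native numbering.  Absent residues
    yield a zero count with a warning.
    """
    pool = _eligible(classified, mode)
    results: dict[str, int] = {}
    for spot in hotspots:
        if isinstance(spot, str):
            gene, _, change = spot.partition(":")
            spot = parse_protein_change(gene, change, scheme="native")
        native = spot.to_native(offsets)
        key = f"{native.gene}:{native.protein_change}"
        count = sum(
            v.record.total_ac
            for v in pool
            if v.gene == native.gene and v.record.protein_change == native.protein_change
        )
        if count == 0:
            logger.warning("hotspot %s not found in the eligible set", key)
        results[key] = count
    return results
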