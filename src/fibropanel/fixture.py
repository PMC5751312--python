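"""Deterministic reference dataset reconstructing the published aggregates.

The gnomAD release-2.0 allele-level data behind the fibrinogen burden
analysis cannot be redistributed, but every per-(gene, population) aggregate
is printed: summed alternate-allele counts and allele-number denominators
for the recessive- and dominant-eligible sets, the allele counts of the
named recurrent/founder/hotspot variants, the unique-mutation spectrum per
gene with its database-reported subset, and the database-reported allele
totals implied by the sensitivity reanalysis.

:func:`paper_fixture` builds a synthetic variant table that reproduces all
of those aggregates exactly: the named variants carry their printed allele
counts, and the remaining mass is filled with anonymous variants (mostly
singletons) whose class mix matches the per-gene spectrum.  Per-variant
allele numbers follow the published convention that allele numbers vary
slightly by site: each variant of a gene carries that gene's per-population
allele numbers with a small deficit on the NFE group, and one designated
variant per gene carries the full NFE allele number (deficit moved to OTH),
which makes both the per-population maxima and the panel-wide (ALL) maxima
equal the printed denominators.

The builder re-checks every aggregate before returning and raises if the
reconciliation fails, so the fixture cannot silently drift.
"""
from __future__ import annotations

import itertools
from typing import Iterator, Optional

from .model import (
    GENES,
    OBSERVED_POPULATIONS,
    SPLICE_TOOLS,
    AlleleCount,
    Consequence,
    DatabaseAnnotation,
    DOMINANT_ONLY_PHENOTYPES,
    FilterStatus,
    Population,
    PredictionProfile,
    SpliceScore,
    VariantRecord,
    Verdict,
    parse_phenotypes,
)

P = Population

#: Published per-gene allele-number denominators (recessive-eligible set).
GENE_ALLELE_NUMBERS: dict[str, dict[Population, int]] = {
    "FGA": {P.AFR: 24030, P.AMR: 34414, P.ASJ: 10148, P.EAS: 18868, P.FIN: 25794,
            P.NFE: 126628, P.SAS: 30782, P.OTH: 6462, P.ALL: 277108},
    "FGB": {P.AFR: 24032, P.AMR: 34418, P.ASJ: 10152, P.EAS: 18868, P.FIN: 25790,
            P.NFE: 126646, P.SAS: 30782, P.OTH: 6466, P.ALL: 277144},
    "FGG": {P.AFR: 24034, P.AMR: 34394, P.ASJ: 10150, P.EAS: 18854, P.FIN: 25790,
            P.NFE: 126630, P.SAS: 30782, P.OTH: 6462, P.ALL: 277080},
}

#: Published summed allele counts of the recessive-eligible set.
RECESSIVE_ALLELES: dict[str, dict[Population, int]] = {
    "FGA": {P.AFR: 9, P.AMR: 41, P.ASJ: 0, P.EAS: 8, P.FIN: 0, P.NFE: 67, P.SAS: 21, P.OTH: 8},
    "FGB": {P.AFR: 11, P.AMR: 39, P.ASJ: 0, P.EAS: 12, P.FIN: 4, P.NFE: 137, P.SAS: 23, P.OTH: 5},
    "FGG": {P.AFR: 64, P.AMR: 56, P.ASJ: 13, P.EAS: 13, P.FIN: 40, P.NFE: 608, P.SAS: 43, P.OTH: 19},
}

#: Published pooled dominant-eligible aggregates.
DOMINANT_ALLELE_NUMBERS: dict[Population, int] = {
    P.AFR: 24036, P.AMR: 34418, P.ASJ: 10152, P.EAS: 18868, P.FIN: 25794,
    P.NFE: 126646, P.SAS: 30782, P.OTH: 6466, P.ALL: 277144,
}
DOMINANT_ALLELES: dict[Population, int] = {
    P.AFR: 166, P.AMR: 176, P.ASJ: 44, P.EAS: 35, P.FIN: 44, P.NFE: 922,
    P.SAS: 90, P.OTH: 47,
}

#: Published unique-mutation spectrum: gene -> class -> (total, db-reported).
SPECTRUM: dict[str, dict[str, tuple[int, int]]] = {
    "FGA": {"frameshift": (17, 5), "nonsense": (20, 11), "splicing": (6, 2),
            "missense": (30, 10), "inframe_indel": (6, 2)},
    "FGB": {"frameshift": (4, 0), "nonsense": (5, 3), "splicing": (3, 1),
            "missense": (41, 7), "inframe_indel": (0, 0)},
    "FGG": {"frameshift": (6, 1), "nonsense": (4, 1), "splicing": (7, 1),
            "missense": (39, 12), "inframe_indel": (1, 0)},
}

#: Database-reported alternate-allele totals of the recessive-eligible set
#: (panel-wide), implied by the reported-variants-only reanalysis.
REPORTED_RECESSIVE_ALLELES: dict[str, int] = {"FGA": 50, "FGB": 110, "FGG": 716}

# per-gene deficit between the sum of per-population allele numbers and the
# published panel-wide (ALL) allele number
_DEFICIT = {
    g: sum(GENE_ALLELE_NUMBERS[g][p] for p in OBSERVED_POPULATIONS)
    - GENE_ALLELE_NUMBERS[g][P.ALL]
    for g in GENES
}

_ANON_BASE_POS = {"FGA": 155_505_000, "FGB": 155_486_000, "FGG": 155_526_000}
_ANON_EXONS = {"FGA": ["1", "2", "3", "4", "5"],
               "FGB": ["1", "2", "3", "4", "5", "6", "7", "8"],
               "FGG": ["1", "2", "3", "4", "5", "6", "7", "8", "9"]}


def _an_profile(gene: str, anchor: bool = False) -> dict[Population, int]:
    base = {p: GENE_ALLELE_NUMBERS[gene][p] for p in OBSERVED_POPULATIONS}
    if anchor:
        base[P.OTH] -= _DEFICIT[gene]
    else:
        base[P.NFE] -= _DEFICIT[gene]
    return base


def _spread(n: int, budget: dict[Population, int]) -> list[dict[Population, int]]:
    """Deal ``sum(budget)`` alleles over ``n`` variants, every variant >= 1,
    exhausting each population budget in canonical order."""
    total = sum(budget.values())
    if n < 1 or total < n:
        raise ValueError(f"cannot spread {total} alleles over {n} variants")
    remaining = {p: budget.get(p, 0) for p in OBSERVED_POPULATIONS if budget.get(p, 0) > 0}
    order = [p for p in OBSERVED_POPULATIONS if p in remaining]
    allocs: list[dict[Population, int]] = [dict() for _ in range(n)]
    cursor = 0
    for alloc in allocs:
        while remaining[order[cursor]] == 0:
            cursor += 1
        pop = order[cursor]
        alloc[pop] = alloc.get(pop, 0) + 1
        remaining[pop] -= 1
    i = 0
    for pop in order:
        while remaining[pop] > 0:
            alloc = allocs[i % n]
            alloc[pop] = alloc.get(pop, 0) + 1
            remaining[pop] -= 1
            i += 1
    return allocs


def _profile(kind: str) -> PredictionProfile:
    if kind == "missense7":
        return PredictionProfile.all_damaging()
    if kind == "tolerated":
        return PredictionProfile.all_tolerated()
    if kind == "mixed5":
        verds = {t: Verdict.DAMAGING for t in PredictionProfile.all_damaging().missense_verdicts}
        tools = list(verds)
        verds[tools[0]] = Verdict.TOLERATED
        verds[tools[1]] = Verdict.TOLERATED
        return PredictionProfile(verds)
    if kind == "splice3":
        return PredictionProfile(
            {}, {t: SpliceScore(10.0, 3.0, False, missing=False) for t in SPLICE_TOOLS}
        )
    if kind == "none":
        return PredictionProfile()
    raise ValueError(kind)


class _Builder:
    def __init__(self) -> None:
        self.records: list[VariantRecord] = []
        self.annotations: dict[str, tuple[PredictionProfile, DatabaseAnnotation]] = {}
        self._pos = {g: itertools.count(0) for g in GENES}
        self._residue = {g: itertools.count(40) for g in GENES}
        self._exon = {g: itertools.cycle(_ANON_EXONS[g]) for g in GENES}
        self._core_offset = itertools.cycle([1, -2, 2, -1])
        self._near_offset = itertools.cycle([3, 5, -3, 6, 4])

    def _next_pos(self, gene: str) -> int:
        return _ANON_BASE_POS[gene] + 13 * next(self._pos[gene])

    def add(
        self,
        gene: str,
        consequence: Consequence,
        ac: dict[Population, int],
        phenotypes: str = "",
        profile: str = "none",
        rsid: Optional[str] = None,
        pos: Optional[int] = None,
        protein_change: Optional[str] = None,
        hgvs_c: Optional[str] = None,
        anchor: bool = False,
        an_override: Optional[dict[Population, int]] = None,
        exon_label: Optional[str] = None,
        intron_offset: Optional[int] = None,
        filter_status: FilterStatus = FilterStatus.PASS,
        alt_tx_only: bool = False,
    ) -> None:
        pos = pos if pos is not None else self._next_pos(gene)
        an = an_override if an_override is not None else _an_profile(gene, anchor)
        i = pos % 4
        ref, alt = "ACGT"[i], "ACGT"[(i + 1) % 4]
        if consequence is Consequence.FRAMESHIFT:
            ref, alt = ref + alt, ref
        elif consequence is Consequence.INFRAME_INDEL:
            ref, alt = ref + "CGT", ref
        if consequence in (Consequence.SPLICE_CORE, Consequence.SPLICE_NEAR):
            if intron_offset is None:
                cyc = self._core_offset if consequence is Consequence.SPLICE_CORE else self._near_offset
                intron_offset = next(cyc)
        elif exon_label is None:
            exon_label = next(self._exon[gene])
        if (
            protein_change is None
            and consequence in (Consequence.MISSENSE, Consequence.SYNONYMOUS)
        ):
            aa_alt = "=" if consequence is Consequence.SYNONYMOUS else "Gly"
            protein_change = f"p.Ala{next(self._residue[gene])}{aa_alt}"
        counts = {
            p: AlleleCount(ac.get(p, 0), an[p]) for p in OBSERVED_POPULATIONS
        }
        vid = f"4-{pos}-{ref}-{alt}"
        if vid in self.annotations:
            raise AssertionError(f"duplicate fixture variant id {vid}")
        phenos = parse_phenotypes(phenotypes)
        self.records.append(
            VariantRecord(
                variant_id=vid, rsid=rsid, gene=gene, chrom="4", pos=pos,
                ref=ref, alt=alt, consequence=consequence, counts=counts,
                protein_change=protein_change, hgvs_c=hgvs_c,
                intron_offset=intron_offset, exon_label=exon_label,
                on_alternative_transcript_only=alt_tx_only,
                filter_status=filter_status,
            )
        )
        self.annotations[vid] = (
            _profile(profile),
            DatabaseAnnotation(reported=bool(phenos), phenotypes=phenos),
        )

    def add_group(
        self,
        gene: str,
        spec: list[tuple[Consequence, int, str, str]],
        budget: dict[Population, int],
    ) -> None:
        """Add anonymous variants: (consequence, count, phenotypes, profile)
        tuples sharing one population allele budget."""
        flat: list[tuple[Consequence, str, str]] = []
        for csq, count, phenotypes, profile in spec:
            flat.extend([(csq, phenotypes, profile)] * count)
        for (csq, phenotypes, profile), alloc in zip(flat, _spread(len(flat), budget)):
            self.add(gene, csq, alloc, phenotypes=phenotypes, profile=profile)


def _build() -> _Builder:
    b = _Builder()
    M, F, N, SC, SN, IF = (
        Consequence.MISSENSE, Consequence.FRAMESHIFT, Consequence.NONSENSE,
        Consequence.SPLICE_CORE, Consequence.SPLICE_NEAR, Consequence.INFRAME_INDEL,
    )

    # --- named recessive-eligible variants (recurrent / ethnic-specific) ---
    b.add("FGA", F, {P.AMR: 10, P.NFE: 8}, rsid="rs773619297", pos=155_506_927,
          protein_change="p.Gly552AlafsTer16", anchor=True)
    b.add("FGA", M, {P.AMR: 12}, rsid="rs748106542", pos=155_508_067,
          protein_change="p.Asp172Asn", profile="missense7")
    b.add("FGA", SC, {P.NFE: 12}, rsid="rs146387238", pos=155_508_663,
          hgvs_c="c.510+1G>T", intron_offset=1, phenotypes="a")
    b.add("FGB", M, {P.AMR: 16}, rsid="rs774502903", pos=155_487_641,
          protein_change="p.Gly103Arg", profile="missense7", anchor=True)
    b.add("FGB", M, {P.NFE: 70}, rsid="rs370703973", pos=155_489_611,
          protein_change="p.Tyr266Cys", profile="missense7", phenotypes="h")
    b.add("FGB", M, {P.NFE: 14}, rsid="rs777451745", pos=155_490_421,
          protein_change="p.Ala307Val", profile="missense7", phenotypes="h")
    b.add("FGB", M, {P.SAS: 6}, rsid="rs762523152", pos=155_490_854,
          protein_change="p.Leu383Val", profile="missense7")
    b.add("FGB", M, {P.SAS: 8}, rsid="rs765571602", pos=155_491_770,
          protein_change="p.Met482Val", profile="missense7")
    b.add("FGG", M, {P.AFR: 35}, rsid="rs145051028", pos=155_529_735,
          protein_change="p.Ser245Phe", profile="missense7", anchor=True)
    b.add("FGG", M,
          {P.AFR: 18, P.AMR: 11, P.ASJ: 13, P.FIN: 29, P.NFE: 456, P.SAS: 12},
          rsid="rs148685782", pos=155_533_035, protein_change="p.Ala108Gly",
          profile="missense7", phenotypes="h")
    b.add("FGG", M, {P.AMR: 20}, rsid="rs776288074", pos=155_530_871,
          protein_change="p.Tyr193His", profile="missense7")
    b.add("FGG", M, {P.AMR: 13, P.FIN: 11, P.NFE: 91, P.SAS: 20},
          rsid="rs138511699", pos=155_533_337, protein_change="p.Thr47Ile",
          profile="missense7", phenotypes="h")

    # --- anonymous recessive-eligible variants, database-reported ---
    b.add_group("FGA", [(F, 4, "a", "none"), (N, 9, "a", "none"), (N, 2, "a/h", "none"),
                        (SC, 1, "a", "none"), (M, 1, "h", "missense7"), (IF, 2, "a", "missense7")],
                {P.NFE: 30, P.SAS: 8})
    b.add_group("FGB", [(N, 2, "h", "none"), (N, 1, "a/h", "none"), (SC, 1, "h", "none"),
                        (M, 1, "a", "missense7"), (M, 2, "h", "missense7")],
                {P.NFE: 26})
    b.add_group("FGG", [(F, 1, "a", "none"), (N, 1, "a", "none"), (SC, 1, "a", "none"),
                        (M, 1, "h", "missense7")],
                {P.NFE: 42})

    # --- anonymous recessive-eligible variants, never reported ---
    b.add_group("FGA", [(F, 11, "", "none"), (N, 9, "", "none"), (SC, 2, "", "none"),
                        (SN, 2, "", "splice3"), (M, 19, "", "missense7"), (IF, 4, "", "missense7")],
                {P.AFR: 9, P.AMR: 19, P.EAS: 8, P.NFE: 17, P.SAS: 13, P.OTH: 8})
    b.add_group("FGB", [(F, 4, "", "none"), (N, 2, "", "none"), (SC, 1, "", "none"),
                        (SN, 1, "", "splice3"), (M, 31, "", "missense7")],
                {P.AFR: 11, P.AMR: 23, P.EAS: 12, P.FIN: 4, P.NFE: 27, P.SAS: 9, P.OTH: 5})
    b.add_group("FGG", [(F, 5, "", "none"), (N, 3, "", "none"), (SC, 3, "", "none"),
                        (SN, 3, "", "splice3"), (M, 25, "", "missense7"), (IF, 1, "", "missense7")],
                {P.AFR: 11, P.AMR: 12, P.EAS: 13, P.NFE: 19, P.SAS: 11, P.OTH: 19})

    # --- dominant-only variants (dys-/hypodysfibrinogenemia, amyloidosis) ---
    # dysfibrinogenemia and renal-amyloidosis hotspots
    b.add("FGA", M, {P.NFE: 1}, phenotypes="d", profile="mixed5",
          protein_change="p.Arg35Cys")
    b.add("FGA", M, {P.NFE: 5}, phenotypes="d", profile="mixed5",
          protein_change="p.Arg35His")
    b.add("FGA", M, {P.ASJ: 19, P.NFE: 10}, phenotypes="m", profile="tolerated",
          protein_change="p.Glu545Lys")
    b.add("FGA", M, {P.NFE: 1}, phenotypes="m", profile="tolerated",
          protein_change="p.Glu545Val")
    b.add("FGG", M, {P.NFE: 2}, phenotypes="d", profile="mixed5",
          protein_change="p.Arg301His")
    # anonymous dominant-only mass
    b.add("FGA", F, {P.AFR: 10}, phenotypes="d/h")
    b.add("FGA", M, {P.AFR: 10}, phenotypes="m", profile="tolerated")
    b.add("FGA", M, {P.AFR: 20}, phenotypes="d", profile="missense7")
    b.add("FGA", M, {P.ASJ: 12}, phenotypes="d", profile="missense7")
    b.add("FGA", M, {P.NFE: 40}, phenotypes="d", profile="missense7")
    b.add("FGA", M, {P.OTH: 5}, phenotypes="d", profile="missense7")
    b.add("FGB", M, {P.AFR: 1}, phenotypes="d", profile="missense7",
          an_override={**_an_profile("FGB"), P.AFR: 24_036, P.NFE: 126_632})
    b.add("FGB", M, {P.AFR: 1}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.AFR: 40}, phenotypes="d/h", profile="missense7")
    b.add("FGG", M, {P.AMR: 40}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.EAS: 2}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.NFE: 30}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.SAS: 3}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.OTH: 10}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.NFE: 15}, phenotypes="d", profile="missense7")
    b.add("FGG", M, {P.NFE: 6}, phenotypes="d", profile="missense7")

    # --- non-deleterious showcase rows (do not enter any aggregate) ---
    b.add("FGA", Consequence.SYNONYMOUS, {P.NFE: 5})
    b.add("FGB", M, {P.AFR: 3}, profile="mixed5")
    b.add("FGA", M, {P.NFE: 7}, profile="missense7", exon_label="6")
    b.add("FGG", F, {P.NFE: 2}, filter_status=FilterStatus.LOW_CONFIDENCE)
    b.add("FGG", SN, {P.NFE: 1}, profile="splice3", intron_offset=5, alt_tx_only=True)
    return b


def _reconcile(b: _Builder) -> None:
    """Re-derive every published aggregate from the rows; raise on mismatch."""
    def err(msg: str) -> None:
        raise AssertionError(f"fixture reconciliation failed: {msg}")

    excluded_exons = {"FGA": {"6"}, "FGB": set(), "FGG": {"10"}}
    dominant: dict[str, list[VariantRecord]] = {g: [] for g in GENES}
    recessive: dict[str, list[VariantRecord]] = {g: [] for g in GENES}
    reported: set[str] = set()
    for r in b.records:
        profile, db = b.annotations[r.variant_id]
        if r.filter_status is not FilterStatus.PASS:
            continue
        if r.exon_label in excluded_exons[r.gene]:
            continue
        if r.on_alternative_transcript_only:
            continue
        if r.consequence in (Consequence.SYNONYMOUS, Consequence.OTHER):
            continue
        if r.consequence in (Consequence.MISSENSE, Consequence.INFRAME_INDEL):
            if not db.reported and not all(
                v is Verdict.DAMAGING for v in profile.missense_verdicts.values()
            ):
                continue
        if r.consequence is Consequence.SPLICE_NEAR:
            ok = all(
                (not s.missing) and (s.site_abolished or s.mut_score < 0.5 * s.wt_score)
                for s in profile.splice_scores.values()
            )
            if not ok:
                continue
        dominant[r.gene].append(r)
        if db.reported:
            reported.add(r.variant_id)
        if not (db.phenotypes & DOMINANT_ONLY_PHENOTYPES):
            recessive[r.gene].append(r)

    for gene in GENES:
        for pop in OBSERVED_POPULATIONS:
            got = sum(r.ac(pop) for r in recessive[gene])
            want = RECESSIVE_ALLELES[gene][pop]
            if got != want:
                err(f"{gene}/{pop.value} recessive alleles {got} != {want}")
            got_an = max(r.an(pop) for r in recessive[gene])
            if got_an != GENE_ALLELE_NUMBERS[gene][pop]:
                err(f"{gene}/{pop.value} allele number {got_an}")
        got_an = max(r.an(P.ALL) for r in recessive[gene])
        if got_an != GENE_ALLELE_NUMBERS[gene][P.ALL]:
            err(f"{gene}/ALL allele number {got_an}")
        got_rep = sum(r.ac(P.ALL) for r in recessive[gene] if r.variant_id in reported)
        if got_rep != REPORTED_RECESSIVE_ALLELES[gene]:
            err(f"{gene} reported recessive alleles {got_rep}")

    pool = [r for g in GENES for r in dominant[g]]
    for pop in OBSERVED_POPULATIONS:
        got = sum(r.ac(pop) for r in pool)
        if got != DOMINANT_ALLELES[pop]:
            err(f"dominant alleles {pop.value}: {got} != {DOMINANT_ALLELES[pop]}")
        got_an = max(r.an(pop) for r in pool)
        if got_an != DOMINANT_ALLELE_NUMBERS[pop]:
            err(f"dominant allele number {pop.value}: {got_an}")
    if max(r.an(P.ALL) for r in pool) != DOMINANT_ALLELE_NUMBERS[P.ALL]:
        err("dominant ALL allele number")
    if sum(r.ac(P.ALL) for r in pool) != sum(DOMINANT_ALLELES.values()):
        err("dominant total alleles")

    type_of = {
        Consequence.FRAMESHIFT: "frameshift", Consequence.NONSENSE: "nonsense",
        Consequence.SPLICE_CORE: "splicing", Consequence.SPLICE_NEAR: "splicing",
        Consequence.MISSENSE: "missense", Consequence.INFRAME_INDEL: "inframe_indel",
    }
    for gene in GENES:
        for mtype, (want_total, want_rep) in SPECTRUM[gene].items():
            rows = [r for r in dominant[gene] if type_of[r.consequence] == mtype]
            if len(rows) != want_total:
                err(f"{gene} {mtype} unique count {len(rows)} != {want_total}")
            n_rep = sum(r.variant_id in reported for r in rows)
            if n_rep != want_rep:
                err(f"{gene} {mtype} reported count {n_rep} != {want_rep}")


def paper_fixture() -> tuple[
    list[VariantRecord], dict[str, tuple[PredictionProfile, DatabaseAnnotation]]
]:
    """The reconciled reference dataset (variant table, annotation table)."""
    b = _build()
    _reconcile(b)
    return b.records, b.annotations
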