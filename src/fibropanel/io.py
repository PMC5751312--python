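"""Readers and writers for variant tables, annotations and panel configs.

The canonical internal format is a UTF-8, tab-separated table with one row
per alternate allele and explicit per-population ``AC_*``/``AN_*`` columns in
the gnomAD v2 dialect (lower-case population suffixes).  A VCF 4.x reader
with configurable INFO keys is provided for gnomAD-style input; multi-allelic
sites are decomposed on read, one record per alternate allele.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from .model import (
    MISSENSE_TOOLS,
    OBSERVED_POPULATIONS,
    SPLICE_TOOLS,
    AlleleCount,
    Consequence,
    DatabaseAnnotation,
    FilterStatus,
    GeneDescriptor,
    PanelConfig,
    Population,
    PredictionProfile,
    SpliceScore,
    VariantRecord,
    Verdict,
    format_phenotypes,
    parse_phenotypes,
)

logger = logging.getLogger("fibropanel")

_META_COLUMNS = [
    "variant_id",
    "rsid",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "protein_change",
    "hgvs_c",
    "intron_offset",
    "exon_label",
    "alt_transcript_only",
    "filter",
]


def _pop_suffix(pop: Population) -> str:
    return pop.value.lower()


def variant_table_columns() -> list[str]:
    cols = list(_META_COLUMNS)
    for pop in OBSERVED_POPULATIONS:
        cols += [f"AC_{_pop_suffix(pop)}", f"AN_{_pop_suffix(pop)}"]
    return cols


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def _record_from_row(row: Mapping, line_no: int) -> VariantRecord:
    counts: dict[Population, AlleleCount] = {}
    missing_pops = []
    for pop in OBSERVED_POPULATIONS:
        ac_col, an_col = f"AC_{_pop_suffix(pop)}", f"AN_{_pop_suffix(pop)}"
        ac_raw, an_raw = _opt(row.get(ac_col)), _opt(row.get(an_col))
        if ac_raw is None and an_raw is None:
            missing_pops.append(pop.value)
            counts[pop] = AlleleCount(0, 0)
            continue
        counts[pop] = AlleleCount(int(ac_raw or 0), int(an_raw or 0))
    if missing_pops:
        logger.warning(
            "line %d: no AC/AN fields for population(s) %s; recorded as ac=0, an=0",
            line_no,
            ",".join(missing_pops),
        )
    off = _opt(row.get("intron_offset"))
    alt_tx = _opt(row.get("alt_transcript_only"))
    return VariantRecord(
        variant_id=str(row["variant_id"]).strip(),
        rsid=_opt(row.get("rsid")),
        gene=str(row["gene"]).strip(),
        chrom=str(row["chrom"]).strip(),
        pos=int(row["pos"]),
        ref=str(row["ref"]).strip(),
        alt=str(row["alt"]).strip(),
        consequence=Consequence(str(row["consequence"]).strip()),
        protein_change=_opt(row.get("protein_change")),
        hgvs_c=_opt(row.get("hgvs_c")),
        intron_offset=int(off) if off is not None else None,
        exon_label=_opt(row.get("exon_label")),
        on_alternative_transcript_only=(alt_tx or "").lower() in ("1", "true", "yes"),
        filter_status=FilterStatus(str(row.get("filter", "pass")).strip().lower()),
        counts=counts,
    )


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""], comment="#")
    records = []
    for idx, row in df.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            records.append(_record_from_row(row, line_no))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
    return records


def read_variant_vcf(
    path: str | Path,
    info_keys: Optional[Mapping[str, str]] = None,
) -> list[VariantRecord]:
    """Read a gnomAD-dialect VCF (per-population ``AC_*``/``AN_*`` INFO fields).

    Multi-allelic rows are decomposed into one record per alternate allele;
    list-valued INFO fields are indexed by alternate allele.  ``info_keys``
    maps logical names (``gene``, ``consequence``, ``protein_change``,
    ``hgvs_c``, ``exon``, ``intron_offset``, ``alt_transcript_only``) to the
    INFO keys used in the file.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on install extras
        raise ImportError("VCF input requires the cyvcf2 package (pip install fibropanel[vcf])") from exc

    keys = {
        "gene": "GENE",
        "consequence": "CONSEQUENCE",
        "protein_change": "PROTEIN_CHANGE",
        "hgvs_c": "HGVS_C",
        "exon": "EXON",
        "intron_offset": "INTRON_OFFSET",
        "alt_transcript_only": "ALT_TX_ONLY",
    }
    if info_keys:
        keys.update(info_keys)

    def per_alt(value, i: int, n_alt: int):
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return value[i] if i < len(value) else None
        if isinstance(value, str) and n_alt > 1 and "," in value:
            parts = value.split(",")
            return parts[i] if i < len(parts) else None
        return value

    records: list[VariantRecord] = []
    for var in VCF(str(path)):
        n_alt = len(var.ALT)
        for i, alt in enumerate(var.ALT):
            counts: dict[Population, AlleleCount] = {}
            missing = []
            for pop in OBSERVED_POPULATIONS:
                ac = per_alt(var.INFO.get(f"AC_{_pop_suffix(pop)}"), i, n_alt)
                an = var.INFO.get(f"AN_{_pop_suffix(pop)}")
                if ac is None and an is None:
                    missing.append(pop.value)
                    counts[pop] = AlleleCount(0, 0)
                else:
                    counts[pop] = AlleleCount(int(ac or 0), int(an or 0))
            if missing:
                logger.warning(
                    "%s:%d alt=%s: no AC/AN fields for %s; recorded as ac=0, an=0",
                    var.CHROM, var.POS, alt, ",".join(missing),
                )
            off = per_alt(var.INFO.get(keys["intron_offset"]), i, n_alt)
            exon = per_alt(var.INFO.get(keys["exon"]), i, n_alt)
            alt_tx = per_alt(var.INFO.get(keys["alt_transcript_only"]), i, n_alt)
            pchange = per_alt(var.INFO.get(keys["protein_change"]), i, n_alt)
            hgvs_c = per_alt(var.INFO.get(keys["hgvs_c"]), i, n_alt)
            csq = per_alt(var.INFO.get(keys["consequence"]), i, n_alt)
            gene = var.INFO.get(keys["gene"])
            filt = var.FILTER  # None means PASS in cyvcf2
            try:
                records.append(
                    VariantRecord(
                        variant_id=f"{var.CHROM}-{var.POS}-{var.REF}-{alt}",
                        rsid=var.ID,
                        gene=str(gene),
                        chrom=str(var.CHROM),
                        pos=int(var.POS),
                        ref=var.REF,
                        alt=alt,
                        consequence=Consequence(str(csq)),
                        protein_change=_opt(pchange),
                        hgvs_c=_opt(hgvs_c),
                        intron_offset=int(off) if off is not None else None,
                        exon_label=_opt(exon),
                        on_alternative_transcript_only=str(alt_tx).lower()
                        in ("1", "true", "yes"),
                        filter_status=FilterStatus.PASS
                        if filt is None
                        else FilterStatus.LOW_CONFIDENCE,
                        counts=counts,
                    )
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"{path}: malformed VCF record {var.CHROM}:{var.POS} alt={alt}: {exc}"
                ) from exc
    return records


def read_variant_table(path: str | Path, format: Optional[str] = None, **kwargs) -> list[VariantRecord]:
    """Read a variant table, dispatching on ``format`` or the file suffix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv")
    if fmt == "vcf":
        return read_variant_vcf(path, **kwargs)
    if fmt == "tsv":
        return read_variant_tsv(path)
    raise ValueError(f"unknown format {fmt!r} (expected 'vcf' or 'tsv')")


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "rsid": r.rsid or "",
            "gene": r.gene,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "consequence": r.consequence.value,
            "protein_change": r.protein_change or "",
            "hgvs_c": r.hgvs_c or "",
            "intron_offset": "" if r.intron_offset is None else r.intron_offset,
            "exon_label": r.exon_label or "",
            "alt_transcript_only": "true" if r.on_alternative_transcript_only else "",
            "filter": r.filter_status.value,
        }
        for pop in OBSERVED_POPULATIONS:
            row[f"AC_{_pop_suffix(pop)}"] = r.counts[pop].ac
            row[f"AN_{_pop_suffix(pop)}"] = r.counts[pop].an
        rows.append(row)
    return pd.DataFrame(rows, columns=variant_table_columns())


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    variants_to_frame(records).to_csv(path, sep="\t", index=False)


def write_variant_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records as an uncompressed VCF 4.2 with gnomAD-dialect INFO keys.

    One line per record (records are already one-per-alternate-allele).
    """
    lines = ["##fileformat=VCFv4.2", '##contig=<ID=4,length=191154276>']
    for pop in OBSERVED_POPULATIONS:
        s = _pop_suffix(pop)
        lines.append(
            f'##INFO=<ID=AC_{s},Number=A,Type=Integer,Description="Alternate allele count ({pop.value})">'
        )
        lines.append(
            f'##INFO=<ID=AN_{s},Number=1,Type=Integer,Description="Allele number ({pop.value})">'
        )
    for key, desc in [
        ("GENE", "Gene symbol"),
        ("CONSEQUENCE", "Consequence class"),
        ("PROTEIN_CHANGE", "Protein change, native numbering"),
        ("HGVS_C", "Coding-sequence change"),
        ("EXON", "Canonical-transcript exon"),
        ("INTRON_OFFSET", "Distance from exon/intron boundary"),
        ("ALT_TX_ONLY", "Annotated only on alternative transcripts"),
    ]:
        num = "0" if key == "ALT_TX_ONLY" else "1"
        typ = "Flag" if key == "ALT_TX_ONLY" else "String"
        lines.append(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        info = []
        for pop in OBSERVED_POPULATIONS:
            s = _pop_suffix(pop)
            info.append(f"AC_{s}={r.counts[pop].ac}")
            info.append(f"AN_{s}={r.counts[pop].an}")
        info.append(f"GENE={r.gene}")
        info.append(f"CONSEQUENCE={r.consequence.value}")
        if r.protein_change:
            info.append(f"PROTEIN_CHANGE={r.protein_change}")
        if r.hgvs_c:
            info.append(f"HGVS_C={r.hgvs_c}")
        if r.exon_label:
            info.append(f"EXON={r.exon_label}")
        if r.intron_offset is not None:
            info.append(f"INTRON_OFFSET={r.intron_offset}")
        if r.on_alternative_transcript_only:
            info.append("ALT_TX_ONLY")
        filt = "PASS" if r.filter_status is FilterStatus.PASS else "RF"
        lines.append(
            "\t".join(
                [r.chrom, str(r.pos), r.rsid or ".", r.ref, r.alt, ".", filt,
                 ";".join(info)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# annotation table (predictor verdicts + database phenotypes)
# ---------------------------------------------------------------------------

def annotation_columns() -> list[str]:
    cols = ["variant_id", *MISSENSE_TOOLS]
    for tool in SPLICE_TOOLS:
        cols += [f"{tool}_wt", f"{tool}_mut", f"{tool}_abolished"]
    cols.append("phenotypes")
    return cols


def _parse_verdict(cell) -> Verdict:
    text = (_opt(cell) or "").lower()
    if text in ("", "."):
        return Verdict.MISSING
    if text in ("d", "damaging", "deleterious"):
        return Verdict.DAMAGING
    if text in ("t", "tolerated", "benign", "neutral"):
        return Verdict.TOLERATED
    raise ValueError(f"unknown predictor verdict {cell!r}")


def read_annotations(path: str | Path) -> dict[str, tuple[PredictionProfile, DatabaseAnnotation]]:
    """Read the per-variant annotation TSV.

    One row per variant_id; missing predictor cells become missing verdicts;
    a ``phenotypes`` cell such as ``d/h`` is parsed into a label set.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""], comment="#")
    out: dict[str, tuple[PredictionProfile, DatabaseAnnotation]] = {}
    for idx, row in df.iterrows():
        line_no = int(idx) + 2
        vid = str(row["variant_id"]).strip()
        if vid in out:
            raise ValueError(f"{path}: duplicate variant_id {vid!r} at line {line_no}")
        try:
            verdicts = {t: _parse_verdict(row.get(t)) for t in MISSENSE_TOOLS}
            scores: dict[str, SpliceScore] = {}
            for tool in SPLICE_TOOLS:
                wt, mut = _opt(row.get(f"{tool}_wt")), _opt(row.get(f"{tool}_mut"))
                ab = (_opt(row.get(f"{tool}_abolished")) or "").lower() in ("1", "true", "yes")
                if wt is None and mut is None and not ab:
                    scores[tool] = SpliceScore()
                else:
                    scores[tool] = SpliceScore(
                        float(wt or 0.0), float(mut or 0.0), ab, missing=False
                    )
            phenotypes = parse_phenotypes(_opt(row.get("phenotypes")) or "")
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
        out[vid] = (
            PredictionProfile(verdicts, scores),
            DatabaseAnnotation(reported=bool(phenotypes), phenotypes=phenotypes),
        )
    return out


def write_annotations(
    annotations: Mapping[str, tuple[PredictionProfile, DatabaseAnnotation]],
    path: str | Path,
) -> None:
    rows = []
    for vid, (profile, db) in annotations.items():
        row = {"variant_id": vid}
        for tool in MISSENSE_TOOLS:
            v = profile.missense_verdicts[tool]
            row[tool] = "" if v is Verdict.MISSING else v.value
        for tool in SPLICE_TOOLS:
            s = profile.splice_scores[tool]
            if s.missing:
                row[f"{tool}_wt"] = row[f"{tool}_mut"] = row[f"{tool}_abolished"] = ""
            else:
                row[f"{tool}_wt"] = s.wt_score
                row[f"{tool}_mut"] = s.mut_score
                row[f"{tool}_abolished"] = "true" if s.site_abolished else "false"
        row["phenotypes"] = format_phenotypes(db.phenotypes)
        rows.append(row)
    pd.DataFrame(rows, columns=annotation_columns()).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# panel configuration (YAML or JSON)
# ---------------------------------------------------------------------------

def load_panel_config(path: str | Path) -> PanelConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    genes = {}
    for name, spec in (data.get("genes") or {}).items():
        spec = spec or {}
        genes[name] = GeneDescriptor(
            name=name,
            chrom=str(spec.get("chrom", "4")),
            excluded_exon_labels=frozenset(str(e) for e in spec.get("excluded_exons", [])),
        )
    cfg = PanelConfig(genes=genes)
    if "signal_peptide_offsets" in data:
        cfg.signal_peptide_offsets = {
            str(g): int(v) for g, v in data["signal_peptide_offsets"].items()
        }
    if "population_sizes" in data:
        cfg.population_sizes = {
            Population(str(p).upper()): int(v) for p, v in data["population_sizes"].items()
        }
    return cfg


def write_run_log(path: str | Path, manifest: Mapping) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
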