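"""Readers and writers binding the pipeline together.

The canonical on-disk dialect is TSV, UTF-8, LF line endings (HGVS strings
may contain commas and semicolons but never tabs).  Every writer embeds a
content hash of the resolved run configuration so that reports are traceable
and byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd

from .acmg_engine import (
    AcmgConfig,
    Cosegregation,
    CriterionSet,
    DEFAULT_ACMG_CONFIG,
    EvidenceProfile,
    PriorReports,
)
from .insilico import (
    DEFAULT_THRESHOLDS,
    InsilicoThresholds,
    MissensePredictions,
    SplicePredictions,
    missense_verdict,
    splice_verdict,
)
from .variant_model import (
    FiveTierClass,
    IndexCase,
    Variant,
    VariantParseError,
    VariantType,
    parse_variant,
)

logger = logging.getLogger("sdhbcurate")

TRANSCRIPT = "NM_003000.2"

CLASS_LABELS = {
    FiveTierClass.BV: "benign",
    FiveTierClass.LBV: "likely benign",
    FiveTierClass.VUS: "VUS",
    FiveTierClass.LPV: "likely pathogenic",
    FiveTierClass.PV: "pathogenic",
}

LOVD_REMARK = (
    "variant classified by experts from the NGSnPPGL study group (ENS@T/PRESSOR)"
)

#: evidence-table dialect: required `cdna`; everything else optional
EVIDENCE_COLUMNS = [
    "cdna", "protein", "vtype", "af", "af_source", "case_count",
    "cons_ratio", "phylop", "grantham", "polyphen2", "sift", "align_gvgd",
    "mutation_taster", "mes_ref", "mes_alt", "nns_ref", "nns_alt",
    "loh", "shdb_ihc", "sdha_ihc", "sdh_activity", "western_blot",
    "transcriptomic_cluster", "cdna_splicing", "other_sdhx_excluded",
    "coseg_meioses", "coseg_segregates", "prior_pathogenic", "prior_benign",
]

CASE_COLUMNS = [
    "case_id", "cdna", "protein", "vtype", "n_tumours", "tumour_sites",
    "metastatic", "family_history", "age_at_diagnosis",
]


@dataclass(frozen=True)
class RowError:
    line: int
    cdna: str
    message: str


class MissingColumnError(ValueError):
    def __init__(self, column: str):
        super().__init__(f"missing required column {column!r}")
        self.column = column


def _opt(row: Mapping, key: str) -> Optional[str]:
    value = row.get(key)
    if value is None:
        return None
    value = str(value).strip()
    return value or None


def _opt_float(row: Mapping, key: str) -> Optional[float]:
    value = _opt(row, key)
    return float(value) if value is not None else None


def _opt_int(row: Mapping, key: str) -> Optional[int]:
    value = _opt(row, key)
    return int(value) if value is not None else None


def _opt_bool(row: Mapping, key: str) -> bool:
    value = _opt(row, key)
    return value is not None and value.lower() in ("1", "true", "yes")


def profile_from_row(
    row: Mapping[str, Any],
    thresholds: InsilicoThresholds = DEFAULT_THRESHOLDS,
) -> EvidenceProfile:
    """Build an evidence profile from one evidence-table row.

    Raw predictor columns are aggregated into in-silico verdicts here, so
    that profiles built from disk and profiles built in memory follow the
    same code path.  A ``vtype`` column overrides the inferred type with a
    logged warning.
    """
    override = _opt(row, "vtype")
    vtype = VariantType(override) if override else None
    variant = parse_variant(str(row["cdna"]), _opt(row, "protein"), vtype)
    if vtype is not None and parse_variant(str(row["cdna"]), _opt(row, "protein")).vtype != vtype:
        logger.warning(
            "vtype override for %s: inferred %s, using %s",
            variant.cdna,
            parse_variant(str(row["cdna"]), _opt(row, "protein")).vtype.value,
            vtype.value,
        )

    mp = MissensePredictions(
        conservation_ratio=_opt_float(row, "cons_ratio"),
        phylop=_opt_float(row, "phylop"),
        grantham=_opt_int(row, "grantham"),
        polyphen2_humvar=_opt(row, "polyphen2"),
        sift=_opt(row, "sift"),
        align_gvgd=_opt(row, "align_gvgd"),
        mutation_taster=_opt(row, "mutation_taster"),
    )
    has_missense = any(
        getattr(mp, f.name) is not None for f in dataclasses.fields(mp)
    )
    sp = SplicePredictions(
        maxentscan_ref=_opt_float(row, "mes_ref"),
        maxentscan_alt=_opt_float(row, "mes_alt"),
        nnsplice_ref=_opt_float(row, "nns_ref"),
        nnsplice_alt=_opt_float(row, "nns_alt"),
    )
    has_splice = sp.maxentscan_ref is not None or sp.nnsplice_ref is not None

    meioses = _opt_int(row, "coseg_meioses")
    coseg = (
        Cosegregation(meioses, _opt_bool(row, "coseg_segregates"))
        if meioses is not None
        else None
    )
    prior_p = _opt_int(row, "prior_pathogenic")
    prior_b = _opt_int(row, "prior_benign")
    prior = (
        PriorReports(prior_p or 0, prior_b or 0)
        if prior_p is not None or prior_b is not None
        else None
    )

    return EvidenceProfile(
        variant=variant,
        max_population_af=_opt_float(row, "af"),
        af_source=_opt(row, "af_source"),
        case_count=_opt_int(row, "case_count") or 1,
        cosegregation=coseg,
        insilico_missense=missense_verdict(mp, thresholds) if has_missense else None,
        insilico_splice=splice_verdict(sp, thresholds) if has_splice else None,
        cdna_splicing_shown=_opt(row, "cdna_splicing") or "not_done",
        loh=_opt(row, "loh") or "not_done",
        shdb_ihc=_opt(row, "shdb_ihc") or "not_done",
        sdha_ihc=_opt(row, "sdha_ihc") or "not_done",
        sdh_activity=_opt(row, "sdh_activity") or "not_done",
        western_blot=_opt(row, "western_blot") or "not_done",
        transcriptomic_cluster=_opt(row, "transcriptomic_cluster") or "not_done",
        other_sdhx_excluded=_opt_bool(row, "other_sdhx_excluded"),
        prior_reports=prior,
    )


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, comment="#", keep_default_na=False
    ).replace("", None)


def read_evidence_table(
    path, thresholds: InsilicoThresholds = DEFAULT_THRESHOLDS
) -> tuple[list[EvidenceProfile], list[RowError]]:
    """Read a per-variant evidence table; malformed rows become RowErrors."""
    df = _read_tsv(path)
    if "cdna" not in df.columns:
        raise MissingColumnError("cdna")
    profiles, errors = [], []
    for i, row in enumerate(df.to_dict("records")):
        if not row.get("cdna"):
            errors.append(RowError(i + 2, "", "empty cdna"))
            continue
        try:
            profiles.append(profile_from_row(row, thresholds))
        except (VariantParseError, ValueError) as exc:
            errors.append(RowError(i + 2, str(row.get("cdna") or ""), str(exc)))
    return profiles, errors


def case_from_row(row: Mapping[str, Any]) -> IndexCase:
    override = _opt(row, "vtype")
    variant = parse_variant(
        str(row["cdna"]), _opt(row, "protein"),
        VariantType(override) if override else None,
    )
    sites_raw = _opt(row, "tumour_sites")
    sites = frozenset(s for s in sites_raw.split(",") if s) if sites_raw else None
    return IndexCase(
        case_id=_opt(row, "case_id") or "",
        variant=variant,
        n_tumours=_opt_int(row, "n_tumours"),
        tumour_sites=sites,
        metastatic=_opt(row, "metastatic"),
        family_history=_opt(row, "family_history"),
        age_at_diagnosis=_opt_float(row, "age_at_diagnosis"),
    )


def read_cases_table(path) -> tuple[list[IndexCase], list[RowError]]:
    df = _read_tsv(path)
    if "cdna" not in df.columns:
        raise MissingColumnError("cdna")
    cases, errors = [], []
    for i, row in enumerate(df.to_dict("records")):
        try:
            cases.append(case_from_row(row))
        except (VariantParseError, ValueError) as exc:
            errors.append(RowError(i + 2, str(row.get("cdna") or ""), str(exc)))
    return cases, errors


def read_vcf(path) -> tuple[list[Variant], list[RowError]]:
    """Minimal VCF 4.2 reader: accepts records carrying an HGVS-c annotation
    in INFO (key ``HGVSC``); records lacking it are reported per row."""
    import pysam

    variants, errors = [], []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf):
            hgvsc = rec.info.get("HGVSC") if "HGVSC" in rec.info else None
            if isinstance(hgvsc, tuple):
                hgvsc = hgvsc[0]
            if not hgvsc:
                errors.append(
                    RowError(i + 1, f"{rec.chrom}:{rec.pos}", "record lacks HGVSC INFO field")
                )
                continue
            try:
                variants.append(parse_variant(str(hgvsc)))
            except VariantParseError as exc:
                errors.append(RowError(i + 1, str(hgvsc), str(exc)))
    return variants, errors


def read_override_ledger(path) -> dict[str, tuple[FiveTierClass, str]]:
    """Override ledger TSV: columns cdna, final_class, citation."""
    df = _read_tsv(path)
    for col in ("cdna", "final_class"):
        if col not in df.columns:
            raise MissingColumnError(col)
    ledger = {}
    for row in df.to_dict("records"):
        variant = parse_variant(str(row["cdna"]))
        raw = str(row["final_class"]).strip()
        cls = (
            FiveTierClass(int(raw)) if raw.isdigit() else FiveTierClass.from_label(raw)
        )
        ledger[variant.cdna] = (cls, _opt(row, "citation") or "expert override")
    return ledger


# --- config hashing and writers ---------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return sorted((_jsonable(v) for v in obj), key=repr) if isinstance(
            obj, (set, frozenset)
        ) else [_jsonable(v) for v in obj]
    return obj


def config_hash(*configs: Any) -> str:
    """Short content hash of the resolved run configuration."""
    payload = json.dumps([_jsonable(c) for c in configs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path, cfg_hash: Optional[str] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def format_criteria(cs: CriterionSet) -> str:
    parts = [
        f"{c.code}({c.strength.value})" + ("!" if c.conflict else "")
        for c in sorted(cs.met, key=lambda c: c.code)
    ]
    return ",".join(parts)


def export_lovd(report: pd.DataFrame, path, cfg_hash: str = "") -> pd.DataFrame:
    """Write an LOVD shared-instance-style submission table.

    Refuses to export when any variant is still unresolved (missing final
    class): only finalised consensus classes are database-worthy.
    """
    if "final_class" not in report.columns:
        raise ValueError("report lacks final_class column")
    finals = report["final_class"]
    if finals.isna().any() or (finals.astype(str).str.strip() == "").any():
        raise ValueError("unresolved variants present; export refused")
    out = pd.DataFrame({
        "gene": "SDHB",
        "transcript": TRANSCRIPT,
        "cdna": report["cdna"],
        "protein": report.get("protein", pd.Series("", index=report.index)).fillna(""),
        "classification": [
            CLASS_LABELS[FiveTierClass(int(v))] for v in finals
        ],
        "remarks": LOVD_REMARK + (f" [config {cfg_hash}]" if cfg_hash else ""),
    })
    write_tsv(out, path, cfg_hash or None)
    return out
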