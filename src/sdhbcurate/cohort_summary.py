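"""Cohort statistics: clinical table, variant-type and class distributions.

Percentage conventions follow diagnostic-reporting practice: clinical
percentages are computed over the denominator of cases for which the field
is specified ("not specified" strata are listed as counts only), rounded to
one decimal half away from zero; variant-type percentages are over the
distinct-variant total, rounded to the nearest integer.  Every emitted table
self-audits its percentages against count/denominator before returning.
"""

from __future__ import annotations

from collections import Counter
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_model import (
    FiveTierClass,
    IndexCase,
    INDEL_TYPES,
    SUBSTITUTION_TYPES,
    Variant,
    VariantType,
)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int, decimals: int = 1) -> Optional[float]:
    if denominator == 0:
        return None
    return round_half_up(100.0 * count / denominator, decimals)


def _audit(rows: Sequence[dict]) -> None:
    for r in rows:
        if r.get("pct") is None:
            continue
        expect = pct(r["count"], r["denominator"], r.get("_decimals", 1))
        assert r["pct"] == expect, f"percentage self-audit failed for {r}"


# --- clinical table ----------------------------------------------------------

_SITE_ROWS = {
    "head_neck_PGL": "single_head_neck_PGL",
    "TAP_PGL": "single_TAP_PGL",
    "PCC": "single_PCC",
}


def clinical_table(
    cases: Sequence[IndexCase],
    classes: Optional[Mapping[str, FiveTierClass]] = None,
    subset: Optional[Iterable[FiveTierClass]] = None,
) -> pd.DataFrame:
    """Tabulate clinical presentation with known-value denominators.

    ``classes`` maps normalised cDNA to a final 5-tier class; with ``subset``
    (e.g. ``{LPV, PV}``) the table is restricted to carriers of those
    classes.  Rows mirror the standard presentation layout: tumour number
    and location, metastatic status, familial presentation.
    """
    if not cases:
        raise ValueError("clinical_table requires a non-empty cohort")
    if subset is not None:
        if classes is None:
            raise ValueError("subset filtering requires a class mapping")
        allowed = set(subset)
        cases = [
            c for c in cases
            if classes.get(c.variant.cdna) in allowed
        ]
        if not cases:
            raise ValueError("subset filter removed every case")

    n = len(cases)

    def presentation(case: IndexCase) -> str:
        sites = case.tumour_sites or frozenset()
        if case.n_tumours is None and not sites:
            return "not_specified"
        if sites == {"RCC"}:
            return "rcc_only"
        if sites == {"GIST"}:
            return "gist_only"
        if (case.n_tumours or 1) > 1:
            return "multiple_ppgl"
        if not sites or sites == {"unspecified"}:
            return "single_unspecified_site"
        site = next(iter(sites - {"unspecified"}))
        return f"single_{site}"

    pres = Counter(presentation(c) for c in cases)
    n_single = sum(v for k, v in pres.items() if k.startswith("single_"))
    n_known_tumour = n - pres["not_specified"]
    n_site_known = n_single - pres["single_unspecified_site"]

    rows = [
        {"row": "single_PPGL", "count": n_single, "denominator": n_known_tumour},
        {"row": "single_head_neck_PGL", "count": pres["single_head_neck_PGL"],
         "denominator": n_site_known},
        {"row": "single_TAP_PGL", "count": pres["single_TAP_PGL"],
         "denominator": n_site_known},
        {"row": "single_PCC", "count": pres["single_PCC"],
         "denominator": n_site_known},
        {"row": "single_location_not_specified",
         "count": pres["single_unspecified_site"], "denominator": 0},
        {"row": "multiple_PPGL", "count": pres["multiple_ppgl"],
         "denominator": n_known_tumour},
        {"row": "RCC_only", "count": pres["rcc_only"], "denominator": n_known_tumour},
        {"row": "GIST_only", "count": pres["gist_only"], "denominator": n_known_tumour},
        {"row": "tumours_not_specified", "count": pres["not_specified"],
         "denominator": 0},
    ]

    meta = Counter(c.metastatic for c in cases)
    n_meta_known = meta["yes"] + meta["no"]
    rows += [
        {"row": "metastatic", "count": meta["yes"], "denominator": n_meta_known},
        {"row": "benign_disease", "count": meta["no"], "denominator": n_meta_known},
        {"row": "metastatic_not_specified", "count": meta[None], "denominator": 0},
    ]

    fam = Counter(c.family_history for c in cases)
    n_fam_known = fam["yes"] + fam["no"]
    rows += [
        {"row": "family_history", "count": fam["yes"], "denominator": n_fam_known},
        {"row": "no_family_history", "count": fam["no"], "denominator": n_fam_known},
        {"row": "family_history_not_specified", "count": fam[None], "denominator": 0},
    ]

    for r in rows:
        r["pct"] = pct(r["count"], r["denominator"]) if r["denominator"] else None
    _audit(rows)

    df = pd.DataFrame(rows).set_index("row")
    df.attrs["n_cases"] = n
    return df


def carrier_fraction(
    cases: Sequence[IndexCase],
    classes: Mapping[str, FiveTierClass],
    which: Iterable[FiveTierClass] = (FiveTierClass.LPV, FiveTierClass.PV),
) -> tuple[int, float]:
    """(carrier count, percentage of the whole cohort) for the given classes."""
    allowed = set(which)
    carriers = sum(1 for c in cases if classes.get(c.variant.cdna) in allowed)
    return carriers, pct(carriers, len(cases))


# --- occurrence bins ---------------------------------------------------------

OCCURRENCE_BINS = ("1", "2-5", "6-10", "11-20", ">=20")


def occurrence_bins(dedup: Mapping[Variant, int]) -> dict[str, int]:
    """Bin distinct variants by occurrence count; totals sum to len(dedup).

    Bins: exactly once, 2-5, 6-10, 11-20 and "20 or more"; a count of
    exactly 20 belongs to the open-ended last bin, so the 11-20 bin holds
    counts 11-19.
    """
    bins = dict.fromkeys(OCCURRENCE_BINS, 0)
    for count in dedup.values():
        if count < 1:
            raise ValueError("occurrence counts must be >= 1")
        if count == 1:
            bins["1"] += 1
        elif count <= 5:
            bins["2-5"] += 1
        elif count <= 10:
            bins["6-10"] += 1
        elif count < 20:
            bins["11-20"] += 1
        else:
            bins[">=20"] += 1
    return bins


# --- variant type distribution ----------------------------------------------

def type_distribution(variants: Sequence[Variant]) -> pd.DataFrame:
    """Counts and integer percentages per variant type, grouped into
    nucleotide substitutions vs deletions/duplications."""
    total = len(variants)
    counts = Counter(v.vtype for v in variants)
    rows = []
    for group, members in (
        ("substitution", SUBSTITUTION_TYPES),
        ("deletion_duplication", INDEL_TYPES),
    ):
        ordered = [t for t in VariantType if t in members]
        group_count = sum(counts[t] for t in ordered)
        rows.append({
            "category": group, "group": group, "count": group_count,
            "denominator": total,
            "pct": pct(group_count, total, 0) if total else 0,
            "_decimals": 0,
        })
        for t in ordered:
            rows.append({
                "category": t.value, "group": group, "count": counts[t],
                "denominator": total,
                "pct": pct(counts[t], total, 0) if total else 0,
                "_decimals": 0,
            })
    if total:
        _audit(rows)
    for r in rows:
        r.pop("_decimals", None)
        if r["pct"] is None:
            r["pct"] = 0
        r["pct"] = int(r["pct"])
    df = pd.DataFrame(rows).set_index("category")
    sub = df.loc["substitution", "count"]
    indel = df.loc["deletion_duplication", "count"]
    assert sub + indel == total, "group totals must sum to the variant total"
    return df


# --- class distribution ------------------------------------------------------

def class_distribution(
    finals: Mapping[str, FiveTierClass] | Sequence[tuple[Variant, FiveTierClass]],
) -> dict[str, int]:
    """Counts per 5-tier class plus the merged B/LB, VUS, LP/P groups."""
    if isinstance(finals, Mapping):
        items = list(finals.items())
    else:
        items = [(v.cdna, cls) for v, cls in finals]
    keys = [k for k, _ in items]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate variant in final classification list")
    counts = Counter(cls for _, cls in items)
    out = {cls.name: counts[cls] for cls in FiveTierClass}
    out["B_LB"] = out["BV"] + out["LBV"]
    out["LP_P"] = out["LPV"] + out["PV"]
    out["VUS_group"] = out["VUS"]
    out["total"] = len(items)
    assert out["B_LB"] + out["VUS_group"] + out["LP_P"] == out["total"]
    return out
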