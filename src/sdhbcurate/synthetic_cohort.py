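"""Synthetic SDHB cohorts with known ground truth, plus reference fixtures.

The generator emulates the statistical structure of the international
NGSnPPGL curated SDHB cohort: 737 index cases collapsing to 223 distinct
variants, the printed occurrence, variant-type and final-class
distributions, the tumour-assay availability rates and the clinical
composition of the cohort.  Occurrence, variant-type and class quotas are
drawn exactly (quota sampling) so the headline structural counts are
reproducible per seed, while clinical fields are independent categorical
draws and thus match their marginals only to binomial error.

Evidence is coupled to the drawn truth class: each variant always receives
the minimal evidence that supports its class at default thresholds (a
pathogenic truncating variant is absent from controls and carries a
confirmatory tumour assay; a benign variant carries a common allele
frequency), and the per-assay availability rates steer which assay modality
is reported and which optional extras appear.  The generator never
fabricates evidence contradicting the truth class unless ``evidence_noise``
is raised above its default of 0.

``fixture_reference_tables`` returns the reference tabulations of the curated
cohort (transcribed counts, not computations) for desk-scale verification
of the accounting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .acmg_engine import EvidenceProfile
from .consensus import DualClassification
from .io import profile_from_row
from .variant_model import (
    EXONS,
    FiveTierClass,
    IndexCase,
    TRUNCATING_TYPES,
    Variant,
    VariantType,
    parse_variant,
)

# --- reference tabulations (transcribed constants) ---------------------------

OCCURRENCE_BIN_COUNTS = {"1": 122, "2-5": 75, "6-10": 12, "11-20": 9, ">=20": 5}

VTYPE_COUNTS = {
    VariantType.MISSENSE: 98,
    VariantType.NONSENSE: 21,
    VariantType.SPLICE_SITE_SUBSTITUTION: 20,
    VariantType.MID_INTRONIC: 12,
    VariantType.SYNONYMOUS: 6,
    VariantType.UTR5: 3,
    VariantType.INITIATION_CODON: 2,
    VariantType.FRAMESHIFT_INDEL: 38,
    VariantType.LARGE_REARRANGEMENT: 14,
    VariantType.INFRAME_INDEL: 4,
    VariantType.NONCODING_INDEL: 3,
    VariantType.SPLICE_SITE_INDEL: 2,
}

CLASS_COUNTS = {
    FiveTierClass.BV: 2,
    FiveTierClass.LBV: 21,
    FiveTierClass.VUS: 51,
    FiveTierClass.LPV: 83,
    FiveTierClass.PV: 66,
}

#: number of distinct variants with each tumour assay reported (of 223)
EVIDENCE_AVAILABILITY_COUNTS = {
    "ihc": 75, "loh": 26, "cluster": 24, "cdna": 15, "western": 7, "activity": 6,
}

CLINICAL_COMPOSITION = {
    "presentation": {
        "single_head_neck_PGL": 213,
        "single_TAP_PGL": 184,
        "single_PCC": 78,
        "single_unspecified_site": 143,
        "multiple_PPGL": 103,
        "RCC_only": 8,
        "GIST_only": 2,
        "not_specified": 6,
    },
    "metastatic": {"yes": 133, "no": 238, "unknown": 366},
    "family_history": {"yes": 159, "no": 374, "unknown": 204},
}

CONCORDANT_BREAKDOWN = {
    FiveTierClass.LBV: 6,
    FiveTierClass.VUS: 61,
    FiveTierClass.LPV: 70,
    FiveTierClass.PV: 24,
}
DISCORDANT_BREAKDOWN = {
    (FiveTierClass.BV, FiveTierClass.LBV): 4,
    (FiveTierClass.BV, FiveTierClass.VUS): 1,
    (FiveTierClass.LBV, FiveTierClass.VUS): 17,
    (FiveTierClass.VUS, FiveTierClass.LPV): 23,
    (FiveTierClass.VUS, FiveTierClass.PV): 6,
    (FiveTierClass.LPV, FiveTierClass.PV): 11,
}
ROUND1_OUTCOMES = {
    "concordant_unchanged": 91,
    "unchanged_breakdown": {
        FiveTierClass.LBV: 5, FiveTierClass.VUS: 28,
        FiveTierClass.LPV: 35, FiveTierClass.PV: 23,
    },
    "promoted_lpv_to_pv": 9,
    "discordant_resolved": 48,
    "resolved_breakdown": {
        FiveTierClass.BV: 2, FiveTierClass.LBV: 12, FiveTierClass.VUS: 12,
        FiveTierClass.LPV: 8, FiveTierClass.PV: 14,
    },
}
ROUND2_UNRESOLVED = {
    (FiveTierClass.LBV, FiveTierClass.VUS): 5,
    (FiveTierClass.VUS, FiveTierClass.PV): 5,
    (FiveTierClass.VUS, FiveTierClass.LPV): 36,
    (FiveTierClass.LPV, FiveTierClass.PV): 29,
}

FINAL_CLASS_COUNTS = dict(CLASS_COUNTS)

COHORT_SIZES = {"n_cases": 737, "n_distinct": 223, "n_lp_p_carriers": 614}


def fixture_reference_tables() -> dict:
    """Reference tabulations of the curated SDHB cohort (NGSnPPGL study
    group; ENS@T/PRESSOR networks), transcribed rather than computed."""
    return {
        "occurrence_bins": dict(OCCURRENCE_BIN_COUNTS),
        "vtype_counts": dict(VTYPE_COUNTS),
        "final_classes": dict(FINAL_CLASS_COUNTS),
        "evidence_availability": dict(EVIDENCE_AVAILABILITY_COUNTS),
        "clinical_composition": {k: dict(v) for k, v in CLINICAL_COMPOSITION.items()},
        "concordant_breakdown": dict(CONCORDANT_BREAKDOWN),
        "discordant_breakdown": dict(DISCORDANT_BREAKDOWN),
        "round1": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in ROUND1_OUTCOMES.items()
        },
        "round2_unresolved": dict(ROUND2_UNRESOLVED),
        "cohort": dict(COHORT_SIZES),
    }


# --- generator config --------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_cases: int = 737
    n_distinct: int = 223
    occurrence_distribution: Mapping[str, int] = field(
        default_factory=lambda: dict(OCCURRENCE_BIN_COUNTS)
    )
    vtype_distribution: Mapping[VariantType, int] = field(
        default_factory=lambda: dict(VTYPE_COUNTS)
    )
    class_distribution: Mapping[FiveTierClass, int] = field(
        default_factory=lambda: dict(CLASS_COUNTS)
    )
    evidence_availability: Mapping[str, float] = field(
        default_factory=lambda: {
            k: v / 223 for k, v in EVIDENCE_AVAILABILITY_COUNTS.items()
        }
    )
    clinical_composition: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in CLINICAL_COMPOSITION.items()
        }
    )
    #: fraction of pathogenic variants drawn as missense with tumour-based
    #: proof of SDHB-specific loss of function
    pv_missense_fraction: float = 0.1
    #: probability an assay result contradicts the truth class
    evidence_noise: float = 0.0

    def __post_init__(self):
        if self.n_distinct > self.n_cases:
            raise ValueError("n_distinct must not exceed n_cases")
        for name in ("occurrence_distribution", "vtype_distribution",
                     "class_distribution"):
            if any(v < 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} weights must be non-negative")


class GeneratorConfigError(ValueError):
    """Raised when the configured quotas are infeasible."""


@dataclass
class CohortBundle:
    cases: list[IndexCase]
    profiles: list[EvidenceProfile]
    truth: dict[Variant, FiveTierClass]
    evidence_rows: list[dict]
    case_rows: list[dict]


# --- quota helpers -----------------------------------------------------------

def largest_remainder(weights: Mapping, total: int) -> dict:
    """Scale integer weights to sum exactly to ``total`` (largest-remainder,
    ties broken by input order for determinism)."""
    keys = list(weights)
    w = np.array([float(weights[k]) for k in keys])
    if w.sum() == 0:
        raise GeneratorConfigError("all quota weights are zero")
    exact = w * total / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = sorted(range(len(keys)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return {k: int(b) for k, b in zip(keys, base)}


_BIN_RANGES = {"1": (1, 1), "2-5": (2, 5), "6-10": (6, 10), "11-20": (11, 19),
               ">=20": (20, None)}


def _occurrence_counts(config: GeneratorConfig, rng: np.random.Generator) -> list[int]:
    """Per-variant occurrence counts honouring the bin quotas exactly and
    summing exactly to n_cases."""
    if config.n_cases == config.n_distinct:
        return [1] * config.n_distinct
    bins = largest_remainder(config.occurrence_distribution, config.n_distinct)
    counts, caps = [], []
    for name, nbin in bins.items():
        lo, hi = _BIN_RANGES[name]
        counts += [lo] * nbin
        caps += [hi] * nbin
    minimum = sum(counts)
    if config.n_cases < minimum:
        raise GeneratorConfigError(
            f"n_cases={config.n_cases} below the bin minimum {minimum}"
        )
    headroom = [
        i for i, cap in enumerate(caps) if cap is None or counts[i] < cap
    ]
    if not headroom and config.n_cases > minimum:
        raise GeneratorConfigError("occurrence bins cannot absorb n_cases")
    remaining = config.n_cases - minimum
    while remaining > 0:
        i = int(rng.choice(headroom))
        counts[i] += 1
        if caps[i] is not None and counts[i] >= caps[i]:
            headroom.remove(i)
            if not headroom:
                raise GeneratorConfigError("occurrence bins cannot absorb n_cases")
        remaining -= 1
    return counts


_NONTRUNCATING = [t for t in VariantType if t not in TRUNCATING_TYPES]
_TRUNC_PREF = [
    VariantType.NONSENSE, VariantType.FRAMESHIFT_INDEL,
    VariantType.LARGE_REARRANGEMENT, VariantType.SPLICE_SITE_SUBSTITUTION,
    VariantType.SPLICE_SITE_INDEL,
]
_BENIGN_PREF = [
    VariantType.SYNONYMOUS, VariantType.UTR5, VariantType.MID_INTRONIC,
    VariantType.NONCODING_INDEL, VariantType.INFRAME_INDEL, VariantType.MISSENSE,
]


def _joint_assignment(config: GeneratorConfig) -> list[tuple[VariantType, FiveTierClass]]:
    """Pair each variant slot's type with a truth class.

    Benign/likely-benign/VUS classes are restricted to non-truncating types
    (a clear null allele is never benign); pathogenic classes prefer
    truncating types, with a configurable missense fraction carrying
    assay-proven pathogenicity.
    """
    vtypes = largest_remainder(config.vtype_distribution, config.n_distinct)
    classes = largest_remainder(config.class_distribution, config.n_distinct)
    pool = {t: vtypes.get(t, 0) for t in VariantType}
    out: list[tuple[VariantType, FiveTierClass]] = []

    def take(vt: VariantType, cls: FiveTierClass, n: int) -> int:
        got = min(n, pool[vt])
        pool[vt] -= got
        out.extend([(vt, cls)] * got)
        return got

    # pathogenic: a missense share with tumour proof, the rest truncating
    n_pv = classes.get(FiveTierClass.PV, 0)
    want_mis = int(round(n_pv * config.pv_missense_fraction))
    avail_trunc = sum(pool[t] for t in _TRUNC_PREF)
    want_mis = max(want_mis, n_pv - avail_trunc)
    got = take(VariantType.MISSENSE, FiveTierClass.PV, want_mis)
    need = n_pv - got
    for t in _TRUNC_PREF:
        need -= take(t, FiveTierClass.PV, need)
    if need:
        raise GeneratorConfigError("not enough variant-type slots for PV quota")

    # benign side and VUS: non-truncating only
    for cls in (FiveTierClass.BV, FiveTierClass.LBV):
        need = classes.get(cls, 0)
        for t in _BENIGN_PREF:
            need -= take(t, cls, need)
        if need:
            raise GeneratorConfigError(
                f"not enough non-truncating slots for the {cls.name} quota"
            )
    n_vus = classes.get(FiveTierClass.VUS, 0)
    nt_pool = {t: pool[t] for t in _NONTRUNCATING if pool[t] > 0}
    if sum(nt_pool.values()) < n_vus:
        raise GeneratorConfigError("not enough non-truncating slots for the VUS quota")
    for t, n in largest_remainder(nt_pool, n_vus).items():
        take(t, FiveTierClass.VUS, n)

    # likely pathogenic: whatever remains (mixed truncating/non-truncating)
    for t in VariantType:
        take(t, FiveTierClass.LPV, pool[t])
    if len(out) != config.n_distinct:
        raise GeneratorConfigError("type/class quotas do not tile the cohort")
    return out


# --- HGVS synthesis ----------------------------------------------------------

_AA = ["Ala", "Arg", "Asp", "Gly", "His", "Leu", "Pro", "Ser", "Thr", "Val"]


class _HgvsFactory:
    """Deterministic synthesis of distinct, parseable SDHB descriptions."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        coding = [p for p in range(4, 844)]
        self.rng.shuffle(coding)
        self._coding = iter(coding)
        self._used: set[str] = set()
        donors = [EXONS[k][1] for k in range(1, 8)]
        acceptors = [EXONS[k][0] for k in range(2, 9)]
        self._splice = iter(
            [f"c.{d}+1G>A" for d in donors]
            + [f"c.{a}-1G>C" for a in acceptors]
            + [f"c.{d}+2T>C" for d in donors]
            + [f"c.{a}-2A>G" for a in acceptors]
        )
        self._splice_indel = iter(
            [f"c.{d}+1del" for d in donors] + [f"c.{a}-2_{a}-1del" for a in acceptors]
        )
        self._intronic = iter(
            f"c.{d}+{off}T>C" for off in range(10, 45) for d in donors
        )
        self._intronic_indel = iter(
            f"c.{d}+{off}del" for off in range(10, 45) for d in donors
        )
        self._utr = iter(f"c.-{n}C>T" for n in range(5, 70))
        self._init = iter(["c.1A>G", "c.2T>C", "c.3G>A", "c.3G>T"])
        spans = (
            [(k, k) for k in range(1, 9)]
            + [(1, 7), (2, 8), (1, 8), (3, 4), (4, 6), (5, 8), (2, 3), (6, 8)]
        )
        self._large = iter(
            f"c.{EXONS[s][0]}-?_{EXONS[e][1]}+?del" for s, e in spans
        )

    def _register(self, cdna: str, protein: Optional[str] = None) -> Variant:
        if cdna in self._used:
            raise GeneratorConfigError(f"duplicate synthetic description {cdna}")
        self._used.add(cdna)
        return parse_variant(cdna, protein)

    def _next_codon_pos(self) -> tuple[int, int]:
        pos = next(self._coding)
        return pos, (pos + 2) // 3

    def make(self, vtype: VariantType) -> Variant:
        rng = self.rng
        try:
            if vtype == VariantType.MISSENSE:
                pos, aa = self._next_codon_pos()
                ref, alt = rng.choice(len(_AA), 2, replace=False)
                return self._register(
                    f"c.{pos}G>A", f"p.{_AA[ref]}{aa}{_AA[alt]}"
                )
            if vtype == VariantType.NONSENSE:
                pos, aa = self._next_codon_pos()
                return self._register(f"c.{pos}C>T", f"p.Arg{aa}Ter")
            if vtype == VariantType.SYNONYMOUS:
                pos, _ = self._next_codon_pos()
                return self._register(f"c.{pos}A>G", "p.(=)")
            if vtype == VariantType.SPLICE_SITE_SUBSTITUTION:
                return self._register(next(self._splice))
            if vtype == VariantType.SPLICE_SITE_INDEL:
                return self._register(next(self._splice_indel))
            if vtype == VariantType.MID_INTRONIC:
                return self._register(next(self._intronic))
            if vtype == VariantType.NONCODING_INDEL:
                return self._register(next(self._intronic_indel))
            if vtype == VariantType.UTR5:
                return self._register(next(self._utr))
            if vtype == VariantType.INITIATION_CODON:
                return self._register(next(self._init))
            if vtype == VariantType.FRAMESHIFT_INDEL:
                pos, _ = self._next_codon_pos()
                return self._register(
                    f"c.{pos}del" if rng.random() < 0.5 else f"c.{pos}dup"
                )
            if vtype == VariantType.INFRAME_INDEL:
                pos, _ = self._next_codon_pos()
                return self._register(f"c.{pos}_{pos + 2}del")
            if vtype == VariantType.LARGE_REARRANGEMENT:
                return self._register(next(self._large))
        except StopIteration:
            raise GeneratorConfigError(
                f"ran out of distinct synthetic positions for {vtype.value}"
            ) from None
        raise GeneratorConfigError(f"no synthesis rule for {vtype}")


# --- evidence synthesis ------------------------------------------------------

_ASSAY_MODALITIES = ("ihc", "activity", "cluster", "western")


def _pick_modality(rng: np.random.Generator, rates: Mapping[str, float]) -> str:
    weights = np.array([max(rates.get(m, 0.0), 1e-9) for m in _ASSAY_MODALITIES])
    return _ASSAY_MODALITIES[int(rng.choice(len(weights), p=weights / weights.sum()))]


def _set_lof_assay(row: dict, modality: str, sdhx_excluded: bool) -> None:
    if modality == "ihc":
        row["shdb_ihc"] = "negative"
        if sdhx_excluded:
            row["sdha_ihc"] = "positive"
    elif modality == "activity":
        row["sdh_activity"] = "lost"
    elif modality == "cluster":
        row["transcriptomic_cluster"] = "cluster_1A"
    elif modality == "western":
        row["western_blot"] = "reduced"
    if sdhx_excluded:
        row["other_sdhx_excluded"] = "true"


_PATH_MISSENSE_PREDICTORS = {
    "cons_ratio": "1.0", "polyphen2": "probably_damaging",
    "sift": "deleterious", "phylop": "3.1",
}
_BENIGN_MISSENSE_PREDICTORS = {
    "cons_ratio": "0.21", "polyphen2": "benign", "sift": "tolerated",
}
_BENIGN_SPLICE_PREDICTORS = {
    "mes_ref": "8.6", "mes_alt": "8.6", "nns_ref": "0.8", "nns_alt": "0.8",
}
_PATH_SPLICE_PREDICTORS = {
    "mes_ref": "9.4", "mes_alt": "0.8", "nns_ref": "0.9", "nns_alt": "0.1",
}


def _evidence_row(
    variant: Variant,
    truth: FiveTierClass,
    occurrence: int,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> dict:
    rates = config.evidence_availability
    row = {c: "" for c in
           ("af", "af_source", "loh", "shdb_ihc", "sdha_ihc", "sdh_activity",
            "western_blot", "transcriptomic_cluster", "cdna_splicing",
            "other_sdhx_excluded", "coseg_meioses", "coseg_segregates",
            "prior_pathogenic", "prior_benign")}
    row.update({
        "cdna": variant.cdna,
        "protein": variant.protein or "",
        "vtype": variant.vtype.value,
        "case_count": str(occurrence),
    })
    truncating = variant.vtype in TRUNCATING_TYPES
    missense = variant.vtype == VariantType.MISSENSE
    splice_candidate = variant.vtype in (
        VariantType.SPLICE_SITE_SUBSTITUTION, VariantType.SPLICE_SITE_INDEL,
        VariantType.MID_INTRONIC, VariantType.SYNONYMOUS,
        VariantType.NONCODING_INDEL,
    )

    if truth == FiveTierClass.BV:
        row["af"], row["af_source"] = "0.01", "gnomAD"
        if rng.random() < rates.get("loh", 0):
            row["loh"] = "variant_allele_lost"
    elif truth == FiveTierClass.LBV:
        row["af"], row["af_source"] = "0.001", "gnomAD"
        row.update(
            _BENIGN_MISSENSE_PREDICTORS if missense else _BENIGN_SPLICE_PREDICTORS
        )
    elif truth == FiveTierClass.VUS:
        pass  # absent from controls, no informative evidence
    elif truth == FiveTierClass.LPV:
        if truncating:
            # rare but observed in controls: the null type alone carries the call
            row["af"], row["af_source"] = "0.0001", "gnomAD"
        else:
            if missense:
                row.update(_PATH_MISSENSE_PREDICTORS)
            _set_lof_assay(row, _pick_modality(rng, rates), sdhx_excluded=False)
            row["prior_pathogenic"], row["prior_benign"] = "3", "0"
    else:  # PV
        if missense:
            row.update(_PATH_MISSENSE_PREDICTORS)
            row["coseg_meioses"], row["coseg_segregates"] = "4", "true"
            _set_lof_assay(row, "ihc", sdhx_excluded=True)
            row["prior_pathogenic"], row["prior_benign"] = "6", "0"
        else:
            _set_lof_assay(row, _pick_modality(rng, rates), sdhx_excluded=True)
            if rng.random() < rates.get("loh", 0):
                row["loh"] = "variant_allele_retained_wt_lost"
            if splice_candidate and rng.random() < rates.get("cdna", 0):
                row["cdna_splicing"] = "aberrant"
                row.update(_PATH_SPLICE_PREDICTORS)

    if config.evidence_noise > 0 and rng.random() < config.evidence_noise:
        _inject_noise(row, rng)
    return row


def _inject_noise(row: dict, rng: np.random.Generator) -> None:
    """Flip one assay field against the truth-consistent direction."""
    flips = {
        "shdb_ihc": {"negative": "positive", "positive": "negative", "": "negative"},
        "sdh_activity": {"lost": "preserved", "preserved": "lost", "": "lost"},
        "loh": {"variant_allele_retained_wt_lost": "variant_allele_lost",
                "variant_allele_lost": "variant_allele_retained_wt_lost",
                "": "variant_allele_lost"},
    }
    field_name = ("shdb_ihc", "sdh_activity", "loh")[int(rng.choice(3))]
    row[field_name] = flips[field_name].get(row[field_name], row[field_name])


# --- clinical synthesis ------------------------------------------------------

def _draw_categorical(rng: np.random.Generator, counts: Mapping[str, int]) -> str:
    keys = list(counts)
    weights = np.array([float(counts[k]) for k in keys])
    return keys[int(rng.choice(len(keys), p=weights / weights.sum()))]


def _make_case(
    case_id: str, variant: Variant, rng: np.random.Generator,
    comp: Mapping[str, Mapping[str, int]],
) -> IndexCase:
    pres = _draw_categorical(rng, comp["presentation"])
    n_tumours: Optional[int] = None
    sites: Optional[frozenset] = None
    if pres == "single_head_neck_PGL":
        n_tumours, sites = 1, frozenset({"head_neck_PGL"})
    elif pres == "single_TAP_PGL":
        n_tumours, sites = 1, frozenset({"TAP_PGL"})
    elif pres == "single_PCC":
        n_tumours, sites = 1, frozenset({"PCC"})
    elif pres == "single_unspecified_site":
        n_tumours, sites = 1, frozenset({"unspecified"})
    elif pres == "multiple_PPGL":
        n_tumours, sites = int(rng.integers(2, 8)), frozenset({"unspecified"})
    elif pres == "RCC_only":
        n_tumours, sites = 1, frozenset({"RCC"})
    elif pres == "GIST_only":
        n_tumours, sites = 1, frozenset({"GIST"})

    metastatic = _draw_categorical(rng, comp["metastatic"])
    if pres == "not_specified":
        metastatic = "unknown"  # metastasis cannot be asserted without tumour data
    family = _draw_categorical(rng, comp["family_history"])
    age = float(np.clip(rng.normal(36.0, 14.0), 6.0, 83.0))
    return IndexCase(
        case_id=case_id,
        variant=variant,
        n_tumours=n_tumours,
        tumour_sites=sites,
        metastatic=None if metastatic == "unknown" else metastatic,
        family_history=None if family == "unknown" else family,
        age_at_diagnosis=round(age, 1),
    )


def _case_row(case: IndexCase) -> dict:
    return {
        "case_id": case.case_id,
        "cdna": case.variant.cdna,
        "protein": case.variant.protein or "",
        "vtype": case.variant.vtype.value,
        "n_tumours": "" if case.n_tumours is None else str(case.n_tumours),
        "tumour_sites": ",".join(sorted(case.tumour_sites)) if case.tumour_sites else "",
        "metastatic": case.metastatic or "",
        "family_history": case.family_history or "",
        "age_at_diagnosis": (
            "" if case.age_at_diagnosis is None else f"{case.age_at_diagnosis:.1f}"
        ),
    }


# --- main entry --------------------------------------------------------------

_CLASS_ORDER = [FiveTierClass.PV, FiveTierClass.LPV, FiveTierClass.VUS,
                FiveTierClass.LBV, FiveTierClass.BV]


def generate(config: GeneratorConfig = GeneratorConfig()) -> CohortBundle:
    """Generate a cohort with the configured structure and known truth.

    The seed fully determines the output.  Occurrence counts are assigned
    in descending order to classes ordered PV, LPV, VUS, LBV, BV, so the
    recurrent alleles are the pathogenic ones, as in real SDHB cohorts
    (founder alleles and rearrangement hotspots).
    """
    rng = np.random.default_rng(config.seed)
    occurrences = sorted(_occurrence_counts(config, rng), reverse=True)
    pairs = _joint_assignment(config)
    pairs.sort(key=lambda p: (_CLASS_ORDER.index(p[1]), list(VariantType).index(p[0])))

    factory = _HgvsFactory(rng)
    evidence_rows, profiles, truth = [], [], {}
    for (vtype, cls), occurrence in zip(pairs, occurrences):
        variant = factory.make(vtype)
        row = _evidence_row(variant, cls, occurrence, rng, config)
        evidence_rows.append(row)
        profiles.append(profile_from_row(row))
        truth[variant] = cls

    cases, case_rows = [], []
    case_no = 0
    for profile, occurrence in zip(profiles, occurrences):
        for _ in range(occurrence):
            case_no += 1
            case = _make_case(
                f"IC{case_no:06d}", profile.variant, rng, config.clinical_composition
            )
            cases.append(case)
            case_rows.append(_case_row(case))
    return CohortBundle(cases, profiles, truth, evidence_rows, case_rows)


# --- fixtures built from the reference tabulations ---------------------------

def fixture_dual_classifications() -> list[DualClassification]:
    """223 framework-class pairs reproducing the reference concordance
    breakdown, attached to synthetic placeholder variants."""
    pairs: list[DualClassification] = []
    pos = iter(range(10, 900))

    def placeholder() -> Variant:
        return parse_variant(f"c.{next(pos)}G>A")

    for cls, n in CONCORDANT_BREAKDOWN.items():
        pairs.extend(
            DualClassification(placeholder(), cls, cls) for _ in range(n)
        )
    for (a, b), n in DISCORDANT_BREAKDOWN.items():
        pairs.extend(
            DualClassification(placeholder(), a, b) for _ in range(n)
        )
    return pairs


def fixture_clinical_cases() -> tuple[list[IndexCase], dict[str, FiveTierClass]]:
    """737 index cases reproducing the clinical composition exactly, with
    614 (likely) pathogenic carriers flagged via the class mapping.

    Field strata are assigned deterministically and independently per field
    (the joint distribution across fields is not part of the reference
    tabulation); the unspecified-presentation cases are placed in the
    unknown-metastatic stratum so every record is internally consistent.
    """
    comp = CLINICAL_COMPOSITION
    presentations = [
        k for k, n in comp["presentation"].items() for _ in range(n)
    ]
    metastatic = [k for k, n in comp["metastatic"].items() for _ in range(n)]
    family = [k for k, n in comp["family_history"].items() for _ in range(n)]
    carrier = parse_variant("c.137G>A", "p.Arg46Gln")
    non_carrier = parse_variant("c.8C>T", "p.Ser3Leu")
    classes = {carrier.cdna: FiveTierClass.PV, non_carrier.cdna: FiveTierClass.VUS}

    cases = []
    for i, (pres, meta, fam) in enumerate(zip(presentations, metastatic, family)):
        n_tumours, sites = None, None
        if pres == "single_head_neck_PGL":
            n_tumours, sites = 1, frozenset({"head_neck_PGL"})
        elif pres == "single_TAP_PGL":
            n_tumours, sites = 1, frozenset({"TAP_PGL"})
        elif pres == "single_PCC":
            n_tumours, sites = 1, frozenset({"PCC"})
        elif pres == "single_unspecified_site":
            n_tumours, sites = 1, frozenset({"unspecified"})
        elif pres == "multiple_PPGL":
            n_tumours, sites = 2, frozenset({"unspecified"})
        elif pres == "RCC_only":
            n_tumours, sites = 1, frozenset({"RCC"})
        elif pres == "GIST_only":
            n_tumours, sites = 1, frozenset({"GIST"})
        cases.append(IndexCase(
            case_id=f"T{i + 1:04d}",
            variant=carrier if i < COHORT_SIZES["n_lp_p_carriers"] else non_carrier,
            n_tumours=n_tumours,
            tumour_sites=sites,
            metastatic=None if meta == "unknown" else meta,
            family_history=None if fam == "unknown" else fam,
        ))
    return cases, classes
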