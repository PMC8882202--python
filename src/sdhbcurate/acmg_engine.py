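"""SDHB/PPGL-adapted ACMG criterion assignment and 5-tier combination.

The engine applies the standard ACMG/AMP evidence codes that are evaluable
for SDHB, a dominantly inherited, incompletely penetrant tumour-suppressor
gene, and excludes the codes that are not applicable to it: PS4, BP1, PP2,
PM1, PM3, PM6, PS2 (de novo SDHB events are exceptional) and PP4 (the PPGL
phenotype is not gene-specific, since many susceptibility genes exist).

Tumour-based evidence is mapped onto a six-step adapted strength ladder:

====================  ========================================================
benign strong         loss of the allele carrying the SDHB variant in tumour
benign supporting     no LOH at the SDHB locus, or an assay not in favour of
                      SDHB loss of function
pathogenic supporting LOH at the SDHB locus (wild-type allele lost)
pathogenic moderate   assay in favour of SDH loss of function without all
                      SDHx genes analysed
pathogenic strong     SDH loss of function with no additional SDHx variant
pathogenic very strong SDHB-specific loss of function (SDHB immunostaining
                      negative with SDHA positive, other SDHx excluded)
====================  ========================================================

These adapted criteria carry package-local codes (BS-LOH, BP-FUNC, PP-LOH,
PM-FUNC, PS-FUNC, PVS-FUNC) and enter the ordinary combining algebra
alongside the standard codes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .insilico import Verdict
from .variant_model import FiveTierClass, Variant, VariantType, TRUNCATING_TYPES


class Strength(str, enum.Enum):
    STAND_ALONE_BENIGN = "stand_alone_benign"
    BENIGN_STRONG = "benign_strong"
    BENIGN_SUPPORTING = "benign_supporting"
    PATHOGENIC_SUPPORTING = "pathogenic_supporting"
    PATHOGENIC_MODERATE = "pathogenic_moderate"
    PATHOGENIC_STRONG = "pathogenic_strong"
    PATHOGENIC_VERY_STRONG = "pathogenic_very_strong"

    @property
    def benign_side(self) -> bool:
        return self in (
            Strength.STAND_ALONE_BENIGN,
            Strength.BENIGN_STRONG,
            Strength.BENIGN_SUPPORTING,
        )


#: ACMG codes never emitted for SDHB.
EXCLUDED_CODES = frozenset({"PS4", "BP1", "PP2", "PM1", "PM3", "PM6", "PS2", "PP4"})

# package-local codes for the adapted tumour-evidence tiers
FUNCTIONAL_CODES = frozenset(
    {"BS-LOH", "BP-FUNC", "PP-LOH", "PM-FUNC", "PS-FUNC", "PVS-FUNC"}
)


@dataclass(frozen=True)
class Cosegregation:
    informative_meioses: int
    segregates: bool


@dataclass(frozen=True)
class PriorReports:
    pathogenic_assertions: int = 0
    benign_assertions: int = 0


_TERNARY = {
    "loh": {"variant_allele_retained_wt_lost", "variant_allele_lost", "no_loh", "not_done"},
    "shdb_ihc": {"negative", "positive", "not_done"},
    "sdha_ihc": {"negative", "positive", "not_done"},
    "sdh_activity": {"lost", "preserved", "not_done"},
    "western_blot": {"reduced", "normal", "not_done"},
    "transcriptomic_cluster": {"cluster_1A", "cluster_1B", "cluster_2A", "not_done"},
    "cdna_splicing_shown": {"aberrant", "normal", "not_done"},
}


@dataclass(frozen=True)
class EvidenceProfile:
    """All machine-readable evidence attached to one distinct variant."""

    variant: Variant
    max_population_af: Optional[float] = None
    af_source: Optional[str] = None          # e.g. "gnomAD", "ESP"
    case_count: int = 1
    cosegregation: Optional[Cosegregation] = None
    de_novo: bool = False                    # recorded but unused (PS2/PM6 excluded)
    insilico_missense: Optional[Verdict] = None
    insilico_splice: Optional[Verdict] = None
    cdna_splicing_shown: str = "not_done"
    loh: str = "not_done"
    shdb_ihc: str = "not_done"
    sdha_ihc: str = "not_done"
    sdh_activity: str = "not_done"
    western_blot: str = "not_done"
    transcriptomic_cluster: str = "not_done"
    other_sdhx_excluded: bool = False
    prior_reports: Optional[PriorReports] = None
    same_aa_change_reported_pathogenic: bool = False   # PS1-type prior
    same_codon_other_pathogenic: bool = False          # PM5-type prior

    def __post_init__(self):
        if self.case_count < 1:
            raise ValueError("case_count must be >= 1")
        if self.max_population_af is not None and not (
            0.0 <= self.max_population_af <= 1.0
        ):
            raise ValueError("max_population_af must lie in [0, 1]")
        for name, allowed in _TERNARY.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"{name} must be one of {sorted(allowed)}, got {value!r}")


@dataclass(frozen=True)
class Criterion:
    code: str
    strength: Strength
    rationale: str = ""
    conflict: bool = False


@dataclass(frozen=True)
class CriterionSet:
    """The set of criteria met for one variant (each code at most once)."""

    met: frozenset[Criterion] = frozenset()

    def __post_init__(self):
        codes = [c.code for c in self.met]
        if len(codes) != len(set(codes)):
            raise ValueError("each criterion code may appear at most once")
        bad = set(codes) & EXCLUDED_CODES
        if bad:
            raise ValueError(f"excluded ACMG codes present: {sorted(bad)}")

    @property
    def codes(self) -> set[str]:
        return {c.code for c in self.met}

    def strength_counts(self) -> dict[Strength, int]:
        counts = {s: 0 for s in Strength}
        for c in self.met:
            counts[c.strength] += 1
        return counts


@dataclass(frozen=True)
class AcmgConfig:
    """Thresholds for the frequency, segregation and reputation criteria.

    The allele-frequency cutoffs are package defaults chosen for a rare,
    incompletely penetrant dominant tumour syndrome; all are configurable and
    echoed (via the config hash) in every report.
    """

    ba1_af: float = 0.005
    bs1_af: float = 0.0005
    pm2_af: float = 0.00001
    min_informative_meioses: int = 3
    initiation_codon_strength: Strength = Strength.PATHOGENIC_STRONG
    # reputation ladder over net prior assertions (pathogenic - benign)
    reputation_strong_net: int = 5
    reputation_moderate_net: int = 2
    reputation_supporting_net: int = 1
    reputation_benign_strong_net: int = -2


DEFAULT_ACMG_CONFIG = AcmgConfig()

_LOF_ASSAYS = (
    ("shdb_ihc", "negative", "positive"),
    ("sdh_activity", "lost", "preserved"),
    ("western_blot", "reduced", "normal"),
    ("transcriptomic_cluster", "cluster_1A", None),
    ("cdna_splicing_shown", "aberrant", "normal"),
)


def _lof_assay_signals(e: EvidenceProfile) -> tuple[bool, bool]:
    """(any assay in favour of SDH loss of function, any assay against it)."""
    in_favour = any(getattr(e, f) == pos for f, pos, _ in _LOF_ASSAYS)
    against = any(
        neg is not None and getattr(e, f) == neg for f, _, neg in _LOF_ASSAYS
    ) or e.transcriptomic_cluster in ("cluster_1B", "cluster_2A")
    return in_favour, against


def assign_functional_criteria(e: EvidenceProfile) -> set[Criterion]:
    """Map tumour-based evidence onto the adapted strength ladder.

    Mutually contradictory assays (benign-direction and pathogenic-direction
    evidence simultaneously) are all returned, each flagged with
    ``conflict=True``, rather than silently resolved.
    """
    lof_pos, lof_neg = _lof_assay_signals(e)
    criteria: list[Criterion] = []

    if e.loh == "variant_allele_lost":
        criteria.append(
            Criterion("BS-LOH", Strength.BENIGN_STRONG,
                      "variant-carrying allele lost in tumour DNA")
        )
    if e.loh == "no_loh" or lof_neg:
        criteria.append(
            Criterion("BP-FUNC", Strength.BENIGN_SUPPORTING,
                      "no LOH at the SDHB locus / assay not in favour of SDHB LOF")
        )
    if e.loh == "variant_allele_retained_wt_lost":
        criteria.append(
            Criterion("PP-LOH", Strength.PATHOGENIC_SUPPORTING,
                      "LOH at the SDHB locus (wild-type allele lost)")
        )
    if lof_pos:
        sdhb_specific = (
            e.shdb_ihc == "negative"
            and e.sdha_ihc == "positive"
            and e.other_sdhx_excluded
        )
        if sdhb_specific:
            criteria.append(
                Criterion("PVS-FUNC", Strength.PATHOGENIC_VERY_STRONG,
                          "SDHB-specific loss of function "
                          "(SDHB IHC negative, SDHA positive, other SDHx excluded)")
            )
        elif e.other_sdhx_excluded:
            criteria.append(
                Criterion("PS-FUNC", Strength.PATHOGENIC_STRONG,
                          "SDH loss of function, no additional SDHx variant")
            )
        else:
            criteria.append(
                Criterion("PM-FUNC", Strength.PATHOGENIC_MODERATE,
                          "SDH loss of function without all SDHx genes analysed")
            )

    benign_dir = any(c.strength.benign_side for c in criteria)
    path_dir = any(not c.strength.benign_side for c in criteria)
    if benign_dir and path_dir:
        criteria = [
            Criterion(c.code, c.strength, c.rationale, conflict=True)
            for c in criteria
        ]
    return set(criteria)


def _pvs1(e: EvidenceProfile, config: AcmgConfig) -> Optional[Criterion]:
    v = e.variant
    if v.vtype not in TRUNCATING_TYPES:
        return None
    if v.vtype == VariantType.LARGE_REARRANGEMENT and "dup" in v.cdna:
        return None  # whole-exon duplications are not clear null alleles
    if v.vtype in (
        VariantType.SPLICE_SITE_SUBSTITUTION, VariantType.SPLICE_SITE_INDEL
    ) and e.cdna_splicing_shown == "normal":
        return None  # RNA analysis rescued the splice site
    strength = (
        config.initiation_codon_strength
        if v.vtype == VariantType.INITIATION_CODON
        else Strength.PATHOGENIC_VERY_STRONG
    )
    return Criterion("PVS1", strength, f"null variant ({v.vtype.value})")


def assign_criteria(
    e: EvidenceProfile, config: AcmgConfig = DEFAULT_ACMG_CONFIG
) -> CriterionSet:
    """Evaluate every applicable criterion for one evidence profile.

    An absent population frequency is treated as absence from controls
    (PM2); the excluded-code invariant holds for every input.
    """
    criteria: list[Criterion] = []

    c = _pvs1(e, config)
    if c:
        criteria.append(c)

    af = e.max_population_af
    if af is not None and af >= config.ba1_af:
        criteria.append(
            Criterion("BA1", Strength.STAND_ALONE_BENIGN,
                      f"AF {af:g} >= {config.ba1_af:g}")
        )
    elif af is not None and af >= config.bs1_af:
        criteria.append(
            Criterion("BS1", Strength.BENIGN_STRONG,
                      f"AF {af:g} >= {config.bs1_af:g}")
        )
    elif af is None or af <= config.pm2_af:
        criteria.append(
            Criterion("PM2", Strength.PATHOGENIC_MODERATE,
                      "absent or ultra-rare in population controls")
        )

    if e.variant.vtype == VariantType.INFRAME_INDEL:
        criteria.append(
            Criterion("PM4", Strength.PATHOGENIC_MODERATE, "protein length change")
        )

    coseg = e.cosegregation
    if coseg is not None and coseg.informative_meioses >= config.min_informative_meioses:
        if coseg.segregates:
            criteria.append(
                Criterion("PP1", Strength.PATHOGENIC_SUPPORTING,
                          f"co-segregation over {coseg.informative_meioses} meioses")
            )
        else:
            criteria.append(
                Criterion("BS4", Strength.BENIGN_STRONG, "non-segregation in family")
            )

    if e.same_aa_change_reported_pathogenic:
        criteria.append(
            Criterion("PS1", Strength.PATHOGENIC_STRONG,
                      "same amino-acid change previously established pathogenic")
        )
    elif e.same_codon_other_pathogenic:
        criteria.append(
            Criterion("PM5", Strength.PATHOGENIC_MODERATE,
                      "different pathogenic change at the same codon")
        )

    verdicts = [v for v in (e.insilico_missense, e.insilico_splice) if v is not None]
    if Verdict.SUPPORTS_PATHOGENIC in verdicts:
        criteria.append(
            Criterion("PP3", Strength.PATHOGENIC_SUPPORTING,
                      "computational evidence supports a deleterious effect")
        )
    elif Verdict.SUPPORTS_BENIGN in verdicts:
        criteria.append(
            Criterion("BP4", Strength.BENIGN_SUPPORTING,
                      "computational evidence supports no impact")
        )

    if (
        e.variant.vtype == VariantType.SYNONYMOUS
        and e.insilico_splice == Verdict.SUPPORTS_BENIGN
    ):
        criteria.append(
            Criterion("BP7", Strength.BENIGN_SUPPORTING,
                      "synonymous with no predicted splice impact")
        )

    if e.prior_reports is not None:
        net = (
            e.prior_reports.pathogenic_assertions
            - e.prior_reports.benign_assertions
        )
        if net >= config.reputation_strong_net:
            criteria.append(Criterion("REP", Strength.PATHOGENIC_STRONG,
                                      f"net prior assertions {net:+d}"))
        elif net >= config.reputation_moderate_net:
            criteria.append(Criterion("REP", Strength.PATHOGENIC_MODERATE,
                                      f"net prior assertions {net:+d}"))
        elif net >= config.reputation_supporting_net:
            criteria.append(Criterion("REP", Strength.PATHOGENIC_SUPPORTING,
                                      f"net prior assertions {net:+d}"))
        elif net <= config.reputation_benign_strong_net:
            criteria.append(Criterion("REP", Strength.BENIGN_STRONG,
                                      f"net prior assertions {net:+d}"))

    criteria.extend(assign_functional_criteria(e))
    return CriterionSet(frozenset(criteria))


def combine(criteria: CriterionSet) -> FiveTierClass:
    """Fold a criterion set into a 5-tier class by the combining rules.

    Pathogenic: >=1 very strong with (>=1 strong, or >=1 moderate, or >=2
    supporting); or >=2 very strong; or >=2 strong; or 1 strong with (>=3
    moderate, or 2 moderate + >=2 supporting, or 1 moderate + >=4 supporting).
    Likely pathogenic: 1 strong + 1-2 moderate; 1 strong + >=2 supporting;
    >=3 moderate; 2 moderate + >=2 supporting; 1 moderate + >=4 supporting.
    Benign: 1 stand-alone, or >=2 strong benign.  Likely benign: 1 strong
    benign + 1 supporting, or >=2 supporting benign.  Simultaneous benign-
    and pathogenic-rule satisfaction, or nothing satisfied, yields VUS.
    """
    n = criteria.strength_counts()
    vs = n[Strength.PATHOGENIC_VERY_STRONG]
    s = n[Strength.PATHOGENIC_STRONG]
    m = n[Strength.PATHOGENIC_MODERATE]
    p = n[Strength.PATHOGENIC_SUPPORTING]
    sa = n[Strength.STAND_ALONE_BENIGN]
    bs = n[Strength.BENIGN_STRONG]
    bp = n[Strength.BENIGN_SUPPORTING]

    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 1 or p >= 2))
        or vs >= 2
        or s >= 2
        or (s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)))
    )
    likely_pathogenic = (
        (s >= 1 and (m >= 1 or p >= 2))
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    benign = sa >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return FiveTierClass.VUS
    if pathogenic:
        return FiveTierClass.PV
    if likely_pathogenic:
        return FiveTierClass.LPV
    if benign:
        return FiveTierClass.BV
    if likely_benign:
        return FiveTierClass.LBV
    return FiveTierClass.VUS


def classify_acmg(
    e: EvidenceProfile, config: AcmgConfig = DEFAULT_ACMG_CONFIG
) -> tuple[FiveTierClass, CriterionSet]:
    """Convenience wrapper: assign criteria then combine."""
    cs = assign_criteria(e, config)
    return combine(cs), cs
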