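"""Concordance analysis and deterministic emulation of expert curation.

The two framework classes are compared per variant; concordant calls keep
their class unless a documented override or the recurrence-promotion rule
applies, while discordant calls are resolved by a deterministic arbitration
policy.  Variants the policy cannot resolve in round 1 go to a second round
with a conservative tie-break.  Genuine expert judgment is not simulatable:
it is externalised as an override ledger (TSV: cdna, final_class, citation)
that takes absolute precedence over the policy at both rounds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .acmg_engine import (
    AcmgConfig,
    Criterion,
    CriterionSet,
    DEFAULT_ACMG_CONFIG,
    EvidenceProfile,
    Strength,
    assign_criteria,
)
from .variant_model import FiveTierClass, Variant


@dataclass(frozen=True)
class DualClassification:
    """One variant's independent ACMG and NGSnPPGL classes."""

    variant: Variant
    acmg: FiveTierClass
    ngs: FiveTierClass

    @property
    def concordant(self) -> bool:
        return self.acmg == self.ngs


@dataclass(frozen=True)
class CurationDecision:
    variant: Variant
    round: int                       # 1 or 2
    pre: tuple[FiveTierClass, ...]   # class(es) entering the round
    post: FiveTierClass
    source: str                      # "policy" | "override"
    rationale: str


@dataclass(frozen=True)
class ConcordanceSummary:
    n_concordant: int
    n_discordant: int
    breakdown: Mapping[tuple[FiveTierClass, FiveTierClass], int]


@dataclass(frozen=True)
class ConsensusPolicy:
    """Arbitration policy parameters.

    ``recurrence_threshold`` is the number of independent index cases above
    which a concordant LPV with strong functional evidence is promoted to PV
    (the promoted alleles in practice are reported 18-52 times, so 10 is a
    deliberately conservative default).
    """

    recurrence_threshold: int = 10


DEFAULT_POLICY = ConsensusPolicy()


class LedgerError(KeyError):
    """An override ledger entry references a variant absent from the input."""


def concordance(pairs: Iterable[DualClassification]) -> ConcordanceSummary:
    """Count concordant/discordant pairs with an unordered class-pair breakdown."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("concordance requires at least one classification pair")
    breakdown: Counter = Counter()
    n_conc = 0
    for pair in pairs:
        key = tuple(sorted((pair.acmg, pair.ngs)))
        breakdown[key] += 1
        n_conc += pair.concordant
    return ConcordanceSummary(n_conc, len(pairs) - n_conc, dict(breakdown))


# --- evidence direction helpers ----------------------------------------------

def _functional_direction(criteria: CriterionSet) -> str:
    """Direction of tumour-assay evidence: pathogenic / benign / conflicting / none."""
    from .acmg_engine import FUNCTIONAL_CODES

    func = [c for c in criteria.met if c.code in FUNCTIONAL_CODES]
    path = any(not c.strength.benign_side for c in func)
    benign = any(c.strength.benign_side for c in func)
    if path and benign:
        return "conflicting"
    if path:
        return "pathogenic"
    if benign:
        return "benign"
    return "none"


def _directional_evidence(criteria: CriterionSet) -> str:
    """Direction of any criterion beyond bare rarity (PM2 is too weak to
    arbitrate a discordance on its own)."""
    path = any(
        not c.strength.benign_side and c.code != "PM2" for c in criteria.met
    )
    benign = any(c.strength.benign_side for c in criteria.met)
    if path and benign:
        return "conflicting"
    if path:
        return "pathogenic"
    if benign:
        return "benign"
    return "none"


def _has_strong_functional(criteria: CriterionSet) -> bool:
    from .acmg_engine import FUNCTIONAL_CODES

    return any(
        c.code in FUNCTIONAL_CODES
        and c.strength in (Strength.PATHOGENIC_STRONG, Strength.PATHOGENIC_VERY_STRONG)
        for c in criteria.met
    )


def _criteria_for(
    pair: DualClassification,
    profiles: Optional[Mapping[str, EvidenceProfile]],
    config: AcmgConfig,
) -> CriterionSet:
    if profiles is None or pair.variant.cdna not in profiles:
        return CriterionSet(frozenset())
    return assign_criteria(profiles[pair.variant.cdna], config)


def _check_ledger(
    overrides: Mapping[str, tuple[FiveTierClass, str]],
    known: set[str],
) -> None:
    unknown = set(overrides) - known
    if unknown:
        raise LedgerError(
            f"override ledger references unknown variants: {sorted(unknown)}"
        )


def curate_round1(
    pairs: Iterable[DualClassification],
    profiles: Optional[Mapping[str, EvidenceProfile]] = None,
    overrides: Optional[Mapping[str, tuple[FiveTierClass, str]]] = None,
    policy: ConsensusPolicy = DEFAULT_POLICY,
    acmg_config: AcmgConfig = DEFAULT_ACMG_CONFIG,
) -> tuple[list[CurationDecision], dict[str, DualClassification]]:
    """First curation round.

    Concordant pairs keep their class unless an override or the
    recurrence-promotion rule fires (LPV, case count at or above the policy
    threshold, and at least one strong/very-strong pathogenic functional
    criterion -> PV).  Discordant pairs resolve by: (1) override; (2) the
    class supported by the tumour-assay direction; (3) the non-VUS class when
    the gap is one class and other evidence is directional and agrees; else
    they are passed unresolved to round 2.
    """
    pairs = list(pairs)
    overrides = dict(overrides or {})
    seen: set[str] = set()
    for pair in pairs:
        if pair.variant.cdna in seen:
            raise ValueError(f"variant appears twice: {pair.variant.cdna}")
        seen.add(pair.variant.cdna)
    _check_ledger(overrides, seen)

    decisions: list[CurationDecision] = []
    unresolved: dict[str, DualClassification] = {}
    for pair in pairs:
        cdna = pair.variant.cdna
        if cdna in overrides:
            cls, citation = overrides[cdna]
            decisions.append(CurationDecision(
                pair.variant, 1, (pair.acmg, pair.ngs), cls, "override", citation
            ))
            continue
        criteria = _criteria_for(pair, profiles, acmg_config)
        if pair.concordant:
            cls = pair.acmg
            rationale = "concordant, unchanged"
            profile = (profiles or {}).get(cdna)
            if (
                cls == FiveTierClass.LPV
                and profile is not None
                and profile.case_count >= policy.recurrence_threshold
                and _has_strong_functional(criteria)
            ):
                cls = FiveTierClass.PV
                rationale = (
                    f"recurrence promotion: {profile.case_count} index cases "
                    "with strong functional evidence"
                )
            decisions.append(CurationDecision(
                pair.variant, 1, (pair.acmg, pair.ngs), cls, "policy", rationale
            ))
            continue
        # discordant
        lo, hi = sorted((pair.acmg, pair.ngs))
        func_dir = _functional_direction(criteria)
        if func_dir == "pathogenic":
            decisions.append(CurationDecision(
                pair.variant, 1, (pair.acmg, pair.ngs), hi, "policy",
                "discordant, tumour-assay evidence pathogenic-direction"
            ))
            continue
        if func_dir == "benign":
            decisions.append(CurationDecision(
                pair.variant, 1, (pair.acmg, pair.ngs), lo, "policy",
                "discordant, tumour-assay evidence benign-direction"
            ))
            continue
        gap = hi - lo
        any_dir = _directional_evidence(criteria)
        if gap == 1 and FiveTierClass.VUS in (lo, hi):
            non_vus = hi if lo == FiveTierClass.VUS else lo
            agrees = (
                (any_dir == "pathogenic" and non_vus > FiveTierClass.VUS)
                or (any_dir == "benign" and non_vus < FiveTierClass.VUS)
            )
            if agrees:
                decisions.append(CurationDecision(
                    pair.variant, 1, (pair.acmg, pair.ngs), non_vus, "policy",
                    f"discordant by one class, {any_dir}-direction evidence "
                    "favours the non-VUS class"
                ))
                continue
        unresolved[cdna] = pair
    return decisions, unresolved


def curate_round2(
    unresolved: Mapping[str, DualClassification],
    profiles: Optional[Mapping[str, EvidenceProfile]] = None,
    overrides: Optional[Mapping[str, tuple[FiveTierClass, str]]] = None,
    acmg_config: AcmgConfig = DEFAULT_ACMG_CONFIG,
) -> list[CurationDecision]:
    """Second curation round: every remaining variant is resolved.

    Overrides win; otherwise the more pathogenic candidate is taken when any
    pathogenic-direction functional criterion exists, and the less
    pathogenic candidate otherwise (conservative clinical default, since
    predictive testing of relatives requires an LPV/PV call).
    """
    overrides = dict(overrides or {})
    decisions: list[CurationDecision] = []
    for cdna in sorted(unresolved):
        pair = unresolved[cdna]
        lo, hi = sorted((pair.acmg, pair.ngs))
        if cdna in overrides:
            cls, citation = overrides[cdna]
            decisions.append(CurationDecision(
                pair.variant, 2, (lo, hi), cls, "override", citation
            ))
            continue
        criteria = _criteria_for(pair, profiles, acmg_config)
        if _functional_direction(criteria) == "pathogenic":
            decisions.append(CurationDecision(
                pair.variant, 2, (lo, hi), hi, "policy",
                "pathogenic-direction functional evidence"
            ))
        else:
            decisions.append(CurationDecision(
                pair.variant, 2, (lo, hi), lo, "policy",
                "no pathogenic functional evidence; conservative candidate"
            ))
    return decisions


@dataclass(frozen=True)
class ConsensusResult:
    variant: Variant
    acmg: FiveTierClass
    ngs: FiveTierClass
    round1: Optional[FiveTierClass]
    final: FiveTierClass
    source: str
    rationale: str


def run_consensus(
    pairs: Iterable[DualClassification],
    profiles: Optional[Mapping[str, EvidenceProfile]] = None,
    overrides: Optional[Mapping[str, tuple[FiveTierClass, str]]] = None,
    policy: ConsensusPolicy = DEFAULT_POLICY,
    acmg_config: AcmgConfig = DEFAULT_ACMG_CONFIG,
) -> list[ConsensusResult]:
    """Both curation rounds end to end; every variant exits with one class."""
    pairs = list(pairs)
    r1, unresolved = curate_round1(pairs, profiles, overrides, policy, acmg_config)
    r2 = curate_round2(unresolved, profiles, overrides, acmg_config)
    by_cdna_r1 = {d.variant.cdna: d for d in r1}
    by_cdna_r2 = {d.variant.cdna: d for d in r2}
    results = []
    for pair in pairs:
        cdna = pair.variant.cdna
        if cdna in by_cdna_r1:
            d = by_cdna_r1[cdna]
            results.append(ConsensusResult(
                pair.variant, pair.acmg, pair.ngs, d.post, d.post, d.source, d.rationale
            ))
        else:
            d = by_cdna_r2[cdna]
            results.append(ConsensusResult(
                pair.variant, pair.acmg, pair.ngs, None, d.post, d.source, d.rationale
            ))
    return results
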