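"""Concordance accounting and the two-round arbitration policy."""

import pytest

from sdhbcurate import (
    DualClassification,
    EvidenceProfile,
    FiveTierClass,
    LedgerError,
    concordance,
    curate_round1,
    curate_round2,
    fixture_dual_classifications,
    parse_variant,
    run_consensus,
)

BV, LBV, VUS, LPV, PV = FiveTierClass


def _pair(cdna, acmg, ngs):
    return DualClassification(parse_variant(cdna), acmg, ngs)


def test_concordance_reference_breakdown():
    """The transcribed framework-class pairs reproduce the 161/62 split."""
    summary = concordance(fixture_dual_classifications())
    assert summary.n_concordant == 161
    assert summary.n_discordant == 62
    assert summary.breakdown[(VUS, LPV)] == 23
    assert summary.breakdown[(VUS, PV)] == 6
    assert sum(summary.breakdown.values()) == 223


def test_concordance_edges():
    all_equal = [_pair(f"c.{i}G>A", VUS, VUS) for i in range(10, 15)]
    summary = concordance(all_equal)
    assert (summary.n_concordant, summary.n_discordant) == (5, 0)
    single = concordance([_pair("c.20G>A", VUS, LPV)])
    assert (single.n_concordant, single.n_discordant) == (0, 1)
    assert single.breakdown == {(VUS, LPV): 1}
    with pytest.raises(ValueError):
        concordance([])


def test_round1_concordant_unchanged():
    pair = _pair("c.30G>A", VUS, VUS)
    decisions, unresolved = curate_round1([pair])
    assert not unresolved
    assert decisions[0].post == VUS
    assert decisions[0].source == "policy"


def test_round1_recurrence_promotion():
    """A concordant LPV reported by many index cases with strong functional
    evidence is promoted to PV."""
    v = parse_variant("c.268C>T", "p.Arg90Ter")
    profile = EvidenceProfile(
        variant=v, case_count=52, max_population_af=1e-4,
        sdh_activity="lost", other_sdhx_excluded=True,
    )
    pair = DualClassification(v, LPV, LPV)
    decisions, _ = curate_round1([pair], {v.cdna: profile})
    assert decisions[0].post == PV
    assert "recurrence" in decisions[0].rationale
    # below the threshold: no promotion
    few = EvidenceProfile(
        variant=v, case_count=3, max_population_af=1e-4,
        sdh_activity="lost", other_sdhx_excluded=True,
    )
    decisions, _ = curate_round1([pair], {v.cdna: few})
    assert decisions[0].post == LPV


def test_round1_functional_evidence_wins_discordance():
    v = parse_variant("c.137G>A", "p.Arg46Gln")
    profile = EvidenceProfile(
        variant=v, shdb_ihc="negative", sdha_ihc="positive",
        other_sdhx_excluded=True,
    )
    pair = DualClassification(v, VUS, PV)
    decisions, unresolved = curate_round1([pair], {v.cdna: profile})
    assert not unresolved
    assert decisions[0].post == PV

    benign = EvidenceProfile(variant=v, loh="variant_allele_lost")
    pair2 = DualClassification(v, LBV, VUS)
    decisions, unresolved = curate_round1([pair2], {v.cdna: benign})
    assert decisions[0].post == LBV


def test_round1_one_class_gap_with_directional_evidence():
    v = parse_variant("c.166_170del")
    profile = EvidenceProfile(variant=v, max_population_af=1e-4)  # PVS1 only
    pair = DualClassification(v, VUS, LPV)
    decisions, unresolved = curate_round1([pair], {v.cdna: profile})
    assert not unresolved
    assert decisions[0].post == LPV


def test_round1_unresolvable_goes_to_round2():
    v = parse_variant("c.137G>A", "p.Arg46Gln")
    profile = EvidenceProfile(variant=v)  # PM2 only: not directional
    pair = DualClassification(v, VUS, LPV)
    decisions, unresolved = curate_round1([pair], {v.cdna: profile})
    assert not decisions
    assert set(unresolved) == {v.cdna}


def test_round2_resolves_everything():
    v1 = parse_variant("c.137G>A", "p.Arg46Gln")
    v2 = parse_variant("c.200A>G")
    unresolved = {
        v1.cdna: DualClassification(v1, LPV, PV),
        v2.cdna: DualClassification(v2, VUS, LBV),
    }
    profiles = {
        v1.cdna: EvidenceProfile(variant=v1, shdb_ihc="negative",
                                 sdha_ihc="positive", other_sdhx_excluded=True),
        v2.cdna: EvidenceProfile(variant=v2, loh="variant_allele_lost"),
    }
    decisions = curate_round2(unresolved, profiles)
    by = {d.variant.cdna: d.post for d in decisions}
    # pathogenic-direction functional evidence: more pathogenic candidate
    assert by[v1.cdna] == PV
    # benign-direction evidence: conservative (less pathogenic) candidate
    assert by[v2.cdna] == LBV
    assert all(d.round == 2 for d in decisions)


def test_round2_conservative_tiebreak_without_functional_evidence():
    v = parse_variant("c.137G>A", "p.Arg46Gln")
    decisions = curate_round2({v.cdna: DualClassification(v, VUS, LPV)})
    assert decisions[0].post == VUS


def test_override_ledger_precedence_and_errors():
    v = parse_variant("c.137G>A", "p.Arg46Gln")
    pair = DualClassification(v, LPV, PV)
    overrides = {v.cdna: (PV, "expert panel decision")}
    decisions = curate_round2({v.cdna: pair}, overrides=overrides)
    assert decisions[0].source == "override"
    assert decisions[0].post == PV

    decisions, unresolved = curate_round1([pair], overrides=overrides)
    assert decisions[0].source == "override" and not unresolved

    with pytest.raises(LedgerError):
        curate_round1([pair], overrides={"c.999G>A": (PV, "unknown variant")})


def test_pipeline_totality_and_conservation(bundle, pipeline_results):
    """Every variant ends with exactly one final class, and the round-1 /
    round-2 accounting tiles the cohort."""
    assert len(pipeline_results) == len(bundle.profiles)
    cdnas = [r.variant.cdna for r in pipeline_results]
    assert len(set(cdnas)) == len(cdnas)
    n_round1 = sum(1 for r in pipeline_results if r.round1 is not None)
    n_round2 = sum(1 for r in pipeline_results if r.round1 is None)
    assert n_round1 + n_round2 == len(bundle.profiles)
    assert all(r.final in FiveTierClass for r in pipeline_results)


def test_replay_determinism(bundle):
    from sdhbcurate.acmg_engine import classify_acmg
    from sdhbcurate.ngsnppgl_engine import classify_ngsnppgl

    pairs = []
    for p in bundle.profiles:
        a, _ = classify_acmg(p)
        n, _ = classify_ngsnppgl(p)
        pairs.append(DualClassification(p.variant, a, n))
    profiles = {p.variant.cdna: p for p in bundle.profiles}
    first = run_consensus(pairs, profiles)
    second = run_consensus(pairs, profiles)
    assert first == second


def test_duplicate_variant_rejected():
    pair = _pair("c.137G>A", VUS, VUS)
    with pytest.raises(ValueError):
        curate_round1([pair, pair])
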