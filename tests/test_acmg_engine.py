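"""Adapted criterion assignment and the 5-tier combining algebra."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tests_oracle_helpers import oracle_combine

from sdhbcurate import (
    Cosegregation,
    Criterion,
    CriterionSet,
    EXCLUDED_CODES,
    EvidenceProfile,
    FiveTierClass,
    PriorReports,
    Strength,
    Verdict,
    assign_criteria,
    assign_functional_criteria,
    combine,
    parse_variant,
)

MISSENSE = parse_variant("c.137G>A", "p.Arg46Gln")
NONSENSE = parse_variant("c.268C>T", "p.Arg90Ter")
SYNONYMOUS = parse_variant("c.540G>C", "p.(=)")
INFRAME = parse_variant("c.300_302del")
SPLICE = parse_variant("c.423+1G>C")


# --- adapted functional tiers -------------------------------------------------

def _codes(criteria):
    return {(c.code, c.strength) for c in criteria}


@pytest.mark.parametrize(
    "fields, expected",
    [
        # SDHB-specific loss of function: the very-strong hallmark
        (dict(shdb_ihc="negative", sdha_ihc="positive", other_sdhx_excluded=True),
         {("PVS-FUNC", Strength.PATHOGENIC_VERY_STRONG)}),
        # loss of the variant-carrying allele in tumour DNA
        (dict(loh="variant_allele_lost"), {("BS-LOH", Strength.BENIGN_STRONG)}),
        (dict(), set()),
        # LOH at the SDHB locus (wild-type allele lost)
        (dict(loh="variant_allele_retained_wt_lost"),
         {("PP-LOH", Strength.PATHOGENIC_SUPPORTING)}),
        # assay in favour of SDH LOF, SDHx genes not all analysed
        (dict(sdh_activity="lost"), {("PM-FUNC", Strength.PATHOGENIC_MODERATE)}),
        (dict(shdb_ihc="negative"), {("PM-FUNC", Strength.PATHOGENIC_MODERATE)}),
        (dict(transcriptomic_cluster="cluster_1A"),
         {("PM-FUNC", Strength.PATHOGENIC_MODERATE)}),
        # SDH LOF with the other SDHx genes excluded
        (dict(sdh_activity="lost", other_sdhx_excluded=True),
         {("PS-FUNC", Strength.PATHOGENIC_STRONG)}),
        # negative IHC without SDHA staining: strong, not very strong
        (dict(shdb_ihc="negative", other_sdhx_excluded=True),
         {("PS-FUNC", Strength.PATHOGENIC_STRONG)}),
        # assay not in favour of SDHB loss of function
        (dict(loh="no_loh"), {("BP-FUNC", Strength.BENIGN_SUPPORTING)}),
        (dict(shdb_ihc="positive"), {("BP-FUNC", Strength.BENIGN_SUPPORTING)}),
        (dict(transcriptomic_cluster="cluster_1B"),
         {("BP-FUNC", Strength.BENIGN_SUPPORTING)}),
    ],
)
def test_functional_tier_mapping(fields, expected):
    profile = EvidenceProfile(variant=MISSENSE, **fields)
    assert _codes(assign_functional_criteria(profile)) == expected


def test_contradictory_assays_flagged_not_dropped():
    profile = EvidenceProfile(
        variant=MISSENSE, loh="variant_allele_lost",
        shdb_ihc="negative", sdha_ihc="positive", other_sdhx_excluded=True,
    )
    criteria = assign_functional_criteria(profile)
    assert {c.code for c in criteria} == {"BS-LOH", "PVS-FUNC"}
    assert all(c.conflict for c in criteria)


# --- criterion assignment ----------------------------------------------------

def _criteria(profile):
    return assign_criteria(profile)


def test_nonsense_absent_from_controls_gets_pvs1_and_pm2():
    cs = _criteria(EvidenceProfile(variant=NONSENSE, max_population_af=None))
    assert {"PVS1", "PM2"} <= cs.codes


def test_prevalence_style_evidence_never_yields_ps4():
    # a profile engineered to look like a textbook case-control enrichment:
    # highly recurrent, rare in controls
    cs = _criteria(EvidenceProfile(
        variant=MISSENSE, case_count=50, max_population_af=1e-6,
    ))
    assert "PS4" not in cs.codes


def test_synonymous_benign_splice_prediction_gets_bp7():
    cs = _criteria(EvidenceProfile(
        variant=SYNONYMOUS, max_population_af=0.002,
        insilico_splice=Verdict.SUPPORTS_BENIGN,
    ))
    assert "BP7" in cs.codes
    assert "BS1" in cs.codes  # 0.002 >= 0.0005


@pytest.mark.parametrize(
    "profile, present, absent",
    [
        (EvidenceProfile(variant=MISSENSE, max_population_af=0.06),
         {"BA1"}, {"PM2", "BS1"}),
        (EvidenceProfile(variant=MISSENSE, max_population_af=0.001),
         {"BS1"}, {"BA1", "PM2"}),
        (EvidenceProfile(variant=MISSENSE, max_population_af=1e-6),
         {"PM2"}, {"BA1", "BS1"}),
        (EvidenceProfile(variant=MISSENSE, max_population_af=1e-4),
         set(), {"BA1", "BS1", "PM2"}),
        (EvidenceProfile(variant=INFRAME), {"PM4", "PM2"}, set()),
        (EvidenceProfile(variant=MISSENSE,
                         cosegregation=Cosegregation(5, True)), {"PP1"}, {"BS4"}),
        (EvidenceProfile(variant=MISSENSE,
                         cosegregation=Cosegregation(5, False)), {"BS4"}, {"PP1"}),
        # too few informative meioses to count
        (EvidenceProfile(variant=MISSENSE,
                         cosegregation=Cosegregation(2, True)), set(), {"PP1", "BS4"}),
        (EvidenceProfile(variant=MISSENSE,
                         insilico_missense=Verdict.SUPPORTS_PATHOGENIC),
         {"PP3"}, {"BP4"}),
        (EvidenceProfile(variant=MISSENSE,
                         insilico_missense=Verdict.SUPPORTS_BENIGN),
         {"BP4"}, {"PP3"}),
        (EvidenceProfile(variant=MISSENSE, same_aa_change_reported_pathogenic=True),
         {"PS1"}, {"PM5"}),
        (EvidenceProfile(variant=MISSENSE, same_codon_other_pathogenic=True),
         {"PM5"}, {"PS1"}),
        (EvidenceProfile(variant=MISSENSE, prior_reports=PriorReports(6, 0)),
         {"REP"}, set()),
    ],
)
def test_standard_criteria(profile, present, absent):
    cs = _criteria(profile)
    assert present <= cs.codes
    assert not (absent & cs.codes)


def test_splice_pvs1_withdrawn_when_rna_normal():
    with_pvs1 = _criteria(EvidenceProfile(variant=SPLICE))
    rescued = _criteria(EvidenceProfile(variant=SPLICE, cdna_splicing_shown="normal"))
    assert "PVS1" in with_pvs1.codes
    assert "PVS1" not in rescued.codes


def test_initiation_codon_pvs1_is_strong_by_default():
    cs = _criteria(EvidenceProfile(variant=parse_variant("c.1A>G")))
    (pvs1,) = [c for c in cs.met if c.code == "PVS1"]
    assert pvs1.strength == Strength.PATHOGENIC_STRONG


def test_reputation_ladder():
    def strength(net_p, net_b):
        cs = _criteria(EvidenceProfile(
            variant=MISSENSE, prior_reports=PriorReports(net_p, net_b)
        ))
        rep = [c for c in cs.met if c.code == "REP"]
        return rep[0].strength if rep else None

    assert strength(6, 0) == Strength.PATHOGENIC_STRONG
    assert strength(3, 0) == Strength.PATHOGENIC_MODERATE
    assert strength(1, 0) == Strength.PATHOGENIC_SUPPORTING
    assert strength(1, 1) is None
    assert strength(0, 3) == Strength.BENIGN_STRONG


# --- combining rules ---------------------------------------------------------

def _crit_set(strengths):
    return CriterionSet(frozenset(
        Criterion(f"X{i}", s) for i, s in enumerate(strengths)
    ))


@pytest.mark.parametrize(
    "strengths, expected",
    [
        ([Strength.PATHOGENIC_VERY_STRONG, Strength.PATHOGENIC_MODERATE],
         FiveTierClass.PV),
        ([Strength.STAND_ALONE_BENIGN], FiveTierClass.BV),
        ([], FiveTierClass.VUS),
        ([Strength.PATHOGENIC_VERY_STRONG, Strength.BENIGN_STRONG],
         FiveTierClass.VUS),
        ([Strength.PATHOGENIC_VERY_STRONG], FiveTierClass.VUS),
        ([Strength.PATHOGENIC_STRONG, Strength.PATHOGENIC_MODERATE],
         FiveTierClass.LPV),
        ([Strength.PATHOGENIC_STRONG, Strength.PATHOGENIC_STRONG],
         FiveTierClass.PV),
        ([Strength.PATHOGENIC_MODERATE] * 3, FiveTierClass.LPV),
        ([Strength.BENIGN_STRONG, Strength.BENIGN_SUPPORTING], FiveTierClass.LBV),
        ([Strength.BENIGN_SUPPORTING] * 2, FiveTierClass.LBV),
        ([Strength.BENIGN_STRONG], FiveTierClass.VUS),
        ([Strength.BENIGN_STRONG] * 2, FiveTierClass.BV),
    ],
)
def test_combine_examples(strengths, expected):
    assert combine(_crit_set(strengths)) == expected


def test_combine_matches_bruteforce_enumeration():
    """Exhaustive equivalence over all criterion multisets with at most three
    entries of each strength (4^7 = 16384 combinations)."""
    order = [
        Strength.PATHOGENIC_VERY_STRONG, Strength.PATHOGENIC_STRONG,
        Strength.PATHOGENIC_MODERATE, Strength.PATHOGENIC_SUPPORTING,
        Strength.STAND_ALONE_BENIGN, Strength.BENIGN_STRONG,
        Strength.BENIGN_SUPPORTING,
    ]
    for counts in itertools.product(range(4), repeat=7):
        strengths = [
            s for s, n in zip(order, counts) for _ in range(n)
        ]
        assert combine(_crit_set(strengths)) == oracle_combine(*counts), counts


@settings(derandomize=True, max_examples=300)
@given(
    st.lists(
        st.sampled_from([
            Strength.PATHOGENIC_VERY_STRONG, Strength.PATHOGENIC_STRONG,
            Strength.PATHOGENIC_MODERATE, Strength.PATHOGENIC_SUPPORTING,
        ]),
        max_size=6,
    ),
    st.sampled_from([
        Strength.PATHOGENIC_VERY_STRONG, Strength.PATHOGENIC_STRONG,
        Strength.PATHOGENIC_MODERATE, Strength.PATHOGENIC_SUPPORTING,
    ]),
)
def test_combine_monotone_under_added_pathogenic_evidence(strengths, extra):
    """With no benign-side criteria, adding pathogenic evidence never lowers
    the class."""
    before = combine(_crit_set(strengths))
    after = combine(_crit_set(strengths + [extra]))
    assert after >= before


# --- excluded-code invariant over randomised profiles ------------------------

variant_st = st.sampled_from([MISSENSE, NONSENSE, SYNONYMOUS, INFRAME, SPLICE,
                              parse_variant("c.1A>G"),
                              parse_variant("c.73-?_200+?del"),
                              parse_variant("c.72+17T>C")])

profiles_st = st.builds(
    EvidenceProfile,
    variant=variant_st,
    max_population_af=st.one_of(
        st.none(), st.floats(min_value=0, max_value=0.1)
    ),
    case_count=st.integers(min_value=1, max_value=60),
    cosegregation=st.one_of(
        st.none(),
        st.builds(Cosegregation,
                  informative_meioses=st.integers(0, 10),
                  segregates=st.booleans()),
    ),
    de_novo=st.booleans(),
    insilico_missense=st.one_of(st.none(), st.sampled_from(list(Verdict))),
    insilico_splice=st.one_of(st.none(), st.sampled_from(list(Verdict))),
    cdna_splicing_shown=st.sampled_from(["aberrant", "normal", "not_done"]),
    loh=st.sampled_from(
        ["variant_allele_retained_wt_lost", "variant_allele_lost",
         "no_loh", "not_done"]
    ),
    shdb_ihc=st.sampled_from(["negative", "positive", "not_done"]),
    sdha_ihc=st.sampled_from(["negative", "positive", "not_done"]),
    sdh_activity=st.sampled_from(["lost", "preserved", "not_done"]),
    western_blot=st.sampled_from(["reduced", "normal", "not_done"]),
    transcriptomic_cluster=st.sampled_from(
        ["cluster_1A", "cluster_1B", "cluster_2A", "not_done"]
    ),
    other_sdhx_excluded=st.booleans(),
    prior_reports=st.one_of(
        st.none(),
        st.builds(PriorReports, st.integers(0, 8), st.integers(0, 8)),
    ),
    same_aa_change_reported_pathogenic=st.booleans(),
    same_codon_other_pathogenic=st.booleans(),
)


@settings(derandomize=True, max_examples=300)
@given(profiles_st)
def test_excluded_codes_never_emitted(profile):
    cs = assign_criteria(profile)
    assert not (cs.codes & EXCLUDED_CODES)
    # determinism: a second evaluation is identical
    assert assign_criteria(profile) == cs


def test_criterion_set_rejects_excluded_and_duplicate_codes():
    with pytest.raises(ValueError):
        CriterionSet(frozenset({Criterion("PS4", Strength.PATHOGENIC_STRONG)}))
    with pytest.raises(ValueError):
        CriterionSet(frozenset({
            Criterion("PM2", Strength.PATHOGENIC_MODERATE, "a"),
            Criterion("PM2", Strength.PATHOGENIC_MODERATE, "b"),
        }))
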