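"""Parsing, typing, normalisation and deduplication of SDHB descriptions."""

import pytest
from hypothesis import given, settings, strategies as st

from sdhbcurate import (
    ConsistencyError,
    IndexCase,
    Variant,
    VariantParseError,
    VariantType,
    deduplicate,
    format_variant,
    parse_variant,
)


@pytest.mark.parametrize(
    "cdna, protein, expected",
    [
        # recurrent coding substitution; missense per its protein consequence
        ("c.137G>A", "p.Arg46Gln", VariantType.MISSENSE),
        # canonical donor +1
        ("c.423+1G>C", None, VariantType.SPLICE_SITE_SUBSTITUTION),
        ("c.72+1A>G", None, VariantType.SPLICE_SITE_SUBSTITUTION),
        ("c.287-2A>G", None, VariantType.SPLICE_SITE_SUBSTITUTION),
        # position 1 of the coding sequence is the initiation codon
        ("c.1A>G", None, VariantType.INITIATION_CODON),
        ("c.3G>T", "p.Met1?", VariantType.INITIATION_CODON),
        ("c.72+17T>C", None, VariantType.MID_INTRONIC),
        ("c.-29C>T", None, VariantType.UTR5),
        ("c.268C>T", "p.Arg90Ter", VariantType.NONSENSE),
        ("c.540G>C", "p.(=)", VariantType.SYNONYMOUS),
        ("c.166_170del", None, VariantType.FRAMESHIFT_INDEL),
        ("c.200dup", None, VariantType.FRAMESHIFT_INDEL),
        ("c.300_302del", None, VariantType.INFRAME_INDEL),
        # 6 bases replaced by 3: net in-frame loss of one codon
        ("c.300_305delinsTTT", None, VariantType.INFRAME_INDEL),
        ("c.300_305delinsTT", None, VariantType.FRAMESHIFT_INDEL),
        ("c.72+30del", None, VariantType.NONCODING_INDEL),
        ("c.423+1del", None, VariantType.SPLICE_SITE_INDEL),
        # breakpoints in the flanking introns spanning a whole exon
        ("c.73-?_200+?del", None, VariantType.LARGE_REARRANGEMENT),
        ("c.1-?_765+?del", None, VariantType.LARGE_REARRANGEMENT),
        ("c.73-?_200+?dup", None, VariantType.LARGE_REARRANGEMENT),
        # coordinates spanning more than one whole exon
        ("c.201_424del", None, VariantType.LARGE_REARRANGEMENT),
    ],
)
def test_typing_rules(cdna, protein, expected):
    assert parse_variant(cdna, protein).vtype == expected


def test_missense_consequence_matches_codon_table():
    """Independent check that a G>A at codon position 2 of an Arg codon
    yields Gln, the consequence asserted for the recurrent c.137G>A."""
    from Bio.Seq import Seq

    # codon 46 spans c.136-138; CGG (Arg) with G>A at the middle base -> CAG
    assert str(Seq("CGG").translate()) == "R"
    assert str(Seq("CAG").translate()) == "Q"
    v = parse_variant("c.137G>A", "p.Arg46Gln")
    assert v.vtype == VariantType.MISSENSE
    assert v.exon == "2"


def test_exon_and_intron_labels():
    assert parse_variant("c.137G>A").exon == "2"
    assert parse_variant("c.40G>A").exon == "1"
    assert parse_variant("c.300A>G", "p.Ala100Val").exon == "4"
    assert parse_variant("c.72+1A>G").exon == "intron 1"
    assert parse_variant("c.287-2A>G").exon == "intron 3"


@pytest.mark.parametrize(
    "cdna, protein, exc",
    [
        ("not-a-variant", None, VariantParseError),
        ("c.12X>Y", None, VariantParseError),
        ("c.", None, VariantParseError),
        ("", None, VariantParseError),
        ("c.100_101ins", None, VariantParseError),
        ("c.137G>A", "q.Arg46Gln", VariantParseError),
        # substitution cannot frameshift
        ("c.137G>A", "p.Arg46GlnfsTer3", ConsistencyError),
        # intronic change cannot carry a missense consequence
        ("c.72+17T>C", "p.Arg46Gln", ConsistencyError),
    ],
)
def test_parse_errors(cdna, protein, exc):
    with pytest.raises(exc):
        parse_variant(cdna, protein)


def test_parse_error_names_offending_token():
    with pytest.raises(VariantParseError) as excinfo:
        parse_variant("g.137G>A")
    assert excinfo.value.token


def test_normalization_whitespace_and_case():
    forms = ["c.137G>A", "  c.137G>A ", "C.137g>a", "c. 137 G>A"]
    parsed = {parse_variant(f) for f in forms}
    assert len(parsed) == 1
    assert parsed.pop().cdna == "c.137G>A"


@st.composite
def hgvs_descriptions(draw):
    kind = draw(st.sampled_from(["sub", "intronic", "utr", "del", "dup", "delins"]))
    pos = draw(st.integers(min_value=4, max_value=843))
    ref, alt = draw(st.sampled_from([("G", "A"), ("C", "T"), ("A", "G"), ("T", "C")]))
    if kind == "sub":
        return f"c.{pos}{ref}>{alt}"
    if kind == "intronic":
        off = draw(st.integers(min_value=1, max_value=40))
        sign = draw(st.sampled_from("+-"))
        return f"c.{pos}{sign}{off}{ref}>{alt}"
    if kind == "utr":
        return f"c.-{draw(st.integers(min_value=1, max_value=80))}{ref}>{alt}"
    if kind == "del":
        span = draw(st.integers(min_value=0, max_value=7))
        return f"c.{pos}_{pos + span}del" if span else f"c.{pos}del"
    if kind == "dup":
        return f"c.{pos}dup"
    span = draw(st.integers(min_value=1, max_value=5))
    ins = draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
    return f"c.{pos}_{pos + span}delins{ins}"


@settings(derandomize=True, max_examples=200)
@given(hgvs_descriptions())
def test_parse_format_roundtrip_and_total_typing(description):
    """parse -> format -> parse is stable, and every parseable description
    receives exactly one variant type."""
    v = parse_variant(description)
    assert isinstance(v.vtype, VariantType)
    again = parse_variant(format_variant(v))
    assert again == v
    assert again.vtype == v.vtype


def _case(i, cdna):
    return IndexCase(case_id=f"c{i}", variant=parse_variant(cdna))


def test_deduplicate_counts_and_normalisation():
    cases = (
        [_case(i, "c.137G>A") for i in range(3)]
        + [_case(9, " c.137G>A ")]
        + [_case(4, "c.72+1A>G")]
    )
    dedup = deduplicate(cases)
    assert len(dedup) == 2
    assert sum(dedup.values()) == len(cases)
    assert dedup[parse_variant("c.137G>A")] == 4


@settings(derandomize=True, max_examples=50)
@given(st.permutations(list(range(8))))
def test_deduplicate_order_invariant(order):
    base = [
        _case(i, cdna)
        for i, cdna in enumerate(
            ["c.137G>A", "c.137G>A", "c.72+1A>G", "c.8C>T",
             "c.8C>T", "c.8C>T", "c.423+1G>C", "c.137G>A"]
        )
    ]
    shuffled = [base[i] for i in order]
    assert deduplicate(shuffled) == deduplicate(base)


def test_deduplicate_empty_and_single():
    assert deduplicate([]) == {}
    single = deduplicate([_case(0, "c.137G>A")])
    assert list(single.values()) == [1]


def test_index_case_invariants():
    v = parse_variant("c.137G>A")
    with pytest.raises(ValueError):
        IndexCase("x", v, metastatic="yes")  # no tumour recorded
    ok = IndexCase("x", v, metastatic="yes", n_tumours=1,
                   tumour_sites=frozenset({"PCC"}))
    assert ok.metastatic == "yes"
    with pytest.raises(ValueError):
        IndexCase("x", v, tumour_sites=frozenset({"lung"}))
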