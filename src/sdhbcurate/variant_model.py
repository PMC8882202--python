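"""Parsing, normalisation, typing and deduplication of SDHB variant descriptions.

All coordinates are HGVS coding-DNA positions on the SDHB reference transcript
NM_003000.2 (8 exons, 281-codon open reading frame).  The parser is an
HGVS-lite: it covers the description forms seen in diagnostic SDHB reporting
(substitutions, del/dup/ins/delins, intronic offsets, UTR positions and
whole-exon rearrangements with ``?`` breakpoints) and nothing more exotic.
Descriptions are taken as submitted: whitespace and prefix case are
normalised, but indels are not 3'-shifted.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

TRANSCRIPT = "NM_003000.2"

#: Coding-DNA intervals of the eight SDHB exons (1-based, inclusive), ending at
#: the stop codon (c.846).  Derived from the canonical donor sites of the
#: transcript (c.72+1, c.200+1, c.286+1, c.423+1, c.540+1, c.642+1, c.765+1).
EXONS: Mapping[int, tuple[int, int]] = {
    1: (1, 72),
    2: (73, 200),
    3: (201, 286),
    4: (287, 423),
    5: (424, 540),
    6: (541, 642),
    7: (643, 765),
    8: (766, 846),
}
CDS_LENGTH = 846


class VariantType(str, enum.Enum):
    """Categories of SDHB alteration used throughout the pipeline."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE_SUBSTITUTION = "splice_site_substitution"
    MID_INTRONIC = "mid_intronic"
    SYNONYMOUS = "synonymous"
    UTR5 = "utr5"
    INITIATION_CODON = "initiation_codon"
    FRAMESHIFT_INDEL = "frameshift_indel"
    LARGE_REARRANGEMENT = "large_rearrangement"
    INFRAME_INDEL = "inframe_indel"
    NONCODING_INDEL = "noncoding_indel"
    SPLICE_SITE_INDEL = "splice_site_indel"


#: Variant types expected to abolish SDHB protein function outright
#: ("null" types for PVS1-style reasoning).
TRUNCATING_TYPES = frozenset(
    {
        VariantType.NONSENSE,
        VariantType.FRAMESHIFT_INDEL,
        VariantType.SPLICE_SITE_SUBSTITUTION,
        VariantType.SPLICE_SITE_INDEL,
        VariantType.INITIATION_CODON,
        VariantType.LARGE_REARRANGEMENT,
    }
)

SUBSTITUTION_TYPES = frozenset(
    {
        VariantType.MISSENSE,
        VariantType.NONSENSE,
        VariantType.SPLICE_SITE_SUBSTITUTION,
        VariantType.MID_INTRONIC,
        VariantType.SYNONYMOUS,
        VariantType.UTR5,
        VariantType.INITIATION_CODON,
    }
)
INDEL_TYPES = frozenset(set(VariantType) - set(SUBSTITUTION_TYPES))


class FiveTierClass(enum.IntEnum):
    """The 5-tier pathogenicity scale: class 1 (benign) .. class 5 (pathogenic)."""

    BV = 1   # benign variant
    LBV = 2  # likely benign variant
    VUS = 3  # variant of unknown significance
    LPV = 4  # likely pathogenic variant
    PV = 5   # pathogenic variant

    @classmethod
    def from_label(cls, label: str) -> "FiveTierClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown 5-tier class label: {label!r}") from None


class VariantParseError(ValueError):
    """Raised when an HGVS-c description cannot be parsed.

    ``token`` names the offending fragment of the description.
    """

    def __init__(self, message: str, token: str = ""):
        super().__init__(message)
        self.token = token


class ConsistencyError(VariantParseError):
    """Raised when the protein description contradicts the cDNA description."""


@dataclass(frozen=True)
class Variant:
    """A normalised distinct SDHB alteration.

    Equality and hashing are on the normalised cDNA description only, so two
    submissions of the same change compare equal regardless of protein
    annotation formatting.
    """

    cdna: str
    vtype: VariantType
    protein: Optional[str] = field(default=None, compare=False)
    exon: Optional[str] = field(default=None, compare=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.cdna


# --- position / description grammar -----------------------------------------

_POS_RE = re.compile(
    r"(?P<base>\*\d+|-\d+|\d+)(?P<off>[+-](?:\d+|\?))?$"
)
_SUB_RE = re.compile(
    r"^c\.(?P<pos>[^_>]+?)(?P<ref>[ACGT])>(?P<alt>[ACGT])$", re.IGNORECASE
)
_INDEL_RE = re.compile(
    r"^c\.(?P<start>[^_]+?)(?:_(?P<end>[^_]+?))?"
    r"(?P<op>delins|del|dup|ins)(?P<arg>[ACGTacgt]+|\d+)?$",
    re.IGNORECASE,
)

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp "
    "Tyr Val Ter Sec".split()
)
_PROT_SUB_RE = re.compile(
    r"^p\.\(?(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>[A-Z][a-z]{2}|\*|\?|=)\)?$"
)


@dataclass(frozen=True)
class _Pos:
    region: str          # "utr5" | "coding" | "utr3"
    base: int            # coding (or UTR-relative) base position
    offset: Optional[int]  # intronic offset; None = exonic; 0 sentinel unused
    unknown_offset: bool = False  # '?' breakpoint ("73-?")
    offset_sign: int = 0

    @property
    def intronic(self) -> bool:
        return self.offset is not None or self.unknown_offset


def _parse_pos(token: str) -> _Pos:
    m = _POS_RE.match(token)
    if not m:
        raise VariantParseError(f"unparseable position token {token!r}", token)
    base_s = m.group("base")
    off_s = m.group("off")
    if base_s.startswith("*"):
        region, base = "utr3", int(base_s[1:])
    elif base_s.startswith("-"):
        region, base = "utr5", int(base_s[1:])
    else:
        region, base = "coding", int(base_s)
    if off_s is None:
        return _Pos(region, base, None)
    sign = 1 if off_s[0] == "+" else -1
    if off_s[1:] == "?":
        return _Pos(region, base, None, unknown_offset=True, offset_sign=sign)
    return _Pos(region, base, sign * int(off_s[1:]), offset_sign=sign)


def _coverage_point(p: _Pos, side: str) -> float:
    """Map a position token to a point on the coding axis for exon-span tests.

    Intronic/unknown offsets land fractionally beyond the anchor base so that a
    deletion written ``c.73-?_200+?del`` covers exon 2 (73..200) exactly.
    """
    if p.region == "utr5":
        return 0.5 - p.base  # upstream of c.1
    base = float(p.base) if p.region == "coding" else CDS_LENGTH + p.base
    if p.unknown_offset:
        return base + 0.5 * p.offset_sign
    if p.offset is not None:
        return base + 0.1 * (1 if p.offset > 0 else -1)
    return base


def _exon_label(p: _Pos) -> Optional[str]:
    if p.region != "coding":
        return None
    exon = next((k for k, (s, e) in EXONS.items() if s <= p.base <= e), None)
    if exon is None:
        return None
    if p.offset is None and not p.unknown_offset:
        return str(exon)
    sign = p.offset_sign or (1 if (p.offset or 0) > 0 else -1)
    return f"intron {exon if sign > 0 else exon - 1}"


def _parse_protein(protein: str) -> Optional[dict]:
    s = "".join(protein.split())
    if not s:
        return None
    if s[:2].lower() == "p.":
        s = "p." + s[2:]
    else:
        raise VariantParseError(f"protein description lacks 'p.' prefix: {protein!r}", s)
    body = s[2:]
    if body in ("?", "(?)"):
        return {"kind": "unknown", "norm": s}
    if body in ("=", "(=)"):
        return {"kind": "synonymous", "norm": s}
    if "fs" in body:
        return {"kind": "frameshift", "norm": s}
    m = _PROT_SUB_RE.match(s)
    if m:
        ref, pos, alt = m.group("ref"), int(m.group("pos")), m.group("alt")
        if ref not in _AA3:
            raise VariantParseError(f"unknown amino acid {ref!r} in {protein!r}", ref)
        if ref == "Met" and pos == 1:
            return {"kind": "initiation", "norm": s}
        if alt in ("Ter", "*"):
            return {"kind": "nonsense", "norm": s}
        if alt in ("=",) or alt == ref:
            return {"kind": "synonymous", "norm": s}
        if alt == "?":
            return {"kind": "unknown", "norm": s}
        if alt not in _AA3:
            raise VariantParseError(f"unknown amino acid {alt!r} in {protein!r}", alt)
        return {"kind": "missense", "norm": s}
    raise VariantParseError(f"unparseable protein description {protein!r}", s)


def normalize_cdna(description: str) -> str:
    """Whitespace-strip and prefix-normalise an HGVS-c description."""
    s = "".join(description.split())
    if not s:
        raise VariantParseError("empty cDNA description", "")
    if s[:2].lower() != "c.":
        raise VariantParseError(f"description lacks 'c.' prefix: {description!r}", s[:2])
    return "c." + s[2:]


def _type_substitution(pos: _Pos, prot: Optional[dict], cdna: str) -> VariantType:
    if pos.region == "utr5":
        return VariantType.UTR5
    if pos.region == "utr3":
        # no dedicated 3'UTR substitution category; bucketed with the
        # non-coding substitutions
        return VariantType.MID_INTRONIC
    if pos.intronic:
        if pos.unknown_offset:
            raise VariantParseError(f"'?' offset invalid in substitution {cdna!r}", cdna)
        return (
            VariantType.SPLICE_SITE_SUBSTITUTION
            if abs(pos.offset) <= 2
            else VariantType.MID_INTRONIC
        )
    if prot is not None and prot["kind"] in ("frameshift",):
        raise ConsistencyError(
            f"substitution {cdna!r} cannot produce frameshift protein change"
        )
    if 1 <= pos.base <= 3:
        return VariantType.INITIATION_CODON
    if prot is None or prot["kind"] in ("unknown",):
        # without a protein consequence a coding substitution defaults to
        # missense; a vtype column may override
        return VariantType.MISSENSE
    return {
        "missense": VariantType.MISSENSE,
        "nonsense": VariantType.NONSENSE,
        "synonymous": VariantType.SYNONYMOUS,
        "initiation": VariantType.INITIATION_CODON,
    }[prot["kind"]]


def _type_indel(
    start: _Pos, end: Optional[_Pos], op: str, arg: Optional[str],
    prot: Optional[dict], cdna: str,
) -> VariantType:
    end = end or start
    # whole-exon span => large rearrangement
    lo, hi = _coverage_point(start, "start"), _coverage_point(end, "end")
    if any(lo <= s and hi >= e for s, e in EXONS.values()):
        return VariantType.LARGE_REARRANGEMENT
    positions = [start, end]
    if any(
        (p.offset is not None and abs(p.offset) <= 2) for p in positions
    ):
        return VariantType.SPLICE_SITE_INDEL
    if any(p.intronic or p.region != "coding" for p in positions):
        return VariantType.NONCODING_INDEL
    if prot is not None and prot["kind"] == "frameshift":
        return VariantType.FRAMESHIFT_INDEL
    span = end.base - start.base + 1
    if arg and arg.isdigit():
        span = int(arg)
    elif arg:
        span = len(arg) if op in ("del", "dup") else span
    if op == "ins":
        net = len(arg) if arg and not arg.isdigit() else int(arg or 0)
    elif op == "delins":
        net = (len(arg) if arg and not arg.isdigit() else int(arg or 0)) - span
    else:  # del / dup
        net = span
    return (
        VariantType.INFRAME_INDEL if net % 3 == 0 else VariantType.FRAMESHIFT_INDEL
    )


def parse_variant(
    description: str,
    protein: Optional[str] = None,
    vtype_override: Optional[VariantType] = None,
) -> Variant:
    """Parse an HGVS-c description (plus optional HGVS-p) into a ``Variant``.

    Typing precedence: whole-exon del/dup -> large_rearrangement; intronic
    offset within +-2 -> splice-site; larger offsets -> mid-intronic (or
    non-coding indel); 5'UTR -> utr5; c.1-3 substitutions -> initiation codon;
    coding substitutions typed by their protein consequence; coding indels
    typed frameshift vs in-frame by net length mod 3 when no protein
    consequence is given.

    Raises :class:`VariantParseError` naming the offending token, or
    :class:`ConsistencyError` when protein and cDNA descriptions contradict.
    """
    cdna = normalize_cdna(description)
    prot = _parse_protein(protein) if protein else None

    m = _SUB_RE.match(cdna)
    if m:
        pos = _parse_pos(m.group("pos"))
        if prot is not None and prot["kind"] not in ("unknown",) and (
            pos.intronic or pos.region != "coding"
        ) and prot["kind"] != "synonymous":
            raise ConsistencyError(
                f"non-coding substitution {cdna!r} cannot have protein change {protein!r}"
            )
        vtype = _type_substitution(pos, prot, cdna)
        norm = (
            f"c.{m.group('pos')}{m.group('ref').upper()}>{m.group('alt').upper()}"
        )
        v = Variant(norm, vtype, prot["norm"] if prot else None, _exon_label(pos))
    else:
        m = _INDEL_RE.match(cdna)
        if m is None:
            raise VariantParseError(f"unparseable cDNA description {cdna!r}", cdna)
        start = _parse_pos(m.group("start"))
        end = _parse_pos(m.group("end")) if m.group("end") else None
        op = m.group("op").lower()
        arg = m.group("arg")
        if op == "ins" and not arg:
            raise VariantParseError(f"ins without inserted sequence in {cdna!r}", "ins")
        vtype = _type_indel(start, end, op, arg.upper() if arg else None, prot, cdna)
        tail = (arg.upper() if arg and not arg.isdigit() else (arg or ""))
        norm = "c." + m.group("start") + (
            f"_{m.group('end')}" if m.group("end") else ""
        ) + op + tail
        v = Variant(norm, vtype, prot["norm"] if prot else None, _exon_label(start))

    if vtype_override is not None and vtype_override != v.vtype:
        v = Variant(v.cdna, vtype_override, v.protein, v.exon)
    return v


def format_variant(v: Variant) -> str:
    """Inverse of :func:`parse_variant` on the cDNA axis (round-trip stable)."""
    return v.cdna


# --- index cases and deduplication -------------------------------------------

TUMOUR_SITES = frozenset(
    {"head_neck_PGL", "TAP_PGL", "PCC", "RCC", "GIST", "unspecified"}
)


@dataclass(frozen=True)
class IndexCase:
    """One index case: the first genotyped affected individual of a family."""

    case_id: str
    variant: Variant
    n_tumours: Optional[int] = None
    tumour_sites: Optional[frozenset] = None
    metastatic: Optional[str] = None       # "yes" | "no" | None (unknown)
    family_history: Optional[str] = None   # "yes" | "no" | None
    age_at_diagnosis: Optional[float] = None

    def __post_init__(self):
        if self.metastatic not in (None, "yes", "no"):
            raise ValueError(f"metastatic must be yes/no/None, got {self.metastatic!r}")
        if self.family_history not in (None, "yes", "no"):
            raise ValueError(
                f"family_history must be yes/no/None, got {self.family_history!r}"
            )
        if self.tumour_sites is not None:
            bad = set(self.tumour_sites) - TUMOUR_SITES
            if bad:
                raise ValueError(f"unknown tumour sites: {sorted(bad)}")
        if self.n_tumours is not None and self.n_tumours < 0:
            raise ValueError("n_tumours must be >= 0")
        if self.metastatic == "yes":
            has_tumour = (self.n_tumours or 0) >= 1 or bool(self.tumour_sites)
            if not has_tumour:
                raise ValueError(
                    "metastatic case must have >=1 tumour or a tumour site"
                )


def deduplicate(cases: Iterable[IndexCase]) -> dict[Variant, int]:
    """Collapse index cases to distinct variants with occurrence counts.

    Counts sum to the number of input cases; keys are normalised variants, so
    the result is invariant under input permutation and whitespace variation
    of the submitted descriptions.
    """
    counter: Counter[Variant] = Counter()
    for case in cases:
        counter[case.variant] += 1
    return dict(counter)
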