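"""Conservation ratio and aggregation of pre-computed predictor outputs.

Missense variants carry a 14-ortholog amino-acid conservation ratio plus
nucleotide-level scores (PhyloP, Grantham) and categorical tool verdicts
(PolyPhen2 HumVar, SIFT, Align-GVGD, MutationTaster).  Splice candidates
(splice-site, synonymous and intronic variants) carry MaxEntScan and NNSplice
reference/alternate scores.  The third-party predictors are consumed as
pre-computed values, never executed.

All aggregation thresholds live in :class:`InsilicoThresholds`.  The defaults
are each tool's conventional published cutoff (e.g. a 15% relative MaxEntScan
score drop, Align-GVGD class C35 and above as damaging); they are deliberate
package defaults, replaceable per run, not calibrated values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

N_ORTHOLOGS = 14

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}


class Verdict(str, enum.Enum):
    SUPPORTS_PATHOGENIC = "supports_pathogenic"
    SUPPORTS_BENIGN = "supports_benign"
    CONFLICTING = "conflicting"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class OrthologColumn:
    """One alignment column: the human residue plus 14 ortholog residues."""

    residues: Sequence[str]
    human_residue: str

    def __post_init__(self):
        if len(self.residues) != N_ORTHOLOGS:
            raise ValueError(
                f"ortholog column must have exactly {N_ORTHOLOGS} residues, "
                f"got {len(self.residues)}"
            )
        for r in list(self.residues) + [self.human_residue]:
            if r.upper() not in _AA_LETTERS:
                raise ValueError(f"invalid amino-acid letter {r!r}")


def conservation_ratio(column: OrthologColumn) -> float:
    """Fraction of the 14 orthologs sharing the human residue (k/14 in [0,1]).

    Alignment gaps count as non-matching: absence of the residue is not
    conservation.
    """
    human = column.human_residue.upper()
    k = sum(1 for r in column.residues if r.upper() == human and r != "-")
    return k / N_ORTHOLOGS


def load_ortholog_alignment(path) -> list:
    """Read an aligned FASTA of the human SDHB protein (first record) plus
    its 14 orthologs; returns the list of records."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != N_ORTHOLOGS + 1:
        raise ValueError(
            f"alignment must contain the human sequence plus {N_ORTHOLOGS} "
            f"orthologs ({N_ORTHOLOGS + 1} records), got {len(records)}"
        )
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment records have unequal lengths")
    return records


def column_at(records: list, residue_number: int) -> OrthologColumn:
    """Extract the ortholog column for a human residue number (1-based,
    counted over non-gap human positions)."""
    human = str(records[0].seq)
    seen = 0
    for i, aa in enumerate(human):
        if aa != "-":
            seen += 1
            if seen == residue_number:
                return OrthologColumn(
                    residues=[str(r.seq)[i] for r in records[1:]],
                    human_residue=aa,
                )
    raise ValueError(f"residue {residue_number} beyond human sequence")


@dataclass(frozen=True)
class MissensePredictions:
    conservation_ratio: Optional[float] = None
    phylop: Optional[float] = None
    grantham: Optional[int] = None
    polyphen2_humvar: Optional[str] = None   # benign | possibly_damaging | probably_damaging
    sift: Optional[str] = None               # tolerated | deleterious
    align_gvgd: Optional[str] = None         # C0 .. C65
    mutation_taster: Optional[str] = None    # polymorphism | disease_causing

    def __post_init__(self):
        if self.conservation_ratio is not None and not (
            0.0 <= self.conservation_ratio <= 1.0
        ):
            raise ValueError("conservation_ratio must lie in [0, 1]")
        if self.grantham is not None and not (0 <= self.grantham <= 215):
            raise ValueError("Grantham distance must lie in [0, 215]")


@dataclass(frozen=True)
class SplicePredictions:
    maxentscan_ref: Optional[float] = None
    maxentscan_alt: Optional[float] = None
    nnsplice_ref: Optional[float] = None
    nnsplice_alt: Optional[float] = None

    def __post_init__(self):
        if self.maxentscan_alt is not None and self.maxentscan_ref is None:
            raise ValueError("maxentscan_alt present without maxentscan_ref")
        if self.nnsplice_alt is not None and self.nnsplice_ref is None:
            raise ValueError("nnsplice_alt present without nnsplice_ref")
        for v in (self.nnsplice_ref, self.nnsplice_alt):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("NNSplice scores must lie in [0, 1]")


@dataclass(frozen=True)
class InsilicoThresholds:
    """Aggregation cutoffs (package defaults; configurable per run)."""

    cons_pathogenic: float = 0.9      # near-total conservation across orthologs
    cons_benign: float = 0.5          # weakly conserved position
    phylop_pathogenic: float = 1.6    # conventional conserved-site cutoff
    phylop_benign: float = 0.1
    grantham_pathogenic: int = 145    # radical substitution
    grantham_benign: int = 50         # conservative substitution
    gvgd_pathogenic_min: int = 35     # C35 and above
    min_tools: int = 2
    mes_drop_pathogenic: float = 0.15  # relative MaxEntScan score drop
    mes_drop_benign: float = 0.05
    nns_site_floor: float = 0.4        # NNSplice detection threshold


DEFAULT_THRESHOLDS = InsilicoThresholds()

_PATH, _BENIGN, _NEUTRAL = 1, -1, 0


def _missense_votes(p: MissensePredictions, t: InsilicoThresholds) -> list[int]:
    votes = []
    if p.conservation_ratio is not None:
        votes.append(
            _PATH if p.conservation_ratio >= t.cons_pathogenic
            else _BENIGN if p.conservation_ratio <= t.cons_benign
            else _NEUTRAL
        )
    if p.phylop is not None:
        votes.append(
            _PATH if p.phylop >= t.phylop_pathogenic
            else _BENIGN if p.phylop <= t.phylop_benign
            else _NEUTRAL
        )
    if p.grantham is not None:
        votes.append(
            _PATH if p.grantham >= t.grantham_pathogenic
            else _BENIGN if p.grantham <= t.grantham_benign
            else _NEUTRAL
        )
    if p.polyphen2_humvar is not None:
        votes.append(
            _PATH if p.polyphen2_humvar == "probably_damaging"
            else _BENIGN if p.polyphen2_humvar == "benign"
            else _NEUTRAL
        )
    if p.sift is not None:
        votes.append(_PATH if p.sift == "deleterious" else _BENIGN)
    if p.align_gvgd is not None:
        cls = int(p.align_gvgd.lstrip("Cc"))
        votes.append(
            _PATH if cls >= t.gvgd_pathogenic_min
            else _BENIGN if cls == 0
            else _NEUTRAL
        )
    if p.mutation_taster is not None:
        votes.append(_PATH if p.mutation_taster == "disease_causing" else _BENIGN)
    return votes


def missense_verdict(
    p: MissensePredictions, thresholds: InsilicoThresholds = DEFAULT_THRESHOLDS
) -> Verdict:
    """Aggregate missense predictor outputs into a four-way verdict.

    ``conflicting`` when at least one tool is on the pathogenic side of its
    cutoff and another on the benign side; ``insufficient`` when fewer than
    ``min_tools`` tools report, or no reporting tool is directional.
    """
    votes = _missense_votes(p, thresholds)
    if len(votes) < thresholds.min_tools:
        return Verdict.INSUFFICIENT
    n_path = votes.count(_PATH)
    n_benign = votes.count(_BENIGN)
    if n_path and n_benign:
        return Verdict.CONFLICTING
    if n_path:
        return Verdict.SUPPORTS_PATHOGENIC
    if n_benign:
        return Verdict.SUPPORTS_BENIGN
    return Verdict.INSUFFICIENT


def splice_verdict(
    p: SplicePredictions, thresholds: InsilicoThresholds = DEFAULT_THRESHOLDS
) -> Verdict:
    """Aggregate splice-score deltas into a three-way verdict.

    supports_pathogenic when at least one tool shows site loss (MaxEntScan
    relative drop >= ``mes_drop_pathogenic``, or NNSplice site falling below
    ``nns_site_floor`` from a detected reference site) and no reporting tool
    shows essentially no change; supports_benign when every reporting tool's
    drop stays below ``mes_drop_benign``.
    """
    losses, no_changes, reporting = [], [], 0
    if p.maxentscan_alt is not None:
        if p.maxentscan_ref == 0:
            raise ValueError("MaxEntScan reference score of 0: relative drop undefined")
        reporting += 1
        drop = (p.maxentscan_ref - p.maxentscan_alt) / p.maxentscan_ref
        losses.append(drop >= thresholds.mes_drop_pathogenic)
        no_changes.append(drop < thresholds.mes_drop_benign)
    if p.nnsplice_alt is not None:
        reporting += 1
        drop = (
            (p.nnsplice_ref - p.nnsplice_alt) / p.nnsplice_ref
            if p.nnsplice_ref else 0.0
        )
        losses.append(
            p.nnsplice_ref >= thresholds.nns_site_floor
            and p.nnsplice_alt < thresholds.nns_site_floor
        )
        no_changes.append(drop < thresholds.mes_drop_benign)
    if reporting == 0:
        return Verdict.INSUFFICIENT
    if any(losses) and not any(no_changes):
        return Verdict.SUPPORTS_PATHOGENIC
    if all(no_changes):
        return Verdict.SUPPORTS_BENIGN
    return Verdict.INSUFFICIENT
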