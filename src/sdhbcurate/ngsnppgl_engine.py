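"""NGSnPPGL-style classification as a configurable decision tree.

The NGSnPPGL study-group framework rates a variant from the frequency of the
variant in the general population, the variant type, in silico predictions,
co-segregation in families and tumour-assay results.  Here that is realised
as a small decision tree shipped as a versioned, JSON-serialisable config so
the topology can be adjusted without code changes.  Default order of gates:

1. frequency gate — common variants exit benign/likely benign immediately
   (this gate dominates: no assay can promote a common variant);
2. truncating-type gate — rare null variants are likely pathogenic, promoted
   to pathogenic by a confirmatory assay or by high recurrence;
3. assay gate — a loss-of-function-direction assay promotes one class, a
   benign-direction assay demotes one class (saturating at 1 and 5);
4. in silico + segregation gate for missense/splice candidates;
5. default leaf: VUS.

Every classification returns a full audit trace; the classifier is a pure
function of (profile, tree).
"""

from __future__ import annotations

from dataclasses import dataclass

from .acmg_engine import EvidenceProfile, _lof_assay_signals
from .insilico import Verdict
from .variant_model import FiveTierClass, TRUNCATING_TYPES


class NgsTreeConfigError(ValueError):
    """Malformed tree config; the message carries the offending node path."""


#: Default tree topology, version-tagged.  Nodes are
#: ``{"node": label, "factor": f, "op": op, "value": v, "true": .., "false": ..}``;
#: leaves are ``{"class": 1..5, "modifiers": [...]}``.
DEFAULT_TREE: dict = {
    "version": "1.0",
    "recurrence_threshold": 10,
    "root": {
        "node": "frequency_stand_alone",
        "factor": "af", "op": "ge", "value": 0.005,
        "true": {"class": 1, "modifiers": []},
        "false": {
            "node": "frequency_likely_benign",
            "factor": "af", "op": "ge", "value": 0.0005,
            "true": {"class": 2, "modifiers": []},
            "false": {
                "node": "truncating",
                "factor": "is_truncating", "op": "eq", "value": True,
                "true": {"class": 4, "modifiers": ["assay_adjust", "recurrence_promote"]},
                "false": {
                    "node": "insilico_pathogenic",
                    "factor": "insilico", "op": "eq", "value": "supports_pathogenic",
                    "true": {
                        "node": "segregation",
                        "factor": "segregates", "op": "eq", "value": True,
                        "true": {"class": 4, "modifiers": ["assay_adjust"]},
                        "false": {"class": 3, "modifiers": ["assay_adjust"]},
                    },
                    "false": {
                        "node": "insilico_benign",
                        "factor": "insilico", "op": "eq", "value": "supports_benign",
                        "true": {"class": 2, "modifiers": ["assay_adjust"]},
                        "false": {"class": 3, "modifiers": ["assay_adjust"]},
                    },
                },
            },
        },
    },
}

_FACTORS = ("af", "is_truncating", "insilico", "segregates", "case_count")
_OPS = {
    "ge": lambda a, b: a is not None and a >= b,
    "le": lambda a, b: a is not None and a <= b,
    "eq": lambda a, b: a == b,
}
_MODIFIERS = ("assay_adjust", "recurrence_promote")


def validate_tree(tree: dict) -> None:
    """Structural validation; raises :class:`NgsTreeConfigError` with the
    node path of the first malformed node."""
    if "root" not in tree:
        raise NgsTreeConfigError("tree config lacks 'root'")

    def walk(node, path):
        if not isinstance(node, dict):
            raise NgsTreeConfigError(f"node at {path} is not a mapping")
        if "class" in node:
            if node["class"] not in (1, 2, 3, 4, 5):
                raise NgsTreeConfigError(f"leaf at {path}: class must be 1..5")
            for mod in node.get("modifiers", []):
                if mod not in _MODIFIERS:
                    raise NgsTreeConfigError(f"leaf at {path}: unknown modifier {mod!r}")
            return
        for key in ("node", "factor", "op", "value", "true", "false"):
            if key not in node:
                raise NgsTreeConfigError(f"node at {path}: missing key {key!r}")
        if node["factor"] not in _FACTORS:
            raise NgsTreeConfigError(
                f"node at {path}: unknown factor {node['factor']!r}"
            )
        if node["op"] not in _OPS:
            raise NgsTreeConfigError(f"node at {path}: unknown op {node['op']!r}")
        walk(node["true"], path + ".true")
        walk(node["false"], path + ".false")

    walk(tree["root"], "root")


@dataclass(frozen=True)
class DecisionTrace:
    """Ordered audit trail: (node label, observed input, branch taken)."""

    steps: tuple[tuple[str, object, str], ...]
    final: FiveTierClass

    def __post_init__(self):
        if not self.steps:
            raise ValueError("decision trace may not be empty")


def _factors(e: EvidenceProfile) -> dict:
    lof_pos, lof_neg = _lof_assay_signals(e)
    loh_benign = e.loh == "variant_allele_lost"
    loh_path = e.loh == "variant_allele_retained_wt_lost"
    path_assay = lof_pos or loh_path
    benign_assay = (lof_neg or loh_benign or e.loh == "no_loh") and not lof_pos
    verdicts = [v for v in (e.insilico_missense, e.insilico_splice) if v is not None]
    if Verdict.SUPPORTS_PATHOGENIC in verdicts:
        insilico = "supports_pathogenic"
    elif Verdict.SUPPORTS_BENIGN in verdicts:
        insilico = "supports_benign"
    elif Verdict.CONFLICTING in verdicts:
        insilico = "conflicting"
    else:
        insilico = "insufficient"
    return {
        "af": e.max_population_af,
        "is_truncating": e.variant.vtype in TRUNCATING_TYPES,
        "insilico": insilico,
        "segregates": bool(e.cosegregation and e.cosegregation.segregates),
        "case_count": e.case_count,
        "_assay_direction": (
            "conflicting" if (path_assay and benign_assay)
            else "pathogenic" if path_assay
            else "benign" if benign_assay
            else "none"
        ),
    }


def classify_ngsnppgl(
    e: EvidenceProfile, tree: dict = DEFAULT_TREE
) -> tuple[FiveTierClass, DecisionTrace]:
    """Classify one profile through the decision tree with an audit trace."""
    validate_tree(tree)
    facts = _factors(e)
    steps: list[tuple[str, object, str]] = []

    node = tree["root"]
    while "class" not in node:
        value = facts[node["factor"]]
        branch = _OPS[node["op"]](value, node["value"])
        steps.append((node["node"], value, "true" if branch else "false"))
        node = node["true"] if branch else node["false"]

    cls = node["class"]
    for mod in node.get("modifiers", []):
        if mod == "assay_adjust":
            direction = facts["_assay_direction"]
            if direction == "pathogenic":
                cls = min(5, cls + 1)
            elif direction == "benign":
                cls = max(1, cls - 1)
            steps.append(("assay_adjust", direction, f"class={cls}"))
        elif mod == "recurrence_promote":
            threshold = tree.get("recurrence_threshold", 10)
            fired = facts["case_count"] >= threshold and cls == 4
            if fired:
                cls = 5
            steps.append(("recurrence_promote", facts["case_count"], f"class={cls}"))
    final = FiveTierClass(cls)
    return final, DecisionTrace(tuple(steps), final)


def classify_both(
    e: EvidenceProfile,
    acmg_config=None,
    tree: dict = DEFAULT_TREE,
) -> tuple[FiveTierClass, FiveTierClass]:
    """Run the ACMG and NGSnPPGL engines independently on one profile."""
    from .acmg_engine import DEFAULT_ACMG_CONFIG, classify_acmg

    acmg_class, _ = classify_acmg(e, acmg_config or DEFAULT_ACMG_CONFIG)
    ngs_class, _ = classify_ngsnppgl(e, tree)
    return acmg_class, ngs_class


def iter_leaves(tree: dict):
    """Yield (path, leaf) pairs; used to test that every leaf is reachable."""
    def walk(node, path):
        if "class" in node:
            yield path, node
        else:
            yield from walk(node["true"], path + ".true")
            yield from walk(node["false"], path + ".false")
    yield from walk(tree["root"], "root")
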