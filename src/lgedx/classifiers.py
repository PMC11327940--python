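"""LGE diagnostic classifiers.

Four binary classifiers for distinguishing ARVC from its differentials
("any RV-LGE", "any LV-LGE", "RV-LGE per Padua criteria", "LV-LGE per Padua
criteria"), the four-way Padua category, and a serializable binary decision
tree over :class:`~lgedx.segments.FeatureVector` predicates.

Padua tissue-characterization rules
-----------------------------------
* RV-LGE: enhancement in the RV inlet, outlet, or apex confirmed in two
  orthogonal views, i.e. in at least one of segments 18-20, 23 or 24 (the
  mid free-wall segments 21/22 do not qualify).
* LV-LGE: subepicardial or mid-myocardial enhancement in at least one of LV
  segments 1-16, excluding septal junctional (insertion-point) enhancement.
  The true apex (17) and subendocardial/transmural patterns never qualify.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

from .segments import (
    PADUA_LV_PATTERNS,
    Diagnosis,
    FeatureVector,
    FEATURE_NAMES,
    LVSegment,
    PatientRecord,
    RVSegment,
    extract_features,
)

__all__ = [
    "PaduaConfig",
    "PaduaCategory",
    "any_rv_lge",
    "any_lv_lge",
    "padua_rv_criterion",
    "padua_lv_criterion",
    "padua_category",
    "TreeNode",
    "DecisionTree",
    "tree_classify",
    "tree_from_json",
    "tree_to_json",
    "default_paper_tree",
]


@dataclass(frozen=True)
class PaduaConfig:
    """Configurable pieces of the Padua LGE rules.

    ``rv_criterion_segments`` is the inlet/outlet/apex set; it is a config
    value rather than a constant because the segment numbering convention
    for the RV model is not universal.
    """

    rv_criterion_segments: frozenset[int] = frozenset({18, 19, 20, 23, 24})

    def __post_init__(self) -> None:
        if not self.rv_criterion_segments:
            raise ValueError("Padua RV criterion segment set must be non-empty")
        bad = [s for s in self.rv_criterion_segments if s not in set(map(int, RVSegment))]
        if bad:
            raise ValueError(f"criterion segments outside RV range 18-24: {sorted(bad)}")


DEFAULT_PADUA_CONFIG = PaduaConfig()


class PaduaCategory(str, enum.Enum):
    """Joint LV/RV Padua-LGE fulfilment — a partition of any cohort."""

    BOTH = "both"
    LV_ONLY = "lv_only"
    RV_ONLY = "rv_only"
    NEITHER = "neither"


def any_rv_lge(f: FeatureVector) -> bool:
    """True iff LGE is present in any of the 7 RV segments."""
    return f.rv_segment_count > 0


def any_lv_lge(f: FeatureVector) -> bool:
    """True iff LGE is present in any of the 17 LV segments."""
    return f.lv_segment_count > 0


def padua_rv_criterion(
    patient: PatientRecord, config: PaduaConfig = DEFAULT_PADUA_CONFIG
) -> bool:
    """RV-LGE per Padua criteria: LGE in the RV inlet, outlet, or apex."""
    for seg in patient.lge.rv_positive():
        if int(seg) in config.rv_criterion_segments and int(seg) not in patient.lge.unconfirmed:
            return True
    return False


def padua_lv_criterion(patient: PatientRecord) -> bool:
    """LV-LGE per Padua criteria: subepicardial or mid-myocardial LGE in
    segments 1-16.

    Junctional-only septal enhancement is excluded by construction (it is
    never recorded in the segment map); the true apex does not count.
    """
    for seg, trans in patient.lge.lv_positive().items():
        if seg is LVSegment.TRUE_APEX:
            continue
        if int(seg) in patient.lge.unconfirmed:
            continue
        if trans in PADUA_LV_PATTERNS:
            return True
    return False


def padua_category(
    patient: PatientRecord, config: PaduaConfig = DEFAULT_PADUA_CONFIG
) -> PaduaCategory:
    rv = padua_rv_criterion(patient, config)
    lv = padua_lv_criterion(patient)
    if rv and lv:
        return PaduaCategory.BOTH
    if lv:
        return PaduaCategory.LV_ONLY
    if rv:
        return PaduaCategory.RV_ONLY
    return PaduaCategory.NEITHER


# ---------------------------------------------------------------------------
# Decision tree
# ---------------------------------------------------------------------------

class TreeValidationError(ValueError):
    """Raised when a tree references unknown features or is malformed."""


@dataclass(frozen=True)
class TreeNode:
    """One node of a binary decision tree.

    Internal nodes hold a predicate ``feature <op> threshold`` with
    ``op`` in {"ge", "eq"}; ``if_true``/``if_false`` are the subtrees taken
    when the predicate holds/fails.  Leaves hold a diagnosis label.
    Boolean features are compared as 0/1.
    """

    node_id: str = ""
    feature: Optional[str] = None
    op: str = "ge"
    threshold: float = 0.0
    if_true: Optional["TreeNode"] = None
    if_false: Optional["TreeNode"] = None
    leaf_label: Optional[Diagnosis] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_label is not None

    def test(self, f: FeatureVector) -> bool:
        value = f[self.feature]  # KeyError surfaced at validation, not here
        if self.op == "ge":
            return value >= self.threshold
        return value == self.threshold


@dataclass(frozen=True)
class DecisionTree:
    """A binary diagnostic tree over FeatureVector predicates.

    ``provenance`` records whether the topology was fixed from the published
    flowchart or learned by CART; arbitrary extra metadata rides along in
    ``metadata`` and survives JSON round-trips bit-identically.
    """

    root: TreeNode
    provenance: str = "learned"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_node(self.root, path="root")

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(n: TreeNode) -> None:
            if n.is_leaf:
                out.append(n)
            else:
                walk(n.if_false)
                walk(n.if_true)

        walk(self.root)
        return out

    def n_leaves(self) -> int:
        return len(self.leaves())


def _validate_node(node: TreeNode, path: str) -> None:
    if node.is_leaf:
        if not isinstance(node.leaf_label, Diagnosis):
            raise TreeValidationError(f"{path}: leaf label {node.leaf_label!r} is not a Diagnosis")
        return
    if node.feature not in FEATURE_NAMES:
        raise TreeValidationError(f"{path}: unknown feature {node.feature!r}")
    if node.op not in ("ge", "eq"):
        raise TreeValidationError(f"{path}: unknown comparator {node.op!r}")
    if node.if_true is None or node.if_false is None:
        raise TreeValidationError(f"{path}: internal node must have both children")
    _validate_node(node.if_false, path + ".if_false")
    _validate_node(node.if_true, path + ".if_true")


def tree_classify(
    tree: DecisionTree, f: FeatureVector, trace: Optional[list[str]] = None
) -> Diagnosis:
    """Route a feature vector to its unique leaf.

    If ``trace`` is given, the node ids and predicate outcomes along the
    root-to-leaf path are appended to it for reporting.
    """
    node = tree.root
    while not node.is_leaf:
        taken = node.test(f)
        if trace is not None:
            trace.append(
                f"{node.node_id or node.feature}: {node.feature} {node.op} "
                f"{node.threshold:g} -> {taken}"
            )
        node = node.if_true if taken else node.if_false
    if trace is not None:
        trace.append(f"leaf {node.node_id}: {node.leaf_label.value}")
    return node.leaf_label


def classify_patient(tree: DecisionTree, patient: PatientRecord) -> Diagnosis:
    return tree_classify(tree, extract_features(patient))


# --- JSON serialization ----------------------------------------------------

def _node_to_obj(node: TreeNode) -> dict:
    if node.is_leaf:
        obj: dict = {"leaf": node.leaf_label.value}
        if node.node_id:
            obj["node_id"] = node.node_id
        return obj
    obj = {
        "feature": node.feature,
        "op": node.op,
        "threshold": node.threshold,
        "if_true": _node_to_obj(node.if_true),
        "if_false": _node_to_obj(node.if_false),
    }
    if node.node_id:
        obj["node_id"] = node.node_id
    return obj


def _node_from_obj(obj: dict, path: str = "root") -> TreeNode:
    if "leaf" in obj:
        try:
            label = Diagnosis(obj["leaf"])
        except ValueError as exc:
            raise TreeValidationError(f"{path}: unknown diagnosis {obj['leaf']!r}") from exc
        return TreeNode(node_id=obj.get("node_id", ""), leaf_label=label)
    for key in ("feature", "op", "threshold", "if_true", "if_false"):
        if key not in obj:
            raise TreeValidationError(f"{path}: missing key {key!r}")
    return TreeNode(
        node_id=obj.get("node_id", ""),
        feature=obj["feature"],
        op=obj["op"],
        threshold=float(obj["threshold"]),
        if_true=_node_from_obj(obj["if_true"], path + ".if_true"),
        if_false=_node_from_obj(obj["if_false"], path + ".if_false"),
    )


def tree_to_json(tree: DecisionTree) -> str:
    obj = {
        "root": _node_to_obj(tree.root),
        "metadata": {"provenance": tree.provenance, **tree.metadata},
    }
    return json.dumps(obj, indent=2, sort_keys=True)


def tree_from_json(text: Union[str, bytes]) -> DecisionTree:
    obj = json.loads(text)
    if "root" not in obj:
        raise TreeValidationError("tree JSON must have a 'root' key")
    meta = dict(obj.get("metadata", {}))
    provenance = meta.pop("provenance", "learned")
    return DecisionTree(root=_node_from_obj(obj["root"]), provenance=provenance, metadata=meta)


def default_paper_tree() -> DecisionTree:
    """The fixed published CART flowchart, loaded from the packaged asset.

    Split conditions: anteroseptal LV-LGE at the root; on its absence,
    extensive (>=5 segments) then moderate (>=2 segments) mid-myocardial
    LV-LGE; on its presence, extensive (>=16 segments) LV-LGE, moderate
    (>=2 segments) RV-LGE, then inferolateral LV-LGE.
    """
    text = resources.files("lgedx.data").joinpath("padua_cart_tree.json").read_text()
    return tree_from_json(text)
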