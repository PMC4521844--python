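"""Combined tree + architecture assignment of Smyd classes and subgroups.

Tree evidence is primary: a sequence inherits the class of the smallest
well-supported clade that contains it together with at least one reference
anchor, provided every anchor in that clade agrees.  Domain architecture
acts as independent confirmation — a conflicting architecture demotes the
assignment to UNCLASSIFIED rather than overriding the tree — and as a
fallback when no supported anchored clade exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy

from .domain_architecture import Architecture, architecture_class
from .phylogeny import path_metrics

CLASSES = ("SMYD3", "SMYD4", "SMYD5", "SMYDA", "ATYPICAL_TPR")
SUBGROUPS = {
    "SMYD3": ("SMYD1", "SMYD2", "SMYD3"),
    "SMYD4": ("SMYD4", "SMYD4L", "SMYD4I"),
}


@dataclass(frozen=True)
class ClassLabel:
    smyd_class: str
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.smyd_class not in CLASSES + ("UNCLASSIFIED",):
            raise ValueError(f"unknown class {self.smyd_class!r}")
        if self.subgroup is not None and self.smyd_class not in SUBGROUPS:
            raise ValueError("subgroup only valid for SMYD3/SMYD4 classes")


@dataclass
class AnchorSet:
    """Reference sequences with known class (and optionally subgroup)."""

    anchors: dict[str, ClassLabel]

    def of_class(self, smyd_class: str) -> dict[str, ClassLabel]:
        return {k: v for k, v in self.anchors.items() if v.smyd_class == smyd_class}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnchorSet":
        anchors: dict[str, ClassLabel] = {}
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#") or line.startswith("id\t"):
                    continue
                parts = line.split("\t")
                sub = parts[2] if len(parts) > 2 and parts[2] else None
                anchors[parts[0]] = ClassLabel(parts[1], sub)
        return cls(anchors=anchors)

    @classmethod
    def default(cls) -> "AnchorSet":
        with resources.as_file(
            resources.files("smydkit.data") / "anchors_default.tsv"
        ) as p:
            return cls.from_tsv(p)


@dataclass
class Evidence:
    clade_anchors: list[str] = field(default_factory=list)
    clade_support: float | None = None
    architecture_signature: str = ""
    agreement: str = "n/a"  # agree | disagree | architecture-only | n/a


@dataclass
class ClassAssignment:
    seq_id: str
    label: ClassLabel
    evidence: Evidence


def _supported_clades(tree: dendropy.Tree, min_support: float):
    """Clades induced by internal edges with support >= min_support, as
    (leaf-set, support) for both sides of each edge, smallest first."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    clades: list[tuple[frozenset[str], float]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        sup = getattr(node, "support", None)
        if sup is None or sup < min_support:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        clades.append((below, sup))
        other = frozenset(leaves - below)
        if len(other) >= 2:
            clades.append((other, sup))
    clades.sort(key=lambda c: (len(c[0]), sorted(c[0])))
    return clades


def _clade_vote(
    leaf: str,
    clades,
    anchor_labels: dict[str, str],
) -> tuple[str, list[str], float] | None:
    """Smallest supported clade containing ``leaf`` and >=1 anchor with all
    anchors of one label; None when no such clade exists."""
    for members, sup in clades:
        if leaf not in members:
            continue
        present = sorted(a for a in anchor_labels if a in members)
        if not present:
            continue
        votes = {anchor_labels[a] for a in present}
        if len(votes) == 1:
            return votes.pop(), present, sup
    return None


def assign_classes(
    tree: dendropy.Tree,
    architectures: dict[str, Architecture],
    anchors: AnchorSet,
    min_support: float = 70.0,
) -> list[ClassAssignment]:
    """Assign a Smyd class to every non-anchor leaf of the tree.

    Tree rule: smallest clade with support >= ``min_support`` containing the
    leaf and at least one anchor, all contained anchors sharing one class.
    An architecture that names candidate classes must contain the tree's
    class, otherwise the assignment is demoted to UNCLASSIFIED with a
    disagreement flag.  Leaves without a qualifying clade but with a unique
    architecture class get that class as architecture-only evidence.
    """
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(anchors.anchors) - leaf_labels
    if missing:
        raise ValueError(f"anchors missing from tree: {sorted(missing)}")
    clades = _supported_clades(tree, min_support)
    anchor_class = {a: lab.smyd_class for a, lab in anchors.anchors.items()}

    out: list[ClassAssignment] = []
    for leaf in sorted(leaf_labels):
        if leaf in anchors.anchors:
            continue
        arch = architectures.get(leaf)
        arch_classes = architecture_class(arch) if arch is not None else set()
        sig = arch.signature if arch is not None else ""
        vote = _clade_vote(leaf, clades, anchor_class)
        if vote is not None:
            cls, present, sup = vote
            if arch_classes and cls not in arch_classes:
                out.append(
                    ClassAssignment(
                        leaf,
                        ClassLabel("UNCLASSIFIED"),
                        Evidence(present, sup, sig, "disagree"),
                    )
                )
            else:
                out.append(
                    ClassAssignment(
                        leaf,
                        ClassLabel(cls),
                        Evidence(present, sup, sig, "agree" if arch_classes else "n/a"),
                    )
                )
        elif len(arch_classes) == 1:
            out.append(
                ClassAssignment(
                    leaf,
                    ClassLabel(arch_classes.pop()),
                    Evidence([], None, sig, "architecture-only"),
                )
            )
        else:
            out.append(
                ClassAssignment(leaf, ClassLabel("UNCLASSIFIED"), Evidence([], None, sig))
            )
    return out


def assign_subgroups(
    assignments: list[ClassAssignment],
    tree: dendropy.Tree,
    subgroup_anchors: AnchorSet,
    min_support: float = 70.0,
) -> list[ClassAssignment]:
    """Refine SMYD3/SMYD4-class assignments with subgroup anchors, using the
    same smallest-supported-anchored-clade rule within each class."""
    clades = _supported_clades(tree, min_support)
    sub_label = {
        a: lab.subgroup
        for a, lab in subgroup_anchors.anchors.items()
        if lab.subgroup is not None
    }
    out: list[ClassAssignment] = []
    for asg in assignments:
        cls = asg.label.smyd_class
        if cls not in SUBGROUPS:
            out.append(asg)
            continue
        relevant = {
            a: s for a, s in sub_label.items()
            if subgroup_anchors.anchors[a].smyd_class == cls
        }
        vote = _clade_vote(asg.seq_id, clades, relevant)
        if vote is None:
            out.append(asg)
            continue
        sub, present, sup = vote
        out.append(
            ClassAssignment(
                asg.seq_id,
                ClassLabel(cls, sub),
                Evidence(present, sup, asg.evidence.architecture_signature,
                         asg.evidence.agreement),
            )
        )
    return out


def suggest_ortholog(
    query: str, tree: dendropy.Tree, anchors: AnchorSet
) -> tuple[str, float, float]:
    """Closest anchor by patristic distance.

    Returns (anchor id, distance, path support).  Ties in distance are
    broken by the higher minimum bootstrap support along the connecting
    path, then lexicographically.
    """
    if not anchors.anchors:
        raise ValueError("no anchors provided")
    metrics = path_metrics(tree, query)
    candidates = [
        (a, metrics[a][0], metrics[a][1]) for a in anchors.anchors if a in metrics
    ]
    if not candidates:
        raise ValueError("no anchor present in tree")
    candidates.sort(key=lambda c: (round(c[1], 12), -c[2], c[0]))
    return candidates[0]
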