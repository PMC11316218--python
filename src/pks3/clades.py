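"""Clade-level interpretation of the rooted tree.

Monophyly tests, reference-based clade assignment of query sequences,
counting of maximal clades under a leaf predicate, and concordance between
residue-based class labels and tree placement. All operations expect a
rooted tree (root on the outgroup first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy

from .classify import ClassificationResult
from .errors import TreeError

UNPLACED = "unplaced"


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, tip_set: Sequence[str] | set[str]) -> bool:
    """True iff some node's descendant leaf set equals ``tip_set`` exactly.

    Singletons are monophyletic (the leaf itself is the node).
    """
    tips = frozenset(tip_set)
    leaves = _leaf_map(tree)
    missing = tips - leaves.keys()
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(tips) == 1:
        return True
    # walk up from one member; the MRCA's leaf set either equals tips or not
    node = leaves[min(tips)]
    while node is not None:
        node_leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if tips <= node_leaves:
            return node_leaves == tips
        node = node.parent_node
    return False


def assign_query_to_clade(
    tree: dendropy.Tree,
    query_id: str,
    reference_labels: Mapping[str, str],
) -> str:
    """Class of the smallest clade containing the query that holds labeled
    references of exactly one class (the query itself does not vote).

    Returns ``"unplaced"`` when the smallest reference-containing clade
    holds references of more than one class.
    """
    leaves = _leaf_map(tree)
    if query_id not in leaves:
        raise TreeError(f"query {query_id!r} is not a leaf of the tree")
    node = leaves[query_id].parent_node
    while node is not None:
        labels = {
            reference_labels[l.taxon.label]
            for l in node.leaf_iter()
            if l.taxon.label in reference_labels and l.taxon.label != query_id
        }
        if len(labels) == 1:
            return labels.pop()
        if len(labels) > 1:
            return UNPLACED
        node = node.parent_node
    return UNPLACED


def count_maximal_clades(
    tree: dendropy.Tree,
    predicate: Callable[[object], bool],
    metadata: Mapping[str, object],
) -> int:
    """Number of maximal clades whose every leaf satisfies the predicate.

    ``metadata`` maps leaf labels to whatever the predicate inspects; a leaf
    absent from it is an error. No counted clade is nested in another;
    singleton leaves count.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in metadata:
            raise TreeError(f"leaf {leaf.taxon.label!r} has no metadata")

    def satisfied(node: dendropy.Node) -> bool:
        return all(
            predicate(metadata[l.taxon.label]) for l in node.leaf_iter()
        )

    count = 0
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if satisfied(node):
            count += 1  # maximal: don't descend
        else:
            stack.extend(node.child_nodes())
    return count


@dataclass
class CladeReport:
    """Joint residue/phylogeny classification summary."""

    clade_assignments: dict[str, str] = field(default_factory=dict)  # id -> clade label
    residue_labels: dict[str, str] = field(default_factory=dict)     # id -> residue label
    concordant: dict[str, bool] = field(default_factory=dict)
    monophyly: dict[str, bool] = field(default_factory=dict)         # class -> verdict
    class_counts: dict[str, int] = field(default_factory=dict)       # residue labels
    clade_counts: dict[str, int] = field(default_factory=dict)       # clade labels
    maximal_clades: dict[str, int] = field(default_factory=dict)

    @property
    def membership(self) -> dict[str, list[str]]:
        """Partition of query ids by clade label (each id appears once)."""
        out: dict[str, list[str]] = {}
        for seq_id, label in self.clade_assignments.items():
            out.setdefault(label, []).append(seq_id)
        return out

    @property
    def percent_concordant(self) -> float:
        if not self.concordant:
            return 100.0
        return 100.0 * sum(self.concordant.values()) / len(self.concordant)

    def to_json(self) -> str:
        return json.dumps(
            {
                "clade_assignments": self.clade_assignments,
                "residue_labels": self.residue_labels,
                "concordant": self.concordant,
                "monophyly": self.monophyly,
                "class_counts": self.class_counts,
                "clade_counts": self.clade_counts,
                "maximal_clades": self.maximal_clades,
                "percent_concordant": self.percent_concordant,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["id\tresidue_label\tclade_label\tconcordant"]
        for seq_id in sorted(self.clade_assignments):
            lines.append(
                f"{seq_id}\t{self.residue_labels.get(seq_id, '')}\t"
                f"{self.clade_assignments[seq_id]}\t"
                f"{str(self.concordant.get(seq_id, '')).lower()}"
            )
        return "\n".join(lines) + "\n"


def concordance_report(
    classifications: Sequence[ClassificationResult],
    tree: dendropy.Tree,
    reference_labels: Mapping[str, str],
) -> CladeReport:
    """Compare residue-based labels with clade placement for every query.

    Queries are the classified ids; reference ids (``reference_labels``)
    anchor the clade assignment and are tested for per-class monophyly.
    An empty query set yields an empty report.
    """
    report = CladeReport()
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}

    for result in classifications:
        if result.query_id not in leaves:
            continue
        clade = assign_query_to_clade(tree, result.query_id, reference_labels)
        report.clade_assignments[result.query_id] = clade
        report.residue_labels[result.query_id] = result.label
        report.concordant[result.query_id] = clade == result.label
        report.class_counts[result.label] = report.class_counts.get(result.label, 0) + 1
        report.clade_counts[clade] = report.clade_counts.get(clade, 0) + 1

    for class_tag in sorted(set(reference_labels.values())):
        tips = [i for i, c in reference_labels.items() if c == class_tag and i in leaves]
        if tips:
            report.monophyly[class_tag] = is_monophyletic(tree, tips)
    return report
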