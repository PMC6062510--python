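"""Gene-tree tests for venom-gene origin scenarios.

After two rounds of whole-genome duplication (2R-WGD) a gene family holds up
to four ohnologs. If venom function was co-opted once, in a single ohnolog
lineage, the SV genes of a family form one clade and the NV genes the rest
of the tree; if venom copies arose repeatedly, SV tips are scattered across
several clades. On an unrooted tree, monophyly of the SV tip set is the
existence of an edge whose bipartition separates exactly the SV tips, which
avoids any arbitrary rooting choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

LABELS = ("SV", "NV")

SINGLE_COPY_COOPTION = "single_copy_cooption"
INDEPENDENT_DIVERSIFICATION = "independent_diversification"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class LabeledTree:
    """An unrooted gene tree whose tips carry (species, SV/NV) labels.

    Tip labels of the form ``id|species|SV`` are parsed inline; otherwise a
    sidecar mapping tip id -> (species, label) must be supplied.
    """

    tree: dendropy.Tree
    labels: Mapping[str, tuple[str, str]]  # tip id -> (species, "SV"/"NV")

    def __post_init__(self):
        tips = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(tips) < 4:
            raise ValueError("a labeled gene tree needs at least 4 tips")
        if len(set(tips)) != len(tips):
            raise ValueError("tip ids must be unique")
        missing = set(tips) - set(self.labels)
        if missing:
            raise ValueError(f"unlabeled tips: {sorted(missing)[:5]}")
        for tip in tips:
            if self.labels[tip][1] not in LABELS:
                raise ValueError(f"tip {tip}: label must be SV or NV")

    @property
    def tip_ids(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def tips_with_label(self, label: str) -> frozenset[str]:
        return frozenset(t for t in self.tip_ids if self.labels[t][1] == label)


def parse_labeled_tree(
    newick: str, labels: Mapping[str, tuple[str, str]] | None = None
) -> LabeledTree:
    """Read a newick string into a :class:`LabeledTree`.

    Without a sidecar ``labels`` mapping, tip names must follow the inline
    convention ``id|species|LABEL`` (the full name remains the tip id).
    """
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    if labels is None:
        labels = {}
        for leaf in tree.leaf_node_iter():
            parts = leaf.taxon.label.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"tip {leaf.taxon.label!r} not in id|species|LABEL form "
                    "and no sidecar labels given"
                )
            labels[leaf.taxon.label] = (parts[1], parts[2])
    return LabeledTree(tree=tree, labels=dict(labels))


def _bipartitions(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets induced below each edge of the (arbitrarily rooted) tree."""
    sets: list[frozenset[str]] = []

    def collect(node) -> frozenset[str]:
        if node.is_leaf():
            s = frozenset([node.taxon.label])
        else:
            s = frozenset().union(*(collect(ch) for ch in node.child_nodes()))
        sets.append(s)
        return s

    collect(tree.seed_node)
    return sets


def sv_monophyletic(tree: LabeledTree) -> bool:
    """True iff some edge of the unrooted tree splits off exactly the SV tips.

    Requires at least one tip of each label (otherwise there is no split to
    test and ``ValueError`` is raised).
    """
    sv = tree.tips_with_label("SV")
    nv = tree.tips_with_label("NV")
    if not sv or not nv:
        raise ValueError("tree must carry both SV and NV tips")
    all_tips = sv | nv
    for side in _bipartitions(tree.tree):
        if side == sv or all_tips - side == sv:
            return True
    return False


def _maximal_sv_clades(tree: LabeledTree) -> int:
    """Number of maximal SV-only clades on the tree rooted at an NV tip.

    Rooting at an NV tip makes every maximal SV-pure subtree a clade of the
    rooted tree regardless of the original (arbitrary) rooting.
    """
    nv_tip = sorted(tree.tips_with_label("NV"))[0]
    rerooted = tree.tree.clone(depth=1)
    leaf = next(
        l for l in rerooted.leaf_node_iter() if l.taxon.label == nv_tip
    )
    rerooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    labels = tree.labels

    count = 0

    def walk(node) -> bool:
        """Return True when the subtree is SV-pure; count maximal ones."""
        nonlocal count
        if node.is_leaf():
            return labels[node.taxon.label][1] == "SV"
        child_pure = [walk(ch) for ch in node.child_nodes()]
        if all(child_pure) and node.child_nodes():
            return True
        for ch, pure in zip(node.child_nodes(), child_pure):
            if pure:
                count += 1
        return False

    if walk(rerooted.seed_node):
        count = 1
    return count


def classify_ohnolog_scenario(tree: LabeledTree) -> str:
    """Classify a family tree against the ohnolog co-option scenarios.

    * SV tips monophyletic (and >= 2 of them) -> ``single_copy_cooption``:
      one ohnolog lineage was recruited for venom and expanded there.
    * SV tips split across >= 2 maximal clades separated by NV tips ->
      ``independent_diversification``.
    * A single SV tip cannot distinguish the scenarios -> ``undetermined``.
    """
    sv = tree.tips_with_label("SV")
    if len(sv) == 1:
        return UNDETERMINED
    if sv_monophyletic(tree):
        return SINGLE_COPY_COOPTION
    if _maximal_sv_clades(tree) >= 2:
        return INDEPENDENT_DIVERSIFICATION
    return UNDETERMINED
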