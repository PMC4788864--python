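"""Phylogenetic-tree consumption and reference-anchor subgroup assignment.

Trees are produced externally (e.g. maximum-likelihood inference) and read
from Newick. Family subfamilies/subgroups (C1-1 ... C4-3 style) are
transferred from user-declared reference anchors: a query leaf takes
subgroup X when the smallest clade containing it and at least one anchor
contains anchors of only subgroup X; otherwise it takes the subgroup of
its nearest anchor by path length, with exact ties left "unassigned".
Unrooted input is midpoint-rooted first (clade queries need a root) unless
an outgroup leaf is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a path) preserving labels, supports, lengths.

    Internal-node labels are kept as node labels (bootstrap supports in
    the usual convention). Duplicate leaf labels are a hard error.
    """
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if not text.strip():
        raise ValueError("empty Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises reader-specific subclasses
        raise ValueError(f"invalid Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf labels in tree: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def internal_supports(tree: dendropy.Tree) -> list[float]:
    """Bootstrap-style supports parsed from internal-node labels."""
    supports = []
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                supports.append(float(node.label))
            except ValueError:
                continue
    return supports


@dataclass(frozen=True)
class SubgroupAssignment:
    leaf: str
    subgroup: str  # "unassigned" when ambiguous
    method: str    # "anchor", "clade", "nearest-anchor", or "tie"
    supporting_anchors: tuple[str, ...]


def _ensure_rooted(tree: dendropy.Tree, outgroup: str | None) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 1.0
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
        tree.to_outgroup_position(node, update_bipartitions=False)
    elif not tree.is_rooted:
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def assign_subgroups(
    tree: dendropy.Tree,
    anchors: Mapping[str, str],
    *,
    outgroup: str | None = None,
) -> list[SubgroupAssignment]:
    """Assign every non-anchor leaf a subgroup from the anchor map.

    Walks from each query leaf toward the root; the first ancestor whose
    subtree contains anchors decides: one subgroup -> clade assignment,
    several -> fall back to the nearest anchor by path length (ties across
    subgroups -> "unassigned"). Anchors keep their declared subgroup.
    """
    if not anchors:
        raise ValueError("at least one anchor is required")
    rooted = _ensure_rooted(tree, outgroup)
    labels = set(leaf_labels(rooted))
    missing = sorted(set(anchors) - labels)
    if missing:
        raise ValueError(f"anchors not present in tree: {missing}")

    pdm = rooted.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in rooted.taxon_namespace}

    # anchor leaves under each node
    anchor_sets: dict[int, set[str]] = {}
    for node in rooted.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            anchor_sets[id(node)] = {label} if label in anchors else set()
        else:
            merged: set[str] = set()
            for child in node.child_nodes():
                merged |= anchor_sets[id(child)]
            anchor_sets[id(node)] = merged

    assignments: list[SubgroupAssignment] = []
    for leaf in rooted.leaf_node_iter():
        label = leaf.taxon.label
        if label in anchors:
            assignments.append(
                SubgroupAssignment(label, anchors[label], "anchor", (label,))
            )
            continue
        node = leaf.parent_node
        clade_anchors: set[str] = set()
        while node is not None:
            clade_anchors = anchor_sets[id(node)]
            if clade_anchors:
                break
            node = node.parent_node
        subgroups = {anchors[a] for a in clade_anchors}
        if len(subgroups) == 1:
            assignments.append(
                SubgroupAssignment(
                    label, next(iter(subgroups)), "clade", tuple(sorted(clade_anchors))
                )
            )
            continue
        # mixed clade: nearest anchor by path length
        distances = {
            a: pdm.patristic_distance(taxa[label], taxa[a]) for a in anchors
        }
        best = min(distances.values())
        nearest = sorted(a for a, d in distances.items() if abs(d - best) < 1e-12)
        nearest_subgroups = {anchors[a] for a in nearest}
        if len(nearest_subgroups) == 1:
            assignments.append(
                SubgroupAssignment(
                    label, next(iter(nearest_subgroups)), "nearest-anchor", tuple(nearest)
                )
            )
        else:
            assignments.append(
                SubgroupAssignment(label, "unassigned", "tie", tuple(nearest))
            )
    return assignments


def read_anchor_table(path: str | Path) -> dict[str, str]:
    """Anchors TSV (leaf, subgroup) -> mapping; duplicate leaves error."""
    anchors: dict[str, str] = {}
    header_seen = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen and fields[0].lower() == "leaf":
                header_seen = True
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected leaf<TAB>subgroup")
            if fields[0] in anchors:
                raise ValueError(f"{path}:{lineno}: duplicate anchor leaf {fields[0]!r}")
            anchors[fields[0]] = fields[1]
    return anchors


def write_assignments(assignments: Sequence[SubgroupAssignment], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("leaf\tsubgroup\tmethod\tsupporting_anchors\n")
        for a in assignments:
            handle.write(
                f"{a.leaf}\t{a.subgroup}\t{a.method}\t{','.join(a.supporting_anchors)}\n"
            )
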