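"""Rooted phylogenetic trees with branch lengths in substitutions per site.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
This module wraps reading/writing (Newick), outgroup rooting, pruning that
preserves path lengths, and the distance accessors (root-to-tip, patristic)
that the downstream rate metrics are built on.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "root_at_outgroup",
    "tree_total_length",
    "scale_branch_lengths",
    "root_to_tip",
    "patristic_distance",
    "patristic_matrix",
    "prune_preserving_lengths",
]


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    if node.label is not None:
        return str(node.label)
    return "<unnamed internal node>"


def read_newick(source: str | os.PathLike, *, clamp_negative: bool = False) -> dendropy.Tree:
    """Parse a rooted Newick tree from a string or file path.

    Branch lengths are required on every non-root edge; negative lengths are
    rejected unless ``clamp_negative`` is set, in which case they are clamped
    to zero. Internal node labels (e.g. support values) are preserved.
    Scientific-notation lengths and quoted labels are accepted.
    """
    text: str | None = None
    if isinstance(source, str) and ("(" in source or ";" in source):
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="default-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick input: {exc}") from exc

    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        lab = _node_label(leaf)
        if lab in seen:
            raise TreeError(f"duplicate leaf label {lab!r}")
        seen.add(lab)

    root = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise TreeError(f"missing branch length on the edge above {_node_label(node)!r}")
        if node.edge.length < 0:
            if clamp_negative:
                node.edge.length = 0.0
            else:
                raise TreeError(
                    f"negative branch length {node.edge.length} above {_node_label(node)!r}; "
                    "pass clamp_negative=True to clamp to zero"
                )
    return tree


def write_newick(tree: dendropy.Tree, path: str | os.PathLike | None = None) -> str:
    """Serialise a tree to Newick; returns the string and optionally writes a file."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [_node_label(leaf) for leaf in tree.leaf_node_iter()]


def _leaf_by_label(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {_node_label(leaf): leaf for leaf in tree.leaf_node_iter()}


def root_at_outgroup(tree: dendropy.Tree, outgroup_leaves: Iterable[str]) -> dendropy.Tree:
    """Reroot so that the root separates the outgroup from everything else.

    The outgroup must be monophyletic in the unrooted sense (it, or its
    complement, forms a clade). Total branch length is preserved: the edge on
    which the new root is placed is split at its midpoint.
    """
    outgroup = set(outgroup_leaves)
    tree = tree.clone(depth=1)
    lookup = _leaf_by_label(tree)
    missing = outgroup - lookup.keys()
    if missing:
        raise TreeError(f"outgroup leaves not in tree: {sorted(missing)}")
    all_leaves = set(lookup)
    if outgroup == all_leaves:
        raise TreeError("outgroup cannot contain every leaf")

    # Find the edge whose removal bipartitions leaves into outgroup | rest.
    target_node = None
    for node in tree.postorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {_node_label(lf) for lf in node.leaf_iter()}
        if below == outgroup or below == all_leaves - outgroup:
            target_node = node
            break
    if target_node is None:
        # Report which outgroup members break monophyly: those whose smallest
        # enclosing clade drags in non-outgroup leaves.
        raise TreeError(
            f"outgroup {sorted(outgroup)} is not monophyletic (unrooted) in this tree"
        )

    edge = target_node.edge
    half = (edge.length or 0.0) / 2.0
    tree.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=True)
    tree.update_bipartitions(suppress_unifurcations=True)
    return tree


def tree_total_length(tree: dendropy.Tree) -> float:
    """Total extent of molecular evolution: the sum of all branch lengths."""
    return float(sum(e.length for e in tree.preorder_edge_iter() if e.length is not None))


def scale_branch_lengths(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    """Return a copy with every branch length multiplied by ``factor``."""
    if factor <= 0:
        raise TreeError("scale factor must be positive")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


def root_to_tip(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip distance per leaf: summed branch lengths from the root.

    This is the per-lineage extent of evolution since the last common
    ancestor at the root (substitutions per site).
    """
    dist: dict[str, float] = {}
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
        if node.is_leaf():
            dist[_node_label(node)] = depth[id(node)]
    return dist


def patristic_distance(tree: dendropy.Tree, leaf_a: str, leaf_b: str) -> float:
    """Path length between two leaves through their most recent common ancestor."""
    mat = patristic_matrix(tree)
    for lab in (leaf_a, leaf_b):
        if lab not in mat.index:
            raise TreeError(f"leaf {lab!r} not in tree")
    return float(mat.loc[leaf_a, leaf_b])


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """All pairwise leaf-to-leaf path lengths as a symmetric DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [t for t in pdm.taxon_iter()]
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def prune_preserving_lengths(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Restrict a tree to a leaf subset without distorting any retained path.

    Unary internal nodes created by the pruning are collapsed by summing
    their incident branch lengths, so every pairwise patristic distance
    among kept leaves — and every root-to-tip distance, whenever the
    original root still subtends two kept lineages — is unchanged.
    """
    keep = set(keep)
    lookup = _leaf_by_label(tree)
    unknown = keep - lookup.keys()
    if unknown:
        raise TreeError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least two leaves to keep")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    # extract_tree may leave the original root as a unifurcation carrying the
    # path down to the kept clade; keep that edge so root-to-tip distances
    # measured from the original root are preserved.
    return pruned


def species_leaf_index(species_map: Mapping[str, str]) -> dict[str, list[str]]:
    """Invert a leaf→species map into species→[leaf, ...] (sorted for determinism)."""
    index: dict[str, list[str]] = {}
    for leaf, sp in species_map.items():
        index.setdefault(sp, []).append(leaf)
    return {sp: sorted(ls) for sp, ls in sorted(index.items())}
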