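"""Small helpers around dendropy trees: parsing, patristic distances, clades.

All newick handling goes through here so that underscore-bearing taxon labels
(``S_exigua`` etc.) survive a round trip unmangled.
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import numpy as np
import pandas as pd


def load_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string (or read a file path ending in .nwk/.newick/.tre)."""
    if not newick.lstrip().startswith("(") :
        with open(newick) as fh:
            newick = fh.read()
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip()


def leaf_names(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def is_monophyletic(tree: dendropy.Tree, species: Iterable[str]) -> bool:
    """True iff ``species`` is exactly the leaf set of some node of the tree."""
    target = frozenset(species)
    if len(target) == 1:
        return target <= set(leaf_names(tree))
    for nd in tree.preorder_node_iter():
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if leaves == target:
            return True
    return False


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise path-length (patristic) distances between leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    labels = [t.label for t in taxa]
    D = np.zeros((len(taxa), len(taxa)))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i < j:
                d = pdm.patristic_distance(ti, tj)
                D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def nontrivial_clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Leaf sets of internal non-root nodes with 2 <= size < number of leaves.

    A multifurcating root with internal children is taken as evidence the tree
    is unrooted and rejected; a star tree (all children of the single internal
    node are leaves) simply yields no clades.
    """
    root = tree.seed_node
    all_leaves = set(leaf_names(tree))
    internal = [
        nd
        for nd in tree.preorder_node_iter()
        if nd is not root and not nd.is_leaf()
    ]
    if len(root.child_nodes()) > 2 and internal:
        raise ValueError("tree appears unrooted (multifurcating root); root it first")
    clades = []
    for nd in internal:
        leaves = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if 2 <= len(leaves) < len(all_leaves):
            clades.append(leaves)
    # deterministic: by size then lexicographic
    return sorted(set(clades), key=lambda s: (len(s), tuple(sorted(s))))


def smallest_clade_map(tree: dendropy.Tree) -> dict[str, frozenset[str]]:
    """Each leaf -> the smallest non-trivial clade containing it (or its own singleton)."""
    clades = nontrivial_clades(tree)
    out: dict[str, frozenset[str]] = {}
    for sp in leaf_names(tree):
        containing = [c for c in clades if sp in c]
        out[sp] = min(containing, key=len) if containing else frozenset([sp])
    return out
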