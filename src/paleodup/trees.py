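"""Shared Newick I/O and tree utilities built on dendropy.

Trees carry branch lengths in whatever unit the producing stage uses
(Mya for chronograms and dated gene-family trees, coalescent units for
multispecies-coalescent species trees and gene trees).  Files written by
this package start with a ``#units=`` comment line recording the unit;
:func:`read_newick` skips such lines transparently.
"""

from __future__ import annotations

import io
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "read_newick",
    "write_newick",
    "as_newick",
    "node_ages",
    "root_age",
    "is_ultrametric",
    "leaf_labels",
    "bipartitions",
    "prune_to_taxa",
    "mrca_clade",
    "is_monophyletic",
    "clade_sets",
]


class NewickError(ValueError):
    """Raised on malformed Newick input (position reported by dendropy)."""


def _parse_newick_string(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"newick parse error: {exc}") from exc
    tree.is_rooted = True  # everything here treats topologies as rooted
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise NewickError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def read_newick(path_or_text) -> dendropy.Tree:
    """Read one rooted tree from a Newick file or literal string.

    Leading lines beginning with ``#`` (unit headers) are skipped.
    Labels containing ``|`` (the ``sample|copy`` dialect) survive verbatim.
    """
    text = None
    s = str(path_or_text)
    if s.lstrip().startswith("(") or s.lstrip().startswith("#"):
        text = s
    else:
        with open(s) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return _parse_newick_string("\n".join(lines))


def write_newick(tree: dendropy.Tree, path, units: str | None = None) -> None:
    """Write a tree in Newick form, optionally with a ``#units=`` header."""
    with open(path, "w") as fh:
        if units is not None:
            fh.write(f"#units={units}\n")
        fh.write(as_newick(tree))
        fh.write("\n")


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Node ages (time before present) for an ultrametric tree.

    Age of a node = max over leaves below it of the path length to that
    leaf.  For an exactly ultrametric tree all leaves give the same value.
    """
    ages: dict[dendropy.Node, float] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            ages[nd] = 0.0
        else:
            ages[nd] = max(
                ages[ch] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
            )
    return ages


def root_age(tree: dendropy.Tree) -> float:
    return node_ages(tree)[tree.seed_node]


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = []
    for lf in tree.leaf_node_iter():
        d, nd = 0.0, lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax


def bipartitions(
    tree: dendropy.Tree, taxa: Sequence[str] | None = None
) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions as canonical frozensets of labels.

    Each bipartition is represented by the side *not* containing the
    lexicographically smallest taxon, so representations from different
    trees on the same leaf set are directly comparable.
    """
    labels = set(taxa) if taxa is not None else set(leaf_labels(tree))
    anchor = min(labels)
    n = len(labels)
    out: set[frozenset[str]] = set()
    below: dict[dendropy.Node, set[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = {nd.taxon.label} & labels
        else:
            s: set[str] = set()
            for ch in nd.child_nodes():
                s |= below[ch]
            below[nd] = s
            side = s if anchor not in s else labels - s
            if 2 <= len(side) <= n - 2:
                out.add(frozenset(side))
    return out


def prune_to_taxa(tree: dendropy.Tree, taxa: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` restricted to the given leaf labels."""
    keep = set(taxa)
    clone = dendropy.Tree(tree)
    clone.retain_taxa_with_labels(sorted(keep & set(leaf_labels(clone))))
    return clone


def mrca_clade(tree: dendropy.Tree, taxa: Iterable[str]) -> set[str]:
    """Leaf set of the MRCA of ``taxa`` in ``tree``."""
    want = set(taxa)
    mrca = tree.mrca(taxon_labels=sorted(want))
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def is_monophyletic(tree: dendropy.Tree, taxa: Iterable[str]) -> bool:
    want = set(taxa)
    if len(want) <= 1:
        return True
    return mrca_clade(tree, want) == want


def clade_sets(tree: dendropy.Tree) -> dict[frozenset[str], dendropy.Node]:
    """Map every clade (leaf set below a node) to its node."""
    out: dict[frozenset[str], dendropy.Node] = {}
    below: dict[dendropy.Node, frozenset[str]] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset({nd.taxon.label})
        else:
            acc: set[str] = set()
            for ch in nd.child_nodes():
                acc |= below[ch]
            below[nd] = frozenset(acc)
        out[below[nd]] = nd
    return out
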