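"""Rooted-tree support for the phylogenetic metrics.

Trees are ``skbio.TreeNode`` objects, treated as rooted exactly as written
(no re-rooting; UniFrac values depend on the root and this package keeps
the user's root). All non-root branches must carry a non-negative length;
zero-length branches are allowed and simply contribute nothing.

The central structure is the :class:`BranchTable`: for every branch that
lies on a path from a listed tip to the root it records the branch length
and a boolean mask over the listed tips saying which of them descend from
that branch. Faith's PD and both UniFrac variants are simple weighted sums
over this table, which is what makes the "fast" algorithms fast: the table
is computed once per tree and reused for every vector pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode
from skbio.io import FileFormatError, UnrecognizedFormatError

from .exceptions import ValidationError

__all__ = [
    "PhyloTree",
    "BranchTable",
    "read_newick",
    "parse_newick",
    "write_newick",
    "validate_tips",
    "branch_table",
]

PhyloTree = TreeNode


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise ValidationError("tree contains unlabeled tips")
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValidationError(f"duplicate tip label in tree: {n!r}")
        seen.add(n)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            where = node.name if node.name else "an internal node"
            raise ValidationError(f"missing branch length on {where}")
        if node.length < 0:
            raise ValidationError(
                f"negative branch length {node.length} on {node.name or 'internal node'}"
            )
    return tree


def parse_newick(newick: str) -> PhyloTree:
    """Parse a Newick string into a validated rooted tree."""
    import io

    return read_newick(io.StringIO(newick))


def read_newick(path) -> PhyloTree:
    """Read a single rooted tree from a Newick file.

    Every non-root edge must have a branch length; tip labels must be
    unique. Quoted labels are supported by the underlying parser.
    """
    try:
        tree = TreeNode.read(path, format="newick", convert_underscores=False)
    except (FileFormatError, UnrecognizedFormatError) as exc:
        raise ValidationError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.write(path, format="newick")


def validate_tips(tree: PhyloTree, taxa) -> dict:
    """Compare tree tips against a taxon label set (reporting only).

    Returns ``{"missing_from_tree": [...], "extra_tips": [...]}`` sorted for
    stable output; callers decide whether either is fatal.
    """
    tips = {t.name for t in tree.tips()}
    taxa = set(taxa)
    return {
        "missing_from_tree": sorted(taxa - tips),
        "extra_tips": sorted(tips - taxa),
    }


@dataclass(frozen=True)
class BranchTable:
    """Per-branch lengths and descendant-tip masks, restricted to ``taxa``.

    ``masks[b, i]`` is True when tip ``taxa[i]`` descends from branch ``b``.
    Only branches on a root path of some listed tip are included, so every
    row of ``masks`` has at least one True entry.
    """

    taxa: tuple
    lengths: np.ndarray  # (n_branches,)
    masks: np.ndarray  # (n_branches, n_taxa) bool

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def faith_pd(self, present: np.ndarray) -> float:
        """Sum of branch lengths on the union of root paths of present tips."""
        hit = self.masks @ present.astype(bool)
        return float(self.lengths[hit].sum())


def branch_table(tree: PhyloTree, taxa_order) -> BranchTable:
    """Build the branch table of ``tree`` restricted to ``taxa_order`` tips."""
    taxa = tuple(taxa_order)
    index = {t: i for i, t in enumerate(taxa)}
    if len(index) != len(taxa):
        raise ValidationError("duplicate labels in taxa_order")
    tip_names = {t.name for t in tree.tips()}
    unknown = [t for t in taxa if t not in tip_names]
    if unknown:
        raise ValidationError(f"labels not found among tree tips: {unknown}")

    n = len(taxa)
    lengths: list[float] = []
    masks: list[np.ndarray] = []
    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            mask = np.zeros(n, dtype=bool)
            if node.name in index:
                mask[index[node.name]] = True
        else:
            mask = np.zeros(n, dtype=bool)
            for child in node.children:
                mask |= node_mask.pop(id(child))
        node_mask[id(node)] = mask
        if node.parent is not None and mask.any():
            if node.length is None:
                raise ValidationError(
                    f"missing branch length on {node.name or 'internal node'}"
                )
            lengths.append(float(node.length))
            masks.append(mask)
    return BranchTable(
        taxa=taxa,
        lengths=np.asarray(lengths, dtype=float),
        masks=(
            np.asarray(masks, dtype=bool)
            if masks
            else np.zeros((0, n), dtype=bool)
        ),
    )
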