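"""Rooted species tree with a focal-species reference path.

Age stages are the branches on the path from the root to the focal species'
leaf.  Branch ``0`` is the edge above the root (characters present in every
species, i.e. older than the root divergence); branch ``K`` is the terminal
edge of the focal species.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy

__all__ = ["SpeciesTree"]


class SpeciesTree:
    """A rooted tree plus a focal leaf, exposing the root-to-focal path.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`.
    focal_species:
        Leaf label of the focal species; branch indices count from the root
        (0, oldest) down to this leaf (``n_branches``).
    """

    def __init__(self, tree: dendropy.Tree, focal_species: str):
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in species tree")
        if focal_species not in labels:
            raise ValueError(f"focal species {focal_species!r} is not a leaf of the tree")
        self._tree = tree
        self.focal_species = focal_species
        self.species = frozenset(labels)

        focal_node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == focal_species
        )
        path = []
        node = focal_node
        while node is not None:
            path.append(node)
            node = node.parent_node
        self._path = list(reversed(path))  # root .. focal leaf

        # cache leaf-label sets per node (postorder union)
        self._leafset: dict[dendropy.Node, frozenset[str]] = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                self._leafset[nd] = frozenset({nd.taxon.label})
            else:
                acc: frozenset[str] = frozenset()
                for ch in nd.child_nodes():
                    acc = acc | self._leafset[ch]
                self._leafset[nd] = acc

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path, focal_species: str) -> "SpeciesTree":
        """Build from a newick string or a path to a newick file."""
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("(")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                file=io.StringIO(text), schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"malformed newick tree: {exc}") from exc
        return cls(tree, focal_species)

    # -- path / branch geometry -------------------------------------------

    @property
    def n_branches(self) -> int:
        """Index of the terminal (youngest) branch, K."""
        return len(self._path) - 1

    def path_node(self, i: int):
        return self._path[i]

    def branch_label(self, i: int) -> str:
        if i == 0:
            return "stage_0_pre_root"
        if i == self.n_branches:
            return f"stage_{i}_{self.focal_species}"
        return f"stage_{i}"

    def clade_species(self, i: int) -> frozenset[str]:
        """Species descending from path node ``i`` (all species for i=0)."""
        return self._leafset[self._path[i]]

    # -- reconstruction helpers -------------------------------------------

    def branch_index_of_mrca(self, present: frozenset[str] | set[str]) -> int:
        """Deepest path node whose clade contains every ``present`` species.

        Requires the focal species in ``present`` (which guarantees the MRCA
        lies on the root-to-focal path).
        """
        if self.focal_species not in present:
            raise ValueError("focal species must be present")
        unknown = set(present) - self.species
        if unknown:
            raise ValueError(f"species not in tree: {sorted(unknown)}")
        present = frozenset(present)
        for i in range(len(self._path) - 1, -1, -1):
            if present <= self._leafset[self._path[i]]:
                return i
        raise AssertionError("unreachable: root clade contains all species")

    def min_losses(self, branch: int, present: set[str], absent: set[str]) -> int:
        """Minimal number of loss events below path node ``branch``.

        A loss event removes an entire subtree.  Subtrees containing only
        `unknown` leaves are free (assumed retained).
        """
        losses = 0
        stack = [self._path[branch]]
        while stack:
            nd = stack.pop()
            ls = self._leafset[nd]
            if ls & present:
                stack.extend(nd.child_nodes())
            elif ls & absent:
                losses += 1
            # else: all-unknown subtree, no event required
        return losses

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()
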