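"""Time-scaled ultrametric trees: reading, writing, node ages, induced subtrees.

A :class:`TimeTree` is a rooted, bifurcating, ultrametric phylogeny whose
branch lengths are in relative time units.  Tips sit at age 0 and the root at
``root_age``; the age of an internal node is the divergence time of the
species descending from it.  Trees are consumed as-is: if the input tree was
scaled so that the mean evolutionary rate is 1, ages are in substitution-scaled
relative time and any rates estimated from them are in inverse tree-time
units.  Nothing is rescaled silently.

Parsing and serialization (Newick and NEXUS) are delegated to dendropy; this
module adds age bookkeeping, validation, ordered divergence-time extraction
with deterministic tie-breaking, and induced subtrees for species subsets.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "TimeTree",
    "TreeError",
    "PolytomyError",
    "NotUltrametricError",
    "read_tree",
    "write_tree",
    "divergence_times",
    "induced_subtree",
]

#: relative tolerance on tip-to-root distances for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6

#: tie-breaking jitter for equal node ages, relative to the root age
TIE_EPS_REL = 1e-9

_POLYTOMY_RESOLUTION_SEED = 20150923


class TreeError(ValueError):
    """Malformed or unusable input tree."""


class PolytomyError(TreeError):
    """The tree contains a node with more than two children."""


class NotUltrametricError(TreeError):
    """Tip-to-root distances differ by more than the tolerance."""


class TimeTree:
    """Rooted bifurcating ultrametric tree with node ages in relative time.

    Parameters
    ----------
    tree
        A :class:`dendropy.Tree` with branch lengths on every non-root edge.
        The instance takes ownership of the dendropy tree and annotates every
        node with an ``age`` attribute.
    resolve_polytomies
        Polytomies are rejected by default (time trees from modern dating
        software are fully resolved).  When true, they are resolved
        deterministically with zero-length branches instead; the resulting
        tied ages are handled by the divergence-time tie-breaker.
    rtol
        Relative tolerance for the ultrametricity check.  Tip ages within
        ``rtol * root_age`` of zero are snapped to exactly zero.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        resolve_polytomies: bool = False,
        rtol: float = ULTRAMETRIC_RTOL,
    ) -> None:
        if not isinstance(tree, dendropy.Tree):
            raise TypeError("TimeTree wraps a dendropy.Tree")
        tree.suppress_unifurcations()

        for nd in tree.preorder_internal_node_iter():
            if len(nd.child_nodes()) > 2:
                if resolve_polytomies:
                    tree.resolve_polytomies(
                        rng=random.Random(_POLYTOMY_RESOLUTION_SEED)
                    )
                    for inner in tree.preorder_node_iter():
                        if inner is not tree.seed_node and inner.edge.length is None:
                            inner.edge.length = 0.0
                    break
                raise PolytomyError(
                    "tree contains a polytomy (node with "
                    f"{len(nd.child_nodes())} children); pass "
                    "resolve_polytomies=True to break it with zero-length "
                    "branches"
                )

        leaves = list(tree.leaf_node_iter())
        if len(leaves) < 2:
            raise TreeError("a time tree needs at least two tips")
        labels = []
        for lf in leaves:
            if lf.taxon is None or not lf.taxon.label:
                raise TreeError("every tip must carry a label")
            labels.append(lf.taxon.label)
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

        # root-to-node depths; the root's own edge (if any) is ignored
        tree.seed_node.depth = 0.0
        for nd in tree.preorder_node_iter():
            if nd is tree.seed_node:
                continue
            blen = nd.edge.length
            if blen is None:
                raise TreeError("every non-root edge must have a branch length")
            if blen < 0:
                raise TreeError(f"negative branch length {blen!r}")
            nd.depth = nd.parent_node.depth + blen

        root_age = max(lf.depth for lf in leaves)
        if root_age <= 0:
            raise TreeError("root age must be positive (all branch lengths zero?)")
        for lf in leaves:
            if abs(lf.depth - root_age) > rtol * root_age:
                raise NotUltrametricError(
                    f"tip {lf.taxon.label!r} is at depth {lf.depth:g} but the "
                    f"deepest tip is at {root_age:g}; tree is not ultrametric "
                    f"within relative tolerance {rtol:g}"
                )

        for nd in tree.preorder_node_iter():
            nd.age = 0.0 if nd.is_leaf() else root_age - nd.depth

        self._tree = tree
        self._root_age = float(root_age)
        self._tips = frozenset(labels)

    # -- basic accessors -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tips(self) -> frozenset[str]:
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def root_age(self) -> float:
        return self._root_age

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths (any edge above the root excluded)."""
        return float(
            sum(
                nd.edge.length
                for nd in self._tree.preorder_node_iter()
                if nd is not self._tree.seed_node
            )
        )

    def copy(self) -> "TimeTree":
        return TimeTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<TimeTree n_tips={self.n_tips} root_age={self.root_age:g}>"

    # -- I/O ---------------------------------------------------------------

    @staticmethod
    def _infer_schema(path: str | Path) -> str:
        suffix = Path(path).suffix.lower()
        return "nexus" if suffix in {".nex", ".nexus", ".nxs"} else "newick"

    @classmethod
    def read(cls, path: str | Path, schema: str | None = None, **kwargs) -> "TimeTree":
        """Read a tree from ``path`` (Newick or NEXUS, inferred from suffix)."""
        schema = schema or cls._infer_schema(path)
        try:
            tree = dendropy.Tree.get(path=str(path), schema=schema)
        except Exception as exc:  # dendropy raises many error types
            raise TreeError(f"could not read {str(path)!r} as {schema}: {exc}") from exc
        return cls(tree, **kwargs)

    @classmethod
    def from_string(cls, data: str, schema: str = "newick", **kwargs) -> "TimeTree":
        try:
            tree = dendropy.Tree.get(data=data, schema=schema)
        except Exception as exc:
            raise TreeError(f"could not parse tree string as {schema}: {exc}") from exc
        return cls(tree, **kwargs)

    def as_string(self, schema: str = "newick") -> str:
        kwargs = {"real_value_format_specifier": ".17g"}
        if schema == "newick":
            kwargs["suppress_rooting"] = True
        return self._tree.as_string(schema=schema, **kwargs)

    def write(self, path: str | Path, schema: str | None = None) -> None:
        schema = schema or self._infer_schema(path)
        Path(path).write_text(self.as_string(schema=schema))

    # -- divergence times --------------------------------------------------

    def divergence_times(self) -> np.ndarray:
        """Internal node ages, strictly descending.

        Returns the vector (t_1, ..., t_{s-1}) of the s - 1 internal node
        ages of an s-tip tree, oldest first, with t_1 equal to the root age.
        Exactly tied ages (common in files rounded to few digits, and a
        measure-zero event under the generating model) are broken by
        subtracting multiples of ``TIE_EPS_REL * root_age`` so the ordering
        is strict.
        """
        ages = sorted(
            (nd.age for nd in self._tree.preorder_internal_node_iter()),
            reverse=True,
        )
        out = np.asarray(ages, dtype=float)
        eps = TIE_EPS_REL * self._root_age
        for i in range(1, out.size):
            if out[i] >= out[i - 1]:
                out[i] = out[i - 1] - eps
        if out[-1] <= 0:
            raise TreeError("tie-breaking pushed a divergence time below zero")
        return out

    def mrca_age(self, labels: Iterable[str]) -> float:
        """Age of the most recent common ancestor of the given tips."""
        labels = list(labels)
        unknown = set(labels) - self._tips
        if unknown:
            raise TreeError(f"unknown tip labels: {sorted(unknown)}")
        return float(self._tree.mrca(taxon_labels=labels).age)

    # -- subsetting ----------------------------------------------------------

    def induced_subtree(self, members: Iterable[str]) -> "TimeTree":
        """Subtree spanned by ``members``, unary nodes suppressed.

        Each internal node age of the result equals the MRCA age of the
        corresponding tip pair in the parent tree (branch-length sums are
        preserved by the pruning).
        """
        members = frozenset(members)
        unknown = members - self._tips
        if unknown:
            raise TreeError(f"unknown species labels: {sorted(unknown)}")
        if len(members) < 2:
            raise TreeError("an induced subtree needs at least two members")
        sub = self._tree.extract_tree_with_taxa_labels(labels=members)
        return TimeTree(sub)

    def clades(self, include_root: bool = False):
        """Yield the tip-label set below each internal node."""
        for nd in self._tree.preorder_internal_node_iter():
            if nd is self._tree.seed_node and not include_root:
                continue
            yield frozenset(lf.taxon.label for lf in nd.leaf_iter())


# -- functional wrappers -----------------------------------------------------


def read_tree(path: str | Path, format: str | None = None, **kwargs) -> TimeTree:
    """Read a time-scaled tree (Newick or NEXUS)."""
    return TimeTree.read(path, schema=format, **kwargs)


def write_tree(tree: TimeTree, path: str | Path, format: str | None = None) -> None:
    """Write a time-scaled tree (Newick or NEXUS)."""
    tree.write(path, schema=format)


def divergence_times(tree: TimeTree) -> np.ndarray:
    """Ordered (strictly descending) internal node ages of ``tree``."""
    return tree.divergence_times()


def induced_subtree(tree: TimeTree, members: Iterable[str]) -> TimeTree:
    """Subtree of ``tree`` spanned by the species in ``members``."""
    return tree.induced_subtree(members)
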