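"""Rooted, branch-length phylogenies and phylogenetic-diversity primitives.

Trees are time-calibrated: branch lengths are in millions of years (MY), so
every quantity derived from them (PD, TBL, ED) is an amount of evolutionary
history. The central primitives are:

* total PD — the sum of all branch lengths of a tree;
* TBL — a species' terminal (pendant) branch length, its unshared PD;
* subtree PD — branch lengths spanned by a species subset (root path
  included), with the single-species convention that one species represents
  only its own terminal branch;
* fair-proportion ED — each branch's length split equally among its
  descendant tips;
* pruning — removal of species with additive merging of the emptied
  internal edges, used by extinction scenarios;
* rarefaction — random tip subsampling to equalise taxonomic completeness.

Newick/NEXUS parsing is delegated to dendropy; the in-memory representation
is a minimal immutable parent-array structure tailored to PD accounting.
An explicit length on the root (e.g. ``...):5;``) is recorded as
``root_edge_length`` but excluded from total PD and every metric: all
accounting is on the ingroup tree.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "Branch",
    "TreeDistribution",
    "PhylogenyError",
    "parse_newick",
    "total_pd",
    "terminal_branch_lengths",
    "subtree_pd",
    "fair_proportion",
    "prune",
    "rarefy_tree",
]


class PhylogenyError(ValueError):
    """Structurally invalid tree input (bad Newick, duplicate tips, ...)."""


@dataclass(frozen=True)
class Branch:
    """One edge of a tree: its length (MY) and the tips descending from it."""

    branch_id: str
    length: float
    tips: frozenset[str]


class Phylogeny:
    """A rooted tree with non-negative branch lengths and unique tip labels.

    Nodes are integer ids; node 0 is the root and ids follow preorder, so
    identical inputs always produce identical internal numbering (branch ids
    are therefore stable across runs). Unifurcations (including at the root)
    and polytomies are permitted; zero-length edges are permitted and simply
    contribute nothing.
    """

    def __init__(
        self,
        parent: Mapping[int, int],
        length: Mapping[int, float],
        tip_label: Mapping[int, str],
        root: int = 0,
        root_edge_length: float | None = None,
    ):
        self.root = root
        self._parent = dict(parent)
        self._length = {n: float(v) for n, v in length.items()}
        self._tip_label = dict(tip_label)
        self.root_edge_length = root_edge_length
        self._children: dict[int, list[int]] = {root: []}
        for child, par in self._parent.items():
            self._children.setdefault(child, [])
            self._children.setdefault(par, []).append(child)
        for kids in self._children.values():
            kids.sort()
        self._validate()
        self._tip_of_label = {lab: n for n, lab in self._tip_label.items()}

    # -- construction ----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        parent: dict[int, int] = {}
        length: dict[int, float] = {}
        tip_label: dict[int, str] = {}
        ids: dict[int, int] = {}
        for i, nd in enumerate(tree.preorder_node_iter()):
            ids[id(nd)] = i
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise PhylogenyError(
                        "missing branch length on an edge; all edges must "
                        "carry lengths in MY"
                    )
                parent[i] = ids[id(nd.parent_node)]
                length[i] = float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or not nd.taxon.label:
                    raise PhylogenyError("unlabelled tip")
                tip_label[i] = nd.taxon.label
        root_edge = tree.seed_node.edge.length
        return cls(
            parent,
            length,
            tip_label,
            root=0,
            root_edge_length=None if root_edge is None else float(root_edge),
        )

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        result = parse_newick(text)
        if isinstance(result, TreeDistribution):
            raise PhylogenyError("input contains more than one tree")
        return result

    def _validate(self) -> None:
        if self.root in self._parent:
            raise PhylogenyError("root must not have a parent")
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n in seen:
                raise PhylogenyError("cycle detected")
            seen.add(n)
            stack.extend(self._children.get(n, []))
        if seen != set(self._children):
            raise PhylogenyError("disconnected nodes: not a single rooted tree")
        for n, v in self._length.items():
            if not math.isfinite(v) or v < 0:
                raise PhylogenyError(f"edge above node {n} has invalid length {v}")
        labels = list(self._tip_label.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        for n in self._children:
            if not self._children[n] and n not in self._tip_label:
                raise PhylogenyError(f"leaf node {n} has no tip label")

    # -- basic structure -------------------------------------------------

    @property
    def tips(self) -> frozenset[str]:
        return frozenset(self._tip_label.values())

    @property
    def n_tips(self) -> int:
        return len(self._tip_label)

    def children(self, node: int) -> tuple[int, ...]:
        return tuple(self._children[node])

    def tip_nodes(self) -> dict[str, int]:
        """Map tip label -> node id."""
        return dict(self._tip_of_label)

    def edge_lengths(self) -> dict[int, float]:
        """Length of the edge above each non-root node."""
        return dict(self._length)

    def _preorder(self) -> Iterable[int]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(self._children[n]))

    def _postorder(self) -> list[int]:
        order = list(self._preorder())
        order.reverse()
        return order

    def _descendant_tip_sets(self) -> dict[int, frozenset[str]]:
        tipsets: dict[int, frozenset[str]] = {}
        for n in self._postorder():
            if n in self._tip_label:
                tipsets[n] = frozenset({self._tip_label[n]})
            else:
                acc: set[str] = set()
                for c in self._children[n]:
                    acc |= tipsets[c]
                tipsets[n] = frozenset(acc)
        return tipsets

    # -- PD primitives ---------------------------------------------------

    def total_pd(self) -> float:
        """Sum of all branch lengths (MY); the root stem is excluded."""
        return float(sum(self._length.values()))

    def terminal_branch_lengths(self) -> dict[str, float]:
        """Pendant edge length (TBL, MY) per tip.

        Computed on this tree as given — call this on the full tree before
        any intersection with spatial data, so that TBLs reflect the
        complete phylogeny.
        """
        return {lab: self._length[n] for n, lab in self._tip_label.items()}

    def subtree_pd(self, species: Iterable[str]) -> float:
        """PD spanned by a species set.

        For two or more species: the summed length of every edge on the
        union of root-to-tip paths (the root path is included). For exactly
        one species the value is that species' terminal branch length only —
        a deliberate convention for single-occupant grid cells, discontinuous
        with the >=2 rule.
        """
        sp = set(species)
        if not sp:
            raise ValueError("species set is empty")
        unknown = sp - self.tips
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        if len(sp) == 1:
            return float(self._length[self._tip_of_label[next(iter(sp))]])
        marked: set[int] = set()
        for lab in sp:
            n = self._tip_of_label[lab]
            while n != self.root and n not in marked:
                marked.add(n)
                n = self._parent[n]
        return float(sum(self._length[n] for n in marked))

    def fair_proportion(self) -> dict[str, float]:
        """Evolutionary distinctiveness: each edge split equally among its
        descendant tips. Sums to total PD."""
        counts: dict[int, int] = {}
        for n in self._postorder():
            if n in self._tip_label:
                counts[n] = 1
            else:
                counts[n] = sum(counts[c] for c in self._children[n])
        carry: dict[int, float] = {self.root: 0.0}
        ed: dict[str, float] = {}
        for n in self._preorder():
            if n != self.root:
                carry[n] = carry[self._parent[n]] + self._length[n] / counts[n]
            if n in self._tip_label:
                ed[self._tip_label[n]] = carry[n]
        return ed

    def branch_table(self) -> list[Branch]:
        """All edges with their descendant tip sets; lengths sum to total PD."""
        tipsets = self._descendant_tip_sets()
        return [
            Branch(branch_id=f"b{n}", length=self._length[n], tips=tipsets[n])
            for n in sorted(self._length)
        ]

    # -- pruning ---------------------------------------------------------

    def prune(self, drop: Iterable[str]) -> "Phylogeny":
        """Remove tips, merging emptied internal edges additively.

        The original root is kept even if it ends up unifurcating, so the
        pruned tree's total PD equals the length of the retained-tip
        spanning subtree measured from the root; pruning to a single
        survivor leaves that species on one pendant edge equal to its whole
        root-to-tip path.
        """
        drop_set = set(drop)
        unknown = drop_set - self.tips
        if unknown:
            raise KeyError(f"species not in tree: {sorted(unknown)}")
        keep = self.tips - drop_set
        if not keep:
            raise ValueError("cannot prune away every tip")
        marked: set[int] = {self.root}
        for lab in keep:
            n = self._tip_of_label[lab]
            while n not in marked:
                marked.add(n)
                n = self._parent[n]
        # restrict children to marked, then splice unifurcating non-root nodes
        new_parent: dict[int, int] = {}
        new_length: dict[int, float] = {}
        new_tip: dict[int, str] = {}
        next_id = 0

        def walk(old: int, new_par: int | None, carried: float) -> None:
            nonlocal next_id
            kids = [c for c in self._children[old] if c in marked]
            is_tip = old in self._tip_label
            if old != self.root and len(kids) == 1 and not is_tip:
                walk(kids[0], new_par, carried + self._length[kids[0]])
                return
            me = next_id
            next_id += 1
            if new_par is not None:
                new_parent[me] = new_par
                new_length[me] = carried
            if is_tip:
                new_tip[me] = self._tip_label[old]
            for c in kids:
                walk(c, me, self._length[c])

        walk(self.root, None, 0.0)
        return Phylogeny(
            new_parent, new_length, new_tip, root=0,
            root_edge_length=self.root_edge_length,
        )

    # -- serialisation ---------------------------------------------------

    def to_newick(self) -> str:
        def fmt(n: int) -> str:
            if n in self._tip_label:
                core = _quote_label(self._tip_label[n])
            else:
                core = "(" + ",".join(fmt(c) for c in self._children[n]) + ")"
            if n == self.root:
                if self.root_edge_length is not None:
                    return f"{core}:{self.root_edge_length:.12g}"
                return core
            return f"{core}:{self._length[n]:.12g}"

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny {self.n_tips} tips, PD={self.total_pd():.4g} MY>"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ():;,[]'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


class TreeDistribution(list):
    """An ordered collection of trees sharing a taxon namespace.

    Typically a random sample from a posterior distribution of phylogenies;
    the index identifies the tree. Tip sets may differ between trees.
    """

    def __init__(self, trees: Iterable[Phylogeny]):
        super().__init__(trees)
        if not self:
            raise PhylogenyError("a TreeDistribution must contain >= 1 tree")


def parse_newick(source: str | Path) -> Phylogeny | TreeDistribution:
    """Parse a Newick string, a Newick/NEXUS file, or a multi-tree file.

    Every edge must carry a branch length (in MY). A single tree parses to a
    :class:`Phylogeny`; multiple trees (one Newick per line, or a NEXUS
    trees block) parse to a :class:`TreeDistribution`.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and ";" not in str(source) and Path(str(source)).is_file()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tree_list = dendropy.TreeList.get(
            file=io.StringIO(text), schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises many parse-error subclasses
        raise PhylogenyError(f"could not parse tree input: {exc}") from exc
    if len(tree_list) == 0:
        raise PhylogenyError("no trees found in input")
    trees = [Phylogeny.from_dendropy(t) for t in tree_list]
    if len(trees) == 1:
        return trees[0]
    return TreeDistribution(trees)


# ---------------------------------------------------------------------------
# functional facade (mirrors the method API)


def total_pd(tree: Phylogeny) -> float:
    return tree.total_pd()


def terminal_branch_lengths(tree: Phylogeny) -> dict[str, float]:
    return tree.terminal_branch_lengths()


def subtree_pd(tree: Phylogeny, species: Iterable[str]) -> float:
    return tree.subtree_pd(species)


def fair_proportion(tree: Phylogeny) -> dict[str, float]:
    return tree.fair_proportion()


def prune(tree: Phylogeny, drop: Iterable[str]) -> Phylogeny:
    return tree.prune(drop)


def rarefy_tree(
    tree: Phylogeny, target_fraction: float, reps: int, seed: int
) -> TreeDistribution:
    """Random tip subsampling to a fixed completeness fraction.

    Each replicate retains ``round(target_fraction * n_tips)`` tips drawn
    uniformly without replacement; used to put clades with different
    taxonomic completeness on an equal footing.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_keep = int(round(target_fraction * tree.n_tips))
    n_keep = max(n_keep, 1)
    rng = np.random.Generator(np.random.PCG64(seed))
    labels = sorted(tree.tips)
    out = []
    for _ in range(reps):
        if n_keep == tree.n_tips:
            out.append(tree)
            continue
        keep = set(rng.choice(labels, size=n_keep, replace=False))
        out.append(tree.prune(tree.tips - keep))
    return TreeDistribution(out)
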