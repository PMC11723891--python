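"""Phylogeny container, Brownian-motion covariance, Pagel's lambda,
and Felsenstein's independent contrasts.

The tree is a rooted node structure with branch lengths.  Under Brownian
motion the expected covariance between two tips is the depth of their
most recent common ancestor, giving the phylogenetic variance-covariance
matrix V used by generalized least squares.  Pagel's lambda rescales the
off-diagonal of V, interpolating between a star phylogeny (lambda = 0,
no signal) and the full Brownian expectation (lambda = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import dendropy
import numpy as np


class NewickError(ValueError):
    """Malformed or invalid Newick input."""


class ContrastError(ValueError):
    """Independent contrasts cannot be computed on this tree/data."""


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch length to parent; 0 at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree with branch lengths and uniquely named tips."""

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        tips = self.tip_names
        if len(tips) < 2:
            raise NewickError("tree must have at least 2 tips")
        if len(set(tips)) != len(tips):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip names: {dupes}")
        for node in self.postorder():
            if node is not self.root:
                if node.length is None or not np.isfinite(node.length):
                    raise NewickError(
                        f"missing or non-finite branch length above "
                        f"{node.name or 'an internal node'}"
                    )
                if node.length < 0:
                    raise NewickError(f"negative branch length at {node.name}")
            if not node.is_leaf and len(node.children) < 2:
                raise NewickError("internal nodes must have >= 2 children")

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    @property
    def tip_names(self) -> list[str]:
        return [nd.name for nd in self.postorder() if nd.is_leaf]

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def is_bifurcating(self) -> bool:
        return all(
            len(nd.children) == 2 for nd in self.postorder() if not nd.is_leaf
        )

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}

        def walk(nd: Node, d: float) -> None:
            d += nd.length if nd is not self.root else 0.0
            if nd.is_leaf:
                depths[nd.name] = d
            for ch in nd.children:
                walk(ch, d)

        walk(self.root, 0.0)
        return depths

    def rescale_depth(self, target: float = 1.0) -> "Phylogeny":
        """Return a copy with all branch lengths scaled so the maximum
        root-to-tip depth equals ``target``."""
        depth = max(self.tip_depths().values())
        factor = target / depth

        def copy(nd: Node) -> Node:
            return Node(
                nd.name, nd.length * factor, [copy(c) for c in nd.children]
            )

        new_root = copy(self.root)
        new_root.length = 0.0
        return Phylogeny(new_root)


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        length = dnode.edge.length
        node = Node(name=name, length=0.0 if length is None else float(length))
        node.children = [convert(c) for c in dnode.child_nodes()]
        if node.is_leaf and name is None:
            raise NewickError("unnamed tip in tree")
        if not node.is_leaf and length is None and dnode.parent_node is not None:
            raise NewickError("internal branch without length")
        if node.is_leaf and dnode.edge.length is None:
            raise NewickError(f"tip {name!r} has no branch length")
        return node

    root = convert(dtree.seed_node)
    root.length = 0.0
    return Phylogeny(root)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required) into a Phylogeny."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy reports the offending position
        raise NewickError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: Phylogeny) -> str:
    """Serialize with full float precision; round-trips through parse_newick."""

    def fmt(nd: Node) -> str:
        if nd.is_leaf:
            return f"{nd.name}:{nd.length!r}"
        inner = ",".join(fmt(c) for c in nd.children)
        if nd is tree.root:
            return f"({inner})"
        return f"({inner}):{nd.length!r}"

    return fmt(tree.root) + ";"


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance: V[i,j] = depth of MRCA(tip i, tip j)."""

    taxa: tuple[str, ...]
    V: np.ndarray

    def reorder(self, taxa: list[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(tuple(taxa), self.V[np.ix_(idx, idx)])


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    taxa = tree.tip_names
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    V = np.zeros((n, n))

    def walk(nd: Node, depth: float) -> list[int]:
        depth += nd.length if nd is not tree.root else 0.0
        if nd.is_leaf:
            i = index[nd.name]
            V[i, i] = depth
            return [i]
        groups = [walk(ch, depth) for ch in nd.children]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i in groups[a]:
                    for j in groups[b]:
                        V[i, j] = V[j, i] = depth
        return [i for g in groups for i in g]

    walk(tree.root, 0.0)
    return PhyloCovariance(tuple(taxa), V)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda, leaving variances fixed."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return PhyloCovariance(cov.taxa, V)


@dataclass(frozen=True)
class ContrastSet:
    """Standardized independent contrasts, one per internal node."""

    values: np.ndarray
    node_ids: tuple[int, ...]


def independent_contrasts(
    tree: Phylogeny, trait: dict[str, float] | "np.ndarray | list"
) -> ContrastSet:
    """Felsenstein's pruning algorithm for standardized contrasts.

    At each internal node of a bifurcating tree the contrast is
    (x_i - x_j) / sqrt(b_i + b_j); the node's ancestral value is the
    branch-length-weighted mean of its daughters and its parent branch is
    extended by b_i * b_j / (b_i + b_j).
    """
    taxa = tree.tip_names
    if not isinstance(trait, dict):
        arr = np.asarray(trait, dtype=float)
        if arr.shape != (len(taxa),):
            raise ContrastError(
                f"trait vector length {arr.shape} != {len(taxa)} tips"
            )
        trait = dict(zip(taxa, arr))
    missing = [t for t in taxa if t not in trait or not np.isfinite(trait[t])]
    if missing:
        raise ContrastError(f"missing or non-finite trait values for {missing}")
    if not tree.is_bifurcating():
        raise ContrastError(
            "tree has polytomies; resolve them before computing contrasts"
        )

    contrasts: list[float] = []
    node_ids: list[int] = []
    counter = {"id": 0}

    def prune(nd: Node) -> tuple[float, float]:
        """Return (value, effective branch length) for the subtree at nd."""
        blen = nd.length if nd is not tree.root else 0.0
        if nd.is_leaf:
            return trait[nd.name], blen
        (x1, b1), (x2, b2) = (prune(c) for c in nd.children)
        if b1 + b2 <= 0:
            raise ContrastError(
                "zero-length cherry: contrast variance b_i + b_j is zero"
            )
        contrasts.append((x1 - x2) / np.sqrt(b1 + b2))
        node_ids.append(counter["id"])
        counter["id"] += 1
        anc = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2) if b1 > 0 and b2 > 0 else (
            x1 if b1 == 0 else x2
        )
        return anc, blen + b1 * b2 / (b1 + b2)

    prune(tree.root)
    return ContrastSet(np.asarray(contrasts), tuple(node_ids))


def match_taxa(tree: Phylogeny, table_taxa: list[str]) -> list[str]:
    """Check tree tips and table taxa agree (after whitespace trimming).

    Returns the tree's tip order; raises listing both one-sided
    differences otherwise.
    """
    tips = [t.strip() for t in tree.tip_names]
    tab = [t.strip() for t in table_taxa]
    only_tree = sorted(set(tips) - set(tab))
    only_table = sorted(set(tab) - set(tips))
    if only_tree or only_table:
        raise ValueError(
            f"taxon mismatch: in tree only {only_tree}; in table only {only_table}"
        )
    return tips
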