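"""Neighbor-joining trees, bootstrap supports and Newick I/O.

Trees are unrooted and stored with an arbitrary trifurcating "root" node,
the usual representation for unrooted binary trees.  Internal edges are
identified with the bipartition (split) of the leaf set they induce;
splits are canonicalised as the frozen side NOT containing the
lexicographically smallest leaf id, so the same split compares equal no
matter how the tree is traversed or rooted.

Neighbor joining follows Saitou & Nei with the Studier–Keppler criterion
Q(i,j) = (m-2) d(i,j) - Σ_k d(i,k) - Σ_k d(j,k); on additive matrices it
recovers the generating tree exactly.  Bootstrap supports come from
column resampling: each replicate rebuilds the K2P matrix and NJ tree,
and each internal edge of the ORIGINAL tree is annotated with the
percentage of replicates containing its split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distances import (
    DistanceMatrix,
    SaturationError,
    UndefinedDistanceError,
    bootstrap_pair_distances,
    distance_matrix,
    pair_class_matrix,
)
from .io import Alignment, InputError


class NewickError(ValueError):
    """Malformed Newick text."""


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> dict[frozenset, Node]:
        """Canonical split → child node below the corresponding internal edge.

        Only internal edges (both sides with ≥2 leaves) are returned; on an
        unrooted binary tree with n leaves there are n−3 of them.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out[side] = node
            return below

        walk(self.root)
        return out

    def is_monophyletic(self, leaf_subset) -> bool:
        """True iff some edge of the unrooted tree splits off exactly this set."""
        subset = frozenset(leaf_subset)
        all_leaves = frozenset(self.leaf_names())
        unknown = subset - all_leaves
        if unknown:
            raise InputError(f"unknown leaves: {sorted(unknown)}")
        if not subset or subset == all_leaves:
            raise InputError("subset must be a non-empty proper subset of leaves")
        if len(subset) == 1 or len(subset) == len(all_leaves) - 1:
            return True
        anchor = min(all_leaves)
        canonical = subset if anchor not in subset else all_leaves - subset
        return canonical in self.bipartitions()

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            if top or node.length is None:
                return body
            return f"{body}:{node.length:.{decimals}f}"

        return fmt(self.root, True) + ";"


def write_newick(tree: Tree, path: str | Path, decimals: int = 6) -> None:
    Path(path).write_text(tree.to_newick(decimals=decimals) + "\n")


def read_newick(path_or_text: str | Path) -> Tree:
    """Parse a Newick string or file (supports as internal-node labels)."""
    text = str(path_or_text)
    if "(" not in text and Path(text).exists():
        text = Path(text).read_text()
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick text must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r} at {pos}")
        # label (leaf name, or internal support label)
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError as exc:
                raise NewickError(f"bad branch length {s[start:pos]!r}") from exc
        return node

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters after position {pos}")
    if root.is_leaf and root.name is None:
        raise NewickError("empty tree")
    return Tree(root=root)


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken toward the pair whose members were
    created earliest (input order first, then join order), making the
    result deterministic.  Negative branch-length estimates are clamped
    to zero without transferring the deficit elsewhere.
    """
    n = matrix.n
    if n < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    # active nodes carry (creation_order, Node); distances in a dict-of-dict
    nodes: list[Node] = [Node(name=i) for i in matrix.ids]
    creation = {id(node): k for k, node in enumerate(nodes)}
    next_creation = n
    active = list(nodes)
    D: dict[int, dict[int, float]] = {
        id(a): {id(b): float(matrix.d[i, j]) for j, b in enumerate(nodes) if j != i}
        for i, a in enumerate(nodes)
    }

    def clamp(x: float) -> float:
        return x if x > 0.0 else 0.0

    while len(active) > 3:
        m = len(active)
        r = {id(a): sum(D[id(a)].values()) for a in active}
        best = None
        best_key = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                a, b = active[ai], active[bj]
                q = (m - 2) * D[id(a)][id(b)] - r[id(a)] - r[id(b)]
                ca, cb = creation[id(a)], creation[id(b)]
                key = (min(ca, cb), max(ca, cb))
                if best is None or q < best - 1e-12 or (abs(q - best) <= 1e-12 and key < best_key):
                    best, best_key, pair = q, key, (a, b)
        a, b = pair
        dab = D[id(a)][id(b)]
        ba = 0.5 * dab + (r[id(a)] - r[id(b)]) / (2.0 * (m - 2))
        bb = dab - ba
        a.length = clamp(ba)
        b.length = clamp(bb)
        new = Node(children=[a, b])
        creation[id(new)] = next_creation
        next_creation += 1
        D[id(new)] = {}
        for c in active:
            if c is a or c is b:
                continue
            duc = 0.5 * (D[id(a)][id(c)] + D[id(b)][id(c)] - dab)
            D[id(new)][id(c)] = duc
            D[id(c)][id(new)] = duc
            del D[id(c)][id(a)], D[id(c)][id(b)]
        del D[id(a)], D[id(b)]
        active = [c for c in active if c is not a and c is not b] + [new]

    # final trifurcation: closed-form branch from each remaining node
    x, y, z = active
    dxy = D[id(x)][id(y)]
    dxz = D[id(x)][id(z)]
    dyz = D[id(y)][id(z)]
    x.length = clamp(0.5 * (dxy + dxz - dyz))
    y.length = clamp(0.5 * (dxy + dyz - dxz))
    z.length = clamp(0.5 * (dxz + dyz - dxy))
    return Tree(root=Node(children=[x, y, z]))


def path_lengths(tree: Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path length sums (additivity oracle helper)."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: Node) -> dict[str, float]:
        if node.is_leaf:
            below = {node.name: 0.0}
        else:
            below = {}
            merged: list[dict[str, float]] = []
            for child in node.children:
                sub = {k: v + (child.length or 0.0) for k, v in walk(child).items()}
                for prev in merged:
                    for la, da in prev.items():
                        for lb, db in sub.items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
                merged.append(sub)
                below.update(sub)
        return below

    walk(tree.root)
    return dists


def bootstrap_support(
    alignment: Alignment,
    B: int = 1000,
    seed: int = 0,
    max_undefined_frac: float = 0.1,
) -> tuple[Tree, int]:
    """NJ tree with bootstrap supports on its internal edges.

    Each of the B replicates resamples alignment columns with replacement,
    rebuilds the K2P matrix and NJ tree, and contributes its splits.
    Replicates whose resampled matrix is undefined (saturation, or no
    usable columns for some pair) are redrawn and counted; more than
    ``max_undefined_frac * B`` redraws raises :class:`SaturationError`.

    Returns the annotated tree and the number of redrawn replicates.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    if alignment.n < 3:
        raise InputError("need at least 3 sequences")
    matrix = distance_matrix(alignment)
    tree = neighbor_joining(matrix)
    target_splits = tree.bipartitions()
    counts = {split: 0 for split in target_splits}

    codes = alignment.codes()
    n, length = codes.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    class_matrix = pair_class_matrix(codes, pairs)
    p = np.full(length, 1.0 / length)
    rng = np.random.default_rng(seed)

    redrawn = 0
    done = 0
    while done < B:
        weights = rng.multinomial(length, p)
        try:
            dvec = bootstrap_pair_distances(class_matrix, weights)
        except (UndefinedDistanceError, SaturationError):
            redrawn += 1
            if redrawn > max_undefined_frac * B:
                raise SaturationError(
                    f"more than {max_undefined_frac:.0%} of bootstrap replicates undefined"
                )
            continue
        d = np.zeros((n, n))
        for (i, j), val in zip(pairs, dvec):
            d[i, j] = d[j, i] = val
        rep_tree = neighbor_joining(
            DistanceMatrix(ids=list(alignment.ids), d=d, L=np.full((n, n), length))
        )
        rep_splits = rep_tree.bipartitions()
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
        done += 1

    for split, node in target_splits.items():
        node.support = 100.0 * counts[split] / B
    return tree, redrawn


def root_at(tree: Tree, leaf_name: str) -> Tree:
    """Re-draw the unrooted tree with ``leaf_name`` as an outgroup.

    Purely a display operation: the outgroup's pendant edge is split in
    half by a new degree-2 root.  Topology and total path lengths are
    preserved.
    """
    names = set(tree.leaf_names())
    if leaf_name not in names:
        raise InputError(f"unknown leaf {leaf_name!r}")

    # build parent map from a deep copy
    import copy

    t = copy.deepcopy(tree)
    parent: dict[int, Node] = {}

    def index(node: Node) -> None:
        for c in node.children:
            parent[id(c)] = node
            index(c)

    index(t.root)
    out = next(n for n in t.leaves() if n.name == leaf_name)
    # reverse edges from the outgroup's parent up to the old root
    path = [out]
    node = out
    while id(node) in parent:
        node = parent[id(node)]
        path.append(node)
    old_lengths = [n.length for n in path]
    for child, par in zip(path[:-1], path[1:]):
        par.children.remove(child)
    for k, (child, par) in enumerate(zip(path[:-1], path[1:])):
        # hang the parent below the child; the reversed edge keeps its length
        child.children.append(par)
        par.length = old_lengths[k]
    # out is now top: split its single (pendant) edge with a degree-2 root
    inner = out.children[0]
    out.children = []
    half = (inner.length or 0.0) / 2.0
    out.length = inner.length = half
    return Tree(root=Node(children=[out, inner]))
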