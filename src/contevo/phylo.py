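"""Distance matrices and Neighbor-Joining trees from binary mutation profiles.

The NJ implementation follows Saitou & Nei with the standard Q-criterion.
Conventions pinned here so runs are reproducible: ties in Q are broken by
lexicographic taxon-id order (a node's id is its smallest leaf name);
negative branch lengths are clamped to zero with the deficit transferred to
the sister branch (raw values are retained for diagnostics); the tree is
left unrooted, represented with a trifurcating root node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .mutations import PresenceAbsenceMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray
    metric: str = "euclidean-binary"

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def euclidean_distance(pa: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between binary rows:
    d(i, j) = sqrt(#regions where the rows differ)."""
    ids = tuple(pa.populations)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate population ids")
    if len(ids) < 2:
        raise ValueError("need >=2 populations")
    values = squareform(pdist(pa.table.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(ids=ids, values=values)


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes hold child edges as
    (child, length, raw_length) triples."""

    name: str | None = None
    children: list[tuple["Node", float, float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def sort_key(self) -> str:
        return self.name if self.is_leaf else min(self.leaf_names())


@dataclass(frozen=True)
class Tree:
    root: Node

    def leaf_names(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def cophenetic(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (uses clamped branch lengths)."""
        leaves = self.leaf_names()
        idx = {n: i for i, n in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def below(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            groups = []
            for child, length, _ in node.children:
                sub = below(child)
                groups.append({k: v + length for k, v in sub.items()})
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for na, da in groups[a].items():
                        for nb, db in groups[b].items():
                            d[idx[na], idx[nb]] = d[idx[nb], idx[na]] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        below(self.root)
        return DistanceMatrix(ids=tuple(leaves), values=d, metric="cophenetic")


def two_taxon_tree(dm: DistanceMatrix) -> Tree:
    """Trivial single-edge tree for exactly two taxa."""
    if len(dm.ids) != 2:
        raise ValueError("two_taxon_tree needs exactly 2 taxa")
    half = dm.values[0, 1] / 2.0
    root = Node(children=[
        (Node(name=dm.ids[0]), half, half),
        (Node(name=dm.ids[1]), half, half),
    ])
    return Tree(root=root)


def _clamp(length: float) -> tuple[float, float]:
    """(clamped, deficit): deficit is the amount removed (<= 0)."""
    if length < 0:
        return 0.0, length
    return length, 0.0


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei Neighbor-Joining.

    Joins the Q-minimizing pair until three nodes remain, then resolves the
    final star with the three-point formulas.  Deterministic: Q ties are
    broken by the lexicographically smallest (id, id) pair, where a node's id
    is its smallest leaf name.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor_joining needs >=3 taxa (see two_taxon_tree)")
    nodes: list[Node] = [Node(name=i) for i in dm.ids]
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-10 * max(1.0, abs(qmin)):
                    key = tuple(sorted((nodes[i].sort_key(), nodes[j].sort_key())))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best

        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li_c, defi = _clamp(li)
        lj_c, defj = _clamp(lj)
        # transfer the clamped deficit to the sister branch
        li_c = max(li_c + defj, 0.0)
        lj_c = max(lj_c + defi, 0.0)
        parent = Node(children=[
            (nodes[i], li_c, li),
            (nodes[j], lj_c, lj),
        ])

        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_next = np.zeros((len(keep) + 1, len(keep) + 1))
        d_next[: len(keep), : len(keep)] = d[np.ix_(keep, keep)]
        d_next[-1, : len(keep)] = d_next[: len(keep), -1] = new_d[keep]
        d = d_next
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final 3-star with the three-point formulas
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    raw = [la, lb, lc]
    clamped = [max(x, 0.0) for x in raw]
    root = Node(children=[
        (a, clamped[0], raw[0]),
        (b, clamped[1], raw[1]),
        (c, clamped[2], raw[2]),
    ])
    return Tree(root=root)


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}/,;:'\"]")


def _quote(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize to Newick with branch lengths.

    Child ordering is deterministic (lexicographic by smallest leaf name);
    names containing `/` (intergenic-style region ids) or other Newick
    metacharacters are single-quoted.
    """

    def render(node: Node) -> str:
        if node.is_leaf:
            return _quote(node.name)
        parts = [
            f"{render(child)}:{length:.{precision}f}"
            for child, length, _ in sorted(
                node.children, key=lambda e: e[0].sort_key()
            )
        ]
        return "(" + ",".join(parts) + ")"

    return render(tree.root) + ";"


def write_distance_csv(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance matrix for interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for name, row in zip(dm.ids, dm.values):
            safe = name.replace(" ", "_")[:10].ljust(10)
            fh.write(safe + " " + " ".join(f"{x:.6f}" for x in row) + "\n")
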