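"""Dendrite morphology: tree geometry and along-dendrite (geodesic) distances.

A dendrite is represented as a rooted geometric tree.  Every distance in the
package is a geodesic measured along the tree in micrometres, never a
straight-line (Euclidean) distance: two synapses on sibling branches can be
close in space but far apart along the dendrite, and it is the along-dendrite
distance that matters for local synaptic interactions.

Positions on the tree are edge-local: an edge is identified by its child node
(SWC convention) and a position is an offset in µm from the edge's parent end.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TreePosition",
    "DendriteTree",
    "path_distance",
    "pairwise_distances",
    "neighbors_within",
    "read_swc",
    "write_swc",
    "read_synapse_positions",
    "write_synapse_positions",
]


@dataclass(frozen=True, order=True)
class TreePosition:
    """A point on a dendrite: edge id (child-node id) and offset from the
    parent end of that edge, in µm.  Ties at branch points belong to the
    parent edge (offset == edge length)."""

    edge: int
    offset: float

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"negative offset {self.offset}")


class DendriteTree:
    """Rooted geometric tree with positive edge lengths (µm).

    Parameters
    ----------
    nodes : mapping of node id -> (x, y, z) position in µm
    edges : iterable of (parent, child) pairs
    root : root node id
    lengths : optional mapping child -> edge length; if omitted, lengths are
        the 3D Euclidean distances between the node positions.
    """

    def __init__(self, nodes, edges, root, lengths=None):
        self.nodes = {int(k): tuple(float(c) for c in v) for k, v in nodes.items()}
        self.root = int(root)
        self.parent: dict[int, int] = {}
        self.children: dict[int, list[int]] = {n: [] for n in self.nodes}
        self.edge_length: dict[int, float] = {}
        for p, c in edges:
            p, c = int(p), int(c)
            if c in self.parent:
                raise ValueError(f"node {c} has more than one parent")
            self.parent[c] = p
            self.children[p].append(c)
            if lengths is not None and c in lengths:
                length = float(lengths[c])
            else:
                length = float(
                    np.linalg.norm(np.subtract(self.nodes[p], self.nodes[c]))
                )
            if length <= 0:
                raise ValueError(f"edge {p}->{c} has non-positive length {length}")
            self.edge_length[c] = length
        self._validate()
        self._depth: dict[int, float] | None = None
        self._node_dist: dict[int, dict[int, float]] | None = None
        self._desc: dict[int, frozenset[int]] | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def line(cls, length: float) -> "DendriteTree":
        """Degenerate unbranched dendrite: a single edge of the given arc
        length, root at node 1, tip at node 2.  Positions live on edge 2."""
        if length <= 0:
            raise ValueError("length must be positive")
        return cls(
            nodes={1: (0.0, 0.0, 0.0), 2: (length, 0.0, 0.0)},
            edges=[(1, 2)],
            root=1,
        )

    def _validate(self) -> None:
        if self.root not in self.nodes:
            raise ValueError("root not among nodes")
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        # connectivity + acyclicity: every non-root node must reach the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur != self.root:
                if cur in seen or cur not in self.parent:
                    raise ValueError(f"node {n} is disconnected or in a cycle")
                seen.add(cur)
                cur = self.parent[cur]

    # -- cached geometry ------------------------------------------------------

    @property
    def total_length(self) -> float:
        return float(sum(self.edge_length.values()))

    @property
    def edges(self) -> list[int]:
        """Edge ids (child node ids), in insertion order."""
        return list(self.edge_length)

    def depth(self, node: int) -> float:
        """Geodesic distance from the root to a node."""
        if self._depth is None:
            self._depth = {self.root: 0.0}
            stack = [self.root]
            while stack:
                p = stack.pop()
                for c in self.children[p]:
                    self._depth[c] = self._depth[p] + self.edge_length[c]
                    stack.append(c)
        return self._depth[node]

    def node_distance(self, u: int, v: int) -> float:
        if self._node_dist is None:
            g = nx.Graph()
            for c, p in self.parent.items():
                g.add_edge(p, c, weight=self.edge_length[c])
            g.add_node(self.root)
            self._node_dist = {
                s: d for s, d in nx.all_pairs_dijkstra_path_length(g)
            }
        return self._node_dist[u][v]

    def descendants(self, node: int) -> frozenset[int]:
        """All nodes strictly or weakly below ``node`` (includes node)."""
        if self._desc is None:
            self._desc = {}
            # post-order accumulation
            order: list[int] = []
            stack = [self.root]
            while stack:
                n = stack.pop()
                order.append(n)
                stack.extend(self.children[n])
            for n in reversed(order):
                acc = {n}
                for c in self.children[n]:
                    acc |= self._desc[c]
                self._desc[n] = frozenset(acc)
        return self._desc[node]

    def is_unbranched(self) -> bool:
        return all(len(cs) <= 1 for cs in self.children.values())

    # -- positions ------------------------------------------------------------

    def check_position(self, pos: TreePosition) -> None:
        if pos.edge not in self.edge_length:
            raise ValueError(f"edge {pos.edge} not in tree")
        if pos.offset > self.edge_length[pos.edge] + 1e-9:
            raise ValueError(
                f"offset {pos.offset} exceeds edge {pos.edge} length "
                f"{self.edge_length[pos.edge]}"
            )

    def position_depth(self, pos: TreePosition) -> float:
        self.check_position(pos)
        return self.depth(self.parent[pos.edge]) + pos.offset

    def position_at_arclength(self, s: float) -> TreePosition:
        """For unbranched trees: the position s µm from the root."""
        if not self.is_unbranched():
            raise ValueError("arc-length addressing requires an unbranched tree")
        node = self.root
        remaining = float(s)
        while self.children[node]:
            c = self.children[node][0]
            if remaining <= self.edge_length[c] or not self.children[c]:
                return TreePosition(c, min(remaining, self.edge_length[c]))
            remaining -= self.edge_length[c]
            node = c
        raise ValueError("tree has no edges")


def path_distance(tree: DendriteTree, a: TreePosition, b: TreePosition) -> float:
    """Geodesic distance (µm) along the tree between two positions."""
    tree.check_position(a)
    tree.check_position(b)
    if a.edge == b.edge:
        return abs(a.offset - b.offset)
    la = tree.edge_length[a.edge]
    lb = tree.edge_length[b.edge]
    pa, ca = tree.parent[a.edge], a.edge
    pb, cb = tree.parent[b.edge], b.edge
    best = min(
        a.offset + tree.node_distance(pa, pb) + b.offset,
        a.offset + tree.node_distance(pa, cb) + (lb - b.offset),
        (la - a.offset) + tree.node_distance(ca, pb) + b.offset,
        (la - a.offset) + tree.node_distance(ca, cb) + (lb - b.offset),
    )
    return float(best)


def is_distal(tree: DendriteTree, a: TreePosition, b: TreePosition) -> bool:
    """True if ``b`` lies on the side of ``a`` pointing away from the root,
    i.e. the geodesic from a to b never moves toward the root."""
    if a.edge == b.edge:
        return b.offset > a.offset
    return b.edge in tree.descendants(a.edge)


def pairwise_distances(
    tree: DendriteTree, positions: Sequence[TreePosition]
) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise geodesic distances plus the distal-relation matrix.

    Returns
    -------
    D : (n, n) array, D[i, j] = geodesic distance between positions i and j
    distal : (n, n) boolean array, distal[i, j] True iff j is distal of i
    """
    n = len(positions)
    for p in positions:
        tree.check_position(p)
    edge_ids = np.array([p.edge for p in positions])
    offsets = np.array([p.offset for p in positions], dtype=float)

    if tree.is_unbranched():
        # single path from root: arc-length coordinates suffice
        s = np.array([tree.position_depth(p) for p in positions])
        D = np.abs(s[:, None] - s[None, :])
        distal = s[None, :] > s[:, None]
        return D, distal

    lengths = np.array([tree.edge_length[p.edge] for p in positions])
    parents = np.array([tree.parent[p.edge] for p in positions])
    # node-pair distance lookups, vectorized over the (few) distinct nodes
    nodes = sorted({int(x) for x in parents} | {int(e) for e in edge_ids})
    idx = {v: i for i, v in enumerate(nodes)}
    nd = np.array(
        [[tree.node_distance(u, v) for v in nodes] for u in nodes], dtype=float
    )
    pi = np.array([idx[int(x)] for x in parents])
    ci = np.array([idx[int(x)] for x in edge_ids])
    up = offsets  # cost to the parent end
    down = lengths - offsets  # cost to the child end
    D = np.minimum.reduce(
        [
            up[:, None] + nd[pi][:, pi] + up[None, :],
            up[:, None] + nd[pi][:, ci] + down[None, :],
            down[:, None] + nd[ci][:, pi] + up[None, :],
            down[:, None] + nd[ci][:, ci] + down[None, :],
        ]
    )
    same_edge = edge_ids[:, None] == edge_ids[None, :]
    D = np.where(same_edge, np.abs(offsets[:, None] - offsets[None, :]), D)

    desc = np.zeros((n, n), dtype=bool)
    for i in range(n):
        di = tree.descendants(edge_ids[i])
        desc[i] = np.array([e in di for e in edge_ids])
    distal = np.where(
        same_edge, offsets[None, :] > offsets[:, None], desc
    )
    return D, distal


def neighbors_within(
    tree: DendriteTree,
    positions: Sequence[TreePosition],
    focal: int,
    radius: float,
) -> set[int]:
    """Indices of positions within ``radius`` µm (geodesic) of the focal
    position, focal excluded."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    out = set()
    for i, p in enumerate(positions):
        if i == focal:
            continue
        if path_distance(tree, positions[focal], p) <= radius:
            out.add(i)
    return out


# -- SWC and table I/O --------------------------------------------------------

def read_swc(path) -> DendriteTree:
    """Read a standard 7-column SWC file (id, type, x, y, z, radius, parent),
    coordinates in µm.  The single node with parent -1 becomes the root."""
    rows = []
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        rows.append((int(f[0]), float(f[2]), float(f[3]), float(f[4]), int(f[6])))
    nodes = {r[0]: (r[1], r[2], r[3]) for r in rows}
    roots = [r[0] for r in rows if r[4] == -1]
    if len(roots) != 1:
        raise ValueError(f"SWC must have exactly one root, found {len(roots)}")
    edges = [(r[4], r[0]) for r in rows if r[4] != -1]
    return DendriteTree(nodes, edges, roots[0])


def write_swc(tree: DendriteTree, path) -> None:
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    order = [tree.root] + [c for c in tree.parent]
    for n in order:
        x, y, z = tree.nodes[n]
        parent = tree.parent.get(n, -1)
        buf.write(f"{n} 3 {x:.4f} {y:.4f} {z:.4f} 0.5 {parent}\n")
    Path(path).write_text(buf.getvalue())


def read_synapse_positions(path) -> pd.DataFrame:
    """Synapse position table: synapse_id, edge_id, offset_um, type."""
    df = pd.read_csv(path, sep="\t")
    required = {"synapse_id", "edge_id", "offset_um", "type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"synapse table missing columns: {sorted(missing)}")
    bad = ~df["type"].isin(["spine", "shaft"])
    if bad.any():
        raise ValueError("synapse type must be 'spine' or 'shaft'")
    return df


def write_synapse_positions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
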