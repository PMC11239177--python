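"""Spatial statistics of synapse placement along dendrites.

The central question: are functional synapses placed randomly along the
dendrite, or clustered?  The test used here compares the observed
nearest-neighbor distance distribution against a shuffle null built by

1. inserting "empty" candidate positions between the real synapses so the
   whole dendrite is covered at the typical minimal inter-synapse spacing
   (4 µm),
2. redistributing the synapses uniformly, without replacement, across the
   real + empty candidate positions (100 shuffles),
3. comparing observed vs shuffled proximal/distal nearest-neighbor distances
   with a Kolmogorov–Smirnov test.

All distances are geodesics along the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .activity import Synapse
from .morphology import (
    DendriteTree,
    TreePosition,
    pairwise_distances,
    path_distance,
)

__all__ = [
    "ShuffleConfig",
    "ShuffleNull",
    "insert_empty_positions",
    "nn_distances",
    "shuffle_test",
    "distance_to_high_activity",
]


@dataclass
class ShuffleConfig:
    n_shuffles: int = 100
    spacing_um: float = 4.0
    seed: int = 0
    mode: str = "pooled"  # "pooled": KS vs pooled null; "rank": permutation p
    jitter: bool = False  # draw spacing from U(spacing−1, spacing+1)


@dataclass
class ShuffleNull:
    n_shuffles: int
    spacing_um: float
    seed: int
    observed: np.ndarray  # pooled observed nearest-neighbor distances
    null_samples: np.ndarray  # pooled over all shuffles
    statistic: float  # KS D, observed vs pooled null
    p_value: float
    mode: str = "pooled"
    n_candidates: int = 0


def _node_position(tree: DendriteTree, node: int) -> TreePosition:
    """Represent a tree node as a TreePosition (parent-edge convention;
    the root borrows offset 0 of its first child edge)."""
    if node == tree.root:
        child = tree.children[node][0]
        return TreePosition(child, 0.0)
    return TreePosition(node, tree.edge_length[node])


def insert_empty_positions(
    tree: DendriteTree,
    positions: list[TreePosition],
    spacing: float,
) -> list[TreePosition]:
    """Empty candidate positions filling the dendrite between real synapses.

    Uncovered nodes (no synapse within spacing/2) receive an empty position;
    each inter-anchor gap of length g along an edge is filled with
    ceil(g/spacing) − 1 equally spaced empties, so inter-position gaps never
    exceed the spacing.  Empties closer than spacing/2 to a real synapse are
    dropped.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    empties: list[TreePosition] = []

    def min_dist_to_real(pos: TreePosition) -> float:
        if not positions:
            return np.inf
        return min(path_distance(tree, pos, p) for p in positions)

    node_covered: dict[int, float] = {}  # node -> distance of nearest anchor
    for node in tree.nodes:
        npos = _node_position(tree, node)
        d = min_dist_to_real(npos)
        if d < spacing / 2:
            node_covered[node] = d
        else:
            empties.append(npos)
            node_covered[node] = 0.0

    by_edge: dict[int, list[float]] = {e: [] for e in tree.edge_length}
    for p in positions:
        by_edge[p.edge].append(p.offset)
    for p in empties:
        by_edge[p.edge].append(p.offset)

    for edge, offs in by_edge.items():
        length = tree.edge_length[edge]
        pnode, cnode = tree.parent[edge], edge
        anchors = sorted(set(offs) | {-node_covered[pnode], length + node_covered[cnode]})
        for a, b in zip(anchors[:-1], anchors[1:]):
            g = b - a
            n_fill = int(np.ceil(g / spacing)) - 1
            if n_fill <= 0:
                continue
            step = g / (n_fill + 1)
            for k in range(1, n_fill + 1):
                off = a + k * step
                if 0.0 <= off <= length:
                    cand = TreePosition(edge, off)
                    if min_dist_to_real(cand) >= spacing / 2:
                        empties.append(cand)
    return sorted(empties)


def _nn_pooled(
    D: np.ndarray, distal: np.ndarray, idx: np.ndarray | None = None
) -> np.ndarray:
    """Pooled proximal and distal nearest-neighbor distances for the
    positions selected by ``idx`` (all if None).  Positions lacking a
    neighbor on one side contribute only the defined side."""
    if idx is not None:
        D = D[np.ix_(idx, idx)]
        distal = distal[np.ix_(idx, idx)]
    n = len(D)
    if n < 2:
        return np.array([])
    Dm = D.copy()
    np.fill_diagonal(Dm, np.inf)
    dist_side = np.where(distal, Dm, np.inf).min(axis=1)
    prox_side = np.where(~distal, Dm, np.inf).min(axis=1)
    pooled = np.concatenate([dist_side, prox_side])
    return pooled[np.isfinite(pooled)]


def nn_distances(
    tree: DendriteTree, positions: list[TreePosition]
) -> pd.DataFrame:
    """Per-position proximal and distal nearest-neighbor geodesic distances.

    Proximal = nearest position whose geodesic path from the focal position
    starts toward the root; distal = away from the root.  NaN when no
    neighbor exists on that side.
    """
    if len(positions) < 2:
        return pd.DataFrame(columns=["proximal_um", "distal_um"])
    D, distal = pairwise_distances(tree, positions)
    Dm = D.copy()
    np.fill_diagonal(Dm, np.inf)
    dist_side = np.where(distal, Dm, np.inf).min(axis=1)
    prox_side = np.where(~distal, Dm, np.inf).min(axis=1)
    return pd.DataFrame(
        {
            "proximal_um": np.where(np.isfinite(prox_side), prox_side, np.nan),
            "distal_um": np.where(np.isfinite(dist_side), dist_side, np.nan),
        }
    )


def _ks_d(sample: np.ndarray, pool_sorted: np.ndarray) -> float:
    """Two-sample KS statistic of sample vs a pre-sorted pool."""
    s = np.sort(sample)
    n, m = len(s), len(pool_sorted)
    allv = np.concatenate([s, pool_sorted])
    cdf1 = np.searchsorted(s, allv, side="right") / n
    cdf2 = np.searchsorted(pool_sorted, allv, side="right") / m
    return float(np.abs(cdf1 - cdf2).max())


def shuffle_test(
    tree: DendriteTree,
    synapses: list[Synapse] | list[TreePosition],
    config: ShuffleConfig | None = None,
    candidates: list[TreePosition] | None = None,
) -> ShuffleNull:
    """Empty-position shuffle test for non-random synapse placement.

    Draws ``n_shuffles`` uniform placements of the synapses over the
    candidate set (real + empty positions, without replacement), pools their
    nearest-neighbor distances into a null sample, and compares the observed
    distances against it with a two-sample KS test.  In "rank" mode the
    p-value is instead the permutation rank of the observed KS statistic
    among the per-shuffle statistics.

    ``candidates`` overrides the reconstructed real + empty candidate set
    (it must contain every synapse position); useful when the admissible
    positions are known a priori, which also makes the observed placement
    exactly exchangeable with the shuffles.
    """
    cfg = config or ShuffleConfig()
    positions = [
        s.position if isinstance(s, Synapse) else s for s in synapses
    ]
    if len(positions) < 2:
        raise ValueError("need at least 2 synapses")
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.spacing_um
    if candidates is None:
        if cfg.jitter:
            spacing = float(rng.uniform(cfg.spacing_um - 1, cfg.spacing_um + 1))
        empties = insert_empty_positions(tree, positions, spacing)
        candidates = list(positions) + empties
    else:
        missing = set(positions) - set(candidates)
        if missing:
            raise ValueError("candidate set must contain every synapse position")
        pos_set = set(positions)
        # observed positions first, so index bookkeeping matches below
        candidates = list(positions) + [c for c in candidates if c not in pos_set]
    n, m = len(positions), len(candidates)
    if m < n:
        raise ValueError("candidate set smaller than synapse count")
    D, distal = pairwise_distances(tree, candidates)
    observed = _nn_pooled(D, distal, np.arange(n))

    shuffle_samples = []
    for _ in range(cfg.n_shuffles):
        idx = rng.choice(m, size=n, replace=False)
        shuffle_samples.append(_nn_pooled(D, distal, idx))
    null = np.concatenate(shuffle_samples)

    if cfg.mode == "pooled":
        ks = stats.ks_2samp(observed, null)
        d, p = float(ks.statistic), float(ks.pvalue)
    elif cfg.mode == "rank":
        pool = np.sort(null)
        d = _ks_d(observed, pool)
        d_null = np.array([_ks_d(s, pool) for s in shuffle_samples])
        p = float((1 + np.sum(d_null >= d)) / (cfg.n_shuffles + 1))
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")
    return ShuffleNull(
        n_shuffles=cfg.n_shuffles,
        spacing_um=spacing,
        seed=cfg.seed,
        observed=observed,
        null_samples=null,
        statistic=d,
        p_value=p,
        mode=cfg.mode,
        n_candidates=m,
    )


def distance_to_high_activity(
    tree: DendriteTree,
    synapses: list[Synapse],
    threshold_um: float = 10.0,
    bin_width_um: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Distance of every synapse to its nearest high-activity synapse, the
    mean frequency per distance bin, and the near (< threshold) vs far
    (> threshold) group comparison (two-sided unpaired t-test).

    For a high-activity synapse the distance is to the nearest *other*
    high-activity synapse.
    """
    ha = [s for s in synapses if s.high_activity]
    if not ha:
        return pd.DataFrame(), {}
    rows = []
    for s in synapses:
        others = [h for h in ha if h.synapse_id != s.synapse_id]
        if not others:
            continue
        d = min(path_distance(tree, s.position, h.position) for h in others)
        rows.append(
            {
                "synapse_id": s.synapse_id,
                "f": s.f,
                "high_activity": s.high_activity,
                "distance_um": d,
                "group": "near" if d < threshold_um else "far",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {}
    bins = np.arange(0, df["distance_um"].max() + bin_width_um, bin_width_um)
    df["bin"] = pd.cut(df["distance_um"], bins, right=False)
    binned = (
        df.groupby("bin", observed=True)["f"].agg(["mean", "sem", "count"])
        .reset_index()
    )
    near = df.loc[df["group"] == "near", "f"].to_numpy(dtype=float)
    far = df.loc[df["group"] == "far", "f"].to_numpy(dtype=float)
    summary: dict = {
        "n_near": int(len(near)),
        "n_far": int(len(far)),
        "mean_f_near": float(np.mean(near)) if len(near) else np.nan,
        "sem_f_near": float(stats.sem(near)) if len(near) > 1 else np.nan,
        "mean_f_far": float(np.mean(far)) if len(far) else np.nan,
        "sem_f_far": float(stats.sem(far)) if len(far) > 1 else np.nan,
        "binned": binned,
    }
    if len(near) > 1 and len(far) > 1:
        t = stats.ttest_ind(near, far)
        summary["t_statistic"] = float(t.statistic)
        summary["p_value"] = float(t.pvalue)
    return df, summary
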