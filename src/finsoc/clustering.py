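"""Social clusters by Newman's leading-eigenvector modularity method.

The affiliation network is partitioned by recursively splitting on the
leading eigenvector of the modularity matrix

    B = W - s s^T / (2m),   s_i = node strength,  2m = total strength,

with greedy single-node fine-tuning after each split; a split is kept only
if it raises the global modularity

    Q = (1/2m) sum_ij [W_ij - s_i s_j / (2m)] delta(c_i, c_j).

Q above ~0.3 is conventionally taken as a meaningful division.  Negative
affiliation indices are clamped to zero before clustering (modularity is
defined for non-negative weights); the raw matrix is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dyadmatrix import DyadMatrix
from .ranges import estimate_ud, range_contour

__all__ = [
    "Partition",
    "modularity_value",
    "newman_partition",
    "cluster_ranges",
    "export_network",
]

logger = logging.getLogger(__name__)


@dataclass
class Partition:
    """Cluster labels per individual plus the achieved modularity."""

    ids: list[str]
    labels: np.ndarray  # int label per individual, 0..k-1
    q: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.ids, self.labels) if l == label]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.ids, name="cluster")


def _clamped(weights: DyadMatrix) -> np.ndarray:
    w = weights.values.copy()
    neg = w < 0
    if neg.any():
        logger.info("clustering: clamping %d negative weights to 0", int(neg.sum()) // 2)
        w[neg] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def modularity_value(weights: DyadMatrix, labels: np.ndarray) -> float:
    """Direct evaluation of Q for the given labels (negatives clamped)."""
    w = _clamped(weights)
    return _q(w, np.asarray(labels))


def _q(w: np.ndarray, labels: np.ndarray) -> float:
    m2 = w.sum()
    if m2 == 0:
        return 0.0
    s = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    b = w - np.outer(s, s) / m2
    return float(b[same].sum() / m2)


def newman_partition(weights: DyadMatrix) -> Partition:
    """Recursive leading-eigenvector bisection with greedy fine-tuning.

    Each candidate bisection comes from the sign pattern of the leading
    eigenvector of the group's generalized modularity matrix, then is
    refined by greedy single-node moves (ties broken toward the lowest
    node index).  A split is accepted only if it strictly increases the
    global Q, so the returned partition's Q is monotone in the recursion
    and never below the one-cluster value of 0.
    """
    ids = list(weights.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    w = _clamped(weights)
    m2 = w.sum()
    labels = np.zeros(n, dtype=int)
    if m2 == 0:
        logger.warning("all-zero weight matrix: returning a single cluster")
        return Partition(ids=ids, labels=labels, q=0.0)
    s = w.sum(axis=1)
    B = w - np.outer(s, s) / m2

    def split_gain(group: np.ndarray, side: np.ndarray) -> float:
        """Delta-Q of bisecting `group` (bool mask) by `side` (+-1 per member)."""
        Bg = B[np.ix_(group, group)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        return float(side @ Bg @ side) / (2.0 * m2)

    def refine(group_idx: np.ndarray, side: np.ndarray) -> np.ndarray:
        """Kernighan-Lin-style fine-tuning of a bisection.

        Each pass tentatively flips every node exactly once — always the
        flip with the largest (possibly negative) gain, ties broken
        toward the lowest node index — and keeps the best intermediate
        state; passes repeat while they improve the split.  Allowing
        temporary downhill moves lets the refinement escape the local
        optima a strictly greedy sweep gets stuck in.
        """
        group = np.zeros(n, dtype=bool)
        group[group_idx] = True
        Bg = B[np.ix_(group_idx, group_idx)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        m = len(side)

        def gain_of_flip(s, k, Bs):
            # change in s^T Bg s when s_k flips, from the cached Bg @ s
            return (-4.0 * s[k] * Bs[k] + 4.0 * Bg[k, k]) / (2.0 * m2)

        current_gain = float(side @ Bg @ side) / (2.0 * m2)
        improved = True
        while improved:
            improved = False
            s = side.copy()
            Bs = Bg @ s
            moved = np.zeros(m, dtype=bool)
            running = current_gain
            best_running = current_gain
            best_state = None
            for _ in range(m):
                cand_gain = np.array([
                    gain_of_flip(s, k, Bs) if not moved[k] else -np.inf
                    for k in range(m)
                ])
                # a flip that empties one side is not a bisection
                for k in range(m):
                    if not moved[k] and abs(s.sum() - 2 * s[k]) == m:
                        cand_gain[k] = -np.inf
                k = int(np.argmax(cand_gain))
                if not np.isfinite(cand_gain[k]):
                    break
                running += cand_gain[k]
                s[k] = -s[k]
                Bs += 2.0 * s[k] * Bg[:, k]
                moved[k] = True
                if running > best_running + 1e-12:
                    best_running = running
                    best_state = s.copy()
            if best_state is not None:
                side = best_state
                current_gain = best_running
                improved = True
        return side

    next_label = 1
    stack = [0]
    while stack:
        lab = stack.pop(0)
        group_idx = np.flatnonzero(labels == lab)
        if len(group_idx) < 2:
            continue
        Bg = B[np.ix_(group_idx, group_idx)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        evals, evecs = np.linalg.eigh(Bg)
        lead = evecs[:, -1]
        if evals[-1] <= 1e-12:
            continue  # indivisible
        side = np.where(lead >= 0, 1, -1)
        if abs(side.sum()) == len(side):
            # degenerate sign pattern: seed with the largest-component node
            side[int(np.argmax(np.abs(lead)))] *= -1
        group = np.zeros(n, dtype=bool)
        group[group_idx] = True
        side = refine(group_idx, side)
        if split_gain(group, side) <= 1e-12:
            continue
        new_lab = next_label
        next_label += 1
        labels[group_idx[side < 0]] = new_lab
        stack.extend([lab, new_lab])

    # relabel clusters deterministically by lowest member index
    order = {}
    for l in labels:
        if l not in order:
            order[l] = len(order)
    labels = np.array([order[l] for l in labels])
    return Partition(ids=ids, labels=labels, q=_q(w, labels))


def cluster_ranges(
    partition: Partition,
    records: pd.DataFrame,
    h: float = 550.0,
    cell: float = 50.0,
) -> dict[int, dict]:
    """Pooled 95%/50% kernel ranges per social cluster.

    Each group sighting's position is allocated to every cluster with a
    member in the group (once per cluster per group).
    """
    rec = records.copy()
    rec["individual_id"] = rec["individual_id"].astype(str)
    lab = dict(zip(partition.ids, partition.labels))
    rec = rec[rec["individual_id"].isin(lab)]
    rec["cluster"] = rec["individual_id"].map(lab)
    xs = rec["x_m"].to_numpy(float)
    ys = rec["y_m"].to_numpy(float)
    bounds = (xs.min(), xs.max(), ys.min(), ys.max())
    out: dict[int, dict] = {}
    for cl in sorted(set(partition.labels)):
        sub = rec[rec["cluster"] == cl].drop_duplicates(subset=["date", "group_id"])
        pts = sub[["x_m", "y_m"]].to_numpy(float)
        if len(pts) < 1:
            logger.warning("cluster %s has no sighting locations; skipped", cl)
            continue
        ud = estimate_ud(pts, h=h, cell=cell, bounds=bounds)
        _, a95 = range_contour(ud, 0.95)
        _, a50 = range_contour(ud, 0.50)
        out[int(cl)] = {"ud": ud, "area95_m2": a95, "area50_m2": a50, "n_locations": len(pts)}
    return out


def export_network(
    gai: DyadMatrix,
    partition: Partition | None = None,
    edge_threshold: float | str = "twice_mean",
) -> tuple[nx.Graph, pd.DataFrame]:
    """Thresholded affiliation network with node attributes.

    ``edge_threshold="twice_mean"`` keeps edges stronger than twice the
    magnitude of the mean dyadic affiliation (the mean itself may be
    negative, so the rule works on |mean|); a float is used as-is.
    Returns the graph and its edge list (source, target, weight).
    """
    vals = gai.dyad_values()
    thr = 2.0 * abs(float(vals.mean())) if edge_threshold == "twice_mean" else float(edge_threshold)
    g = nx.Graph()
    strengths = np.clip(gai.values, 0, None).sum(axis=1)
    for k, i in enumerate(gai.ids):
        attrs = {"gregariousness": float(strengths[k])}
        if partition is not None:
            attrs["cluster"] = int(partition.labels[partition.ids.index(i)])
        g.add_node(i, **attrs)
    iu, ju = gai.triu_indices()
    rows = []
    for a, b in zip(iu, ju):
        wgt = gai.values[a, b]
        if wgt > thr:
            g.add_edge(gai.ids[a], gai.ids[b], weight=float(wgt))
            rows.append((gai.ids[a], gai.ids[b], float(wgt)))
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    return g, edges
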