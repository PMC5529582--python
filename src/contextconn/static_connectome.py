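"""Time-averaged connectome and canonical-network discovery.

The static connectome is the Pearson correlation between each pair of node
timeseries, Fisher-z averaged across subjects. Canonical networks are found
by Louvain community detection on the cortical submatrix; the Louvain
resolution parameter gamma is trained by scanning a grid and scoring each
resulting partition against an a-priori reference partition with a pairwise
cost function:

    per unique node pair (candidate co-assigns = x, reference co-assigns = y):
        0           if x = 0, y = 0
        n / (m - n) if x = 0, y = 1
        1           if x = 1, y = 0
       -1           if x = 1, y = 1

where m is the number of intramodular pairs in the reference and n the
number of nodes. The total cost is summed over unique pairs; a partition
identical to the reference scores exactly -m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import fisher_z, fisher_z_inverse, n_pairs

SUBCORTICAL_LABEL = "subcortical"


@dataclass
class StaticConnectome:
    """Symmetric N x N Pearson connectome with unit diagonal."""

    E: np.ndarray
    node_ids: list
    is_cortical: np.ndarray

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.is_cortical = np.asarray(self.is_cortical, dtype=bool)
        if not np.allclose(self.E, self.E.T, atol=1e-12):
            raise ValueError("connectome must be symmetric")

    @property
    def n_edges(self) -> int:
        return n_pairs(self.E.shape[0])


@dataclass
class NetworkPartition:
    """node_id -> network label; the subcortical label is reserved."""

    assignment: dict
    networks: list = field(default=None)

    def __post_init__(self):
        if self.networks is None:
            seen = []
            for v in self.assignment.values():
                if v not in seen:
                    seen.append(v)
            self.networks = seen

    def labels_for(self, node_ids) -> np.ndarray:
        return np.array([self.assignment[n] for n in node_ids], dtype=object)

    def nodes_in(self, network) -> list:
        return [n for n, lab in self.assignment.items() if lab == network]

    def cortical_networks(self) -> list:
        return [g for g in self.networks if g != SUBCORTICAL_LABEL]


def compute_static_connectome(ts) -> StaticConnectome:
    """Pearson connectome per subject, Fisher-z averaged across subjects.

    Constant node series produce zero correlations (with a warning) rather
    than NaN so that node indexing is stable.
    """
    n = ts.n_nodes
    zsum = np.zeros((n, n))
    for s in ts.subjects:
        mat = ts.data[s]
        sd = mat.std(axis=0)
        const = sd < 1e-12
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(mat, rowvar=False)
        if const.any():
            warnings.warn(
                f"subject {s}: {int(const.sum())} constant node series; "
                "their correlations set to 0"
            )
            r[const, :] = 0.0
            r[:, const] = 0.0
        np.fill_diagonal(r, 0.0)  # exclude diagonal from z-averaging
        zsum += fisher_z(r)
    e = fisher_z_inverse(zsum / len(ts.subjects))
    np.fill_diagonal(e, 1.0)
    return StaticConnectome(E=e, node_ids=list(ts.node_ids), is_cortical=ts.is_cortical.copy())


def _co_assign_matrix(labels: np.ndarray) -> np.ndarray:
    return labels[:, None] == labels[None, :]


def reference_intra_pairs(reference: NetworkPartition, node_ids) -> int:
    """m: number of node pairs the reference places in the same module."""
    labels = reference.labels_for(node_ids)
    co = _co_assign_matrix(labels)
    iu = np.triu_indices(len(node_ids), k=1)
    return int(co[iu].sum())


def pair_cost_term(x: int, y: int, m: int, n: int) -> float:
    """Per-pair cost of candidate co-assignment x vs reference co-assignment y.

    m must differ from n for the x=0, y=1 term to be defined.
    """
    if x not in (0, 1) or y not in (0, 1):
        raise ValueError("x and y must be 0 or 1")
    if x == 0 and y == 0:
        return 0.0
    if x == 0 and y == 1:
        if m == n:
            raise ZeroDivisionError("cost term n/(m-n) undefined when m = n")
        return n / (m - n)
    if x == 1 and y == 0:
        return 1.0
    return -1.0


def partition_cost(candidate: NetworkPartition, reference: NetworkPartition, node_ids=None) -> float:
    """Total pairwise cost of a candidate partition against the reference.

    Lower is better; a candidate identical to the reference scores -m.
    """
    if node_ids is None:
        node_ids = sorted(set(candidate.assignment) & set(reference.assignment))
    node_ids = list(node_ids)
    n = len(node_ids)
    if n < 2:
        raise ValueError("need at least 2 shared nodes")
    x = _co_assign_matrix(candidate.labels_for(node_ids))
    y = _co_assign_matrix(reference.labels_for(node_ids))
    iu = np.triu_indices(n, k=1)
    xv, yv = x[iu], y[iu]
    m = int(yv.sum())
    if m == n:
        raise ZeroDivisionError("cost term n/(m-n) undefined when m = n")
    ref_only = n / (m - n)
    return float(
        np.sum(np.where(xv & yv, -1.0, np.where(xv, 1.0, np.where(yv, ref_only, 0.0))))
    )


def _louvain_best(graph: nx.Graph, gamma: float, n_runs: int, seed: int):
    best_q, best = -np.inf, None
    for run in range(n_runs):
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=gamma, seed=seed + run
        )
        q = nx.community.modularity(graph, comms, weight="weight", resolution=gamma)
        if q > best_q:
            best_q, best = q, comms
    return best, best_q


def detect_communities(
    conn: StaticConnectome,
    gamma: float = 1.0,
    n_runs: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
) -> NetworkPartition:
    """Best-modularity Louvain partition of the cortical submatrix.

    Edge weights below ``threshold`` (default 0: negative correlations) are
    removed before detection. Subcortical nodes receive the reserved label.
    """
    cort = np.nonzero(conn.is_cortical)[0]
    if cort.size == 0:
        raise ValueError("no cortical nodes")
    sub = conn.E[np.ix_(cort, cort)]
    g = nx.Graph()
    g.add_nodes_from(range(cort.size))
    iu, ju = np.triu_indices(cort.size, k=1)
    for i, j in zip(iu, ju):
        w = sub[i, j]
        if w > threshold:
            g.add_edge(int(i), int(j), weight=float(w))
    comms, _ = _louvain_best(g, gamma, n_runs, seed)
    assignment = {}
    for cid, members in enumerate(sorted(comms, key=lambda c: min(c))):
        for local in members:
            assignment[conn.node_ids[cort[local]]] = f"net{cid}"
    for idx, nid in enumerate(conn.node_ids):
        if not conn.is_cortical[idx]:
            assignment[nid] = SUBCORTICAL_LABEL
    return NetworkPartition(assignment=assignment)


def train_resolution(
    conn: StaticConnectome,
    reference: NetworkPartition,
    gamma_grid,
    n_runs: int = 100,
    seed: int = 0,
    threshold: float = 0.0,
):
    """Scan gamma over a grid, score each partition against the reference.

    Returns (gamma_star, best partition, cost curve). Ties break toward the
    smaller gamma.
    """
    gamma_grid = list(gamma_grid)
    if not gamma_grid:
        raise ValueError("gamma_grid must be non-empty")
    cortical_ids = [n for n, c in zip(conn.node_ids, conn.is_cortical) if c]
    curve = []
    best = None
    for gamma in gamma_grid:
        part = detect_communities(conn, gamma=gamma, n_runs=n_runs, seed=seed, threshold=threshold)
        cost = partition_cost(part, reference, node_ids=cortical_ids)
        curve.append((gamma, cost))
        if best is None or cost < best[1] - 1e-12:
            best = (gamma, cost, part)
    return best[0], best[2], curve


def write_partition(path, partition: NetworkPartition):
    pd.DataFrame(
        {"node_id": list(partition.assignment), "network_label": list(partition.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path) -> NetworkPartition:
    df = pd.read_csv(path, sep="\t")
    return NetworkPartition(
        assignment=dict(zip(df["node_id"].astype(str), df["network_label"].astype(str)))
    )


def write_connectome(path, conn: StaticConnectome):
    pd.DataFrame(conn.E, index=conn.node_ids, columns=conn.node_ids).to_csv(path, sep="\t")
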