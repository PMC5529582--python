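"""Dynamically engaged subsystems within an NC-state.

During some NC-states a network fractionates: subsets of its nodes behave
as coherent sub-units with distinct whole-brain affiliation. Subsystems are
found by agglomerative clustering of nodal allegiance profiles (one row per
network node, one column per brain node) under the correlation distance
1 - r, cutting the tree at a fixed distance (default 0.4, stable through
roughly 0.4-0.6). Clusters of two or fewer nodes are flagged trivial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

NON_COHESIVE = "non-cohesive"


@dataclass
class SubsystemLabeling:
    state: tuple
    labels: dict            # node_id -> subsystem id (int) or NON_COHESIVE
    threshold: float
    trivial: dict           # subsystem id -> bool (size <= 2)

    def subsystem_sizes(self) -> dict:
        sizes = {}
        for lab in self.labels.values():
            if lab != NON_COHESIVE:
                sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def n_subsystems(self) -> int:
        return len(self.subsystem_sizes())


def allegiance_profiles(wbcc, partition, network, node_ids) -> tuple:
    """Rows = the network's nodes, columns = all nodes, values = allegiance.

    Returns (profiles, network node_ids).
    """
    members = [i for i, nid in enumerate(node_ids) if partition.assignment.get(nid) == network]
    if not members:
        raise KeyError(f"network {network!r} not present")
    prof = wbcc.allegiance.A[members, :]
    return prof, [node_ids[i] for i in members]


def cluster_subsystems(
    profiles: np.ndarray,
    row_ids=None,
    threshold: float = 0.4,
    linkage_method: str = "average",
    state=None,
) -> SubsystemLabeling:
    """Cut an agglomerative tree over profile rows at a correlation distance.

    Rows whose profile is constant have undefined correlation distance and
    are labeled non-cohesive with a warning.
    """
    if not (0 < threshold < 2):
        raise ValueError("threshold must lie in (0, 2)")
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    profiles = np.asarray(profiles, dtype=float)
    n = profiles.shape[0]
    if row_ids is None:
        row_ids = list(range(n))
    constant = profiles.std(axis=1) < 1e-12
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profile rows labeled non-cohesive")
    ok = np.nonzero(~constant)[0]
    labels = {row_ids[i]: NON_COHESIVE for i in np.nonzero(constant)[0]}
    trivial = {}
    if ok.size == 1:
        labels[row_ids[ok[0]]] = 1
        trivial[1] = True
    elif ok.size > 1:
        sub = profiles[ok]
        centered = sub - sub.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(centered, axis=1)
        r = (centered @ centered.T) / np.outer(norm, norm)
        dist = np.clip(1.0 - r, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        z = linkage(squareform(dist, checks=False), method=linkage_method)
        flat = fcluster(z, t=threshold, criterion="distance")
        for local, cid in zip(ok, flat):
            labels[row_ids[local]] = int(cid)
        for cid in set(flat.tolist()):
            trivial[int(cid)] = int(np.sum(flat == cid)) <= 2
    return SubsystemLabeling(state=state, labels=labels, threshold=threshold, trivial=trivial)
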