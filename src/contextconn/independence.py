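"""Temporal independence of (pseudo-)networks from whole-cortex dynamics.

The core question: how well do one subsystem's connectivity states explain
the temporal variation of the whole cortex? Each NC-state's *contextual
centroid* (mean Fisher-z whole-cortex edge vector over the state's windows)
is treated as a proposed clustering solution for the cortex; its quality is
the within-cluster sum of squared correlation distances (WCSS) from every
cortical window to the nearest centroid. Lower WCSS = the subsystem's
states explain more global variance = less independent.

Anchors for the independence score:

* **upper bound** (maximal interdependence, minimum WCSS): k-means on all
  cortical features;
* **lower bound** (maximal independence, maximum WCSS): degenerate hybrid
  centroids equal to the time-averaged cortical connectivity except on the
  network's own edges, where they equal the network's NC-state centroids;
* **zero**: the mean WCSS among size- and k-matched random pseudo-networks.

The score maps WCSS piecewise-linearly onto [-1, +1] through these anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import context as context_mod
from ._utils import correlation_distance, edge_columns_for_nodes, fisher_z, spawn_rng
from .state_detection import fit_ncstates


@dataclass
class PseudoNetwork:
    """Random node subset matched in size and state count to a canonical network."""

    nodes: list
    k: int

    def __post_init__(self):
        if len(self.nodes) < 2:
            raise ValueError("pseudo-network needs >= 2 nodes")


@dataclass
class IndependenceReport:
    wcss: float
    wcss_upper_bound: float   # maximal interdependence (minimum WCSS)
    wcss_lower_bound: float   # maximal independence (maximum WCSS)
    pseudo_null: np.ndarray
    p_value: float
    score: float
    network: object = None
    extras: dict = field(default_factory=dict)


def cortex_windows_z(dyn) -> np.ndarray:
    """Fisher-z whole-cortex edge vectors of all non-censored windows."""
    return fisher_z(dyn.windows[dyn.valid_mask()][:, dyn.cortical_edge_columns()])


def contextual_centroids(cortex_windows: np.ndarray, assignments: np.ndarray) -> np.ndarray:
    """Per-state mean of Fisher-z whole-cortex windows (k x E_cortex)."""
    assignments = np.asarray(assignments)
    k = int(assignments.max()) + 1
    out = np.empty((k, cortex_windows.shape[1]))
    for s in range(k):
        mask = assignments == s
        if not mask.any():
            raise ValueError(f"state {s} has no windows")
        out[s] = cortex_windows[mask].mean(axis=0)
    return out


def wcss_error(cortex_windows: np.ndarray, centroids: np.ndarray) -> float:
    """Sum over windows of squared correlation distance to the nearest centroid.

    Zero-variance windows have undefined correlation distance and are
    skipped with a warning.
    """
    d = correlation_distance(cortex_windows, centroids)
    if np.isnan(d).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
            nearest = np.nanmin(d, axis=1)
    else:
        nearest = d.min(axis=1)
    bad = ~np.isfinite(nearest)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance windows skipped in WCSS")
        nearest = nearest[~bad]
    return float(np.sum(nearest**2))


def correlation_kmeans(X: np.ndarray, k: int, restarts: int = 10, seed: int = 0,
                       max_iter: int = 100):
    """K-means under squared correlation distance (assign by 1 - r, centroid
    = mean of members). Used for the maximal-interdependence anchor, where
    the fitted objective must be the scored objective.

    Returns (centroids, labels, objective).
    """
    X = np.asarray(X, dtype=float)
    W = X.shape[0]
    best = None
    for init in range(restarts):
        rng = spawn_rng(seed, 7, init)
        centers = X[rng.choice(W, size=k, replace=False)].copy()
        labels = None
        for _ in range(max_iter):
            d = correlation_distance(X, centers)
            new_labels = np.nanargmin(d, axis=1)
            for c in range(k):
                members = X[new_labels == c]
                if members.shape[0] == 0:
                    far = np.nanmin(d, axis=1).argmax()
                    centers[c] = X[far]
                    new_labels[far] = c
                else:
                    centers[c] = members.mean(axis=0)
            if labels is not None and np.array_equal(labels, new_labels):
                break
            labels = new_labels
        obj = wcss_error(X, centers)
        if best is None or obj < best[2]:
            best = (centers, labels, obj)
    return best


def subsystem_wcss(dyn, nodes, k: int, restarts: int = 10, seed: int = 0,
                   cortex_z: np.ndarray | None = None):
    """Fit k NC-states on a node subset's edges and score the cortex WCSS.

    Returns (wcss, model). ``nodes`` are indices into the dyn node order.
    """
    cols = edge_columns_for_nodes(np.asarray(nodes), dyn.n_nodes)
    win = dyn.windows[dyn.valid_mask()][:, cols]
    model = fit_ncstates(win, k, restarts=restarts, seed=seed)
    if cortex_z is None:
        cortex_z = cortex_windows_z(dyn)
    cents = contextual_centroids(cortex_z, model.assignments)
    return wcss_error(cortex_z, cents), model


def wcss_bounds(
    cortex_z: np.ndarray,
    k: int,
    network_assignments: np.ndarray,
    network_edge_columns_in_cortex: np.ndarray,
    network_state_centroids_z: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
):
    """(upper, lower) WCSS anchors for the independence score.

    upper: k-means on all cortical features under the scored objective
    (correlation distance, mean centroids). lower: hybrid centroids — the
    global time-averaged cortical vector everywhere except the network's own
    edge columns, which carry the network's NC-state centroids.
    """
    _, _, upper = correlation_kmeans(cortex_z, k, restarts=restarts, seed=seed)
    global_mean = cortex_z.mean(axis=0)
    hybrid = np.tile(global_mean, (k, 1))
    hybrid[:, network_edge_columns_in_cortex] = network_state_centroids_z
    lower = wcss_error(cortex_z, hybrid)
    _ = network_assignments  # labels are not needed under nearest-centroid scoring
    return upper, lower


def independence_score(wcss: float, upper: float, lower: float, pseudo_null) -> float:
    """Piecewise-linear map of WCSS onto [-1, +1] through the three anchors.

    upper -> -1 (maximal interdependence), pseudo-network mean -> 0,
    lower -> +1 (maximal independence). Values outside the anchors clamp
    with a warning.
    """
    pseudo_null = np.asarray(pseudo_null, dtype=float)
    if pseudo_null.size == 0:
        raise ValueError("pseudo_null must be non-empty")
    mid = pseudo_null.mean()
    if not (upper < mid < lower):
        if upper == mid or mid == lower:
            raise ValueError("degenerate score anchors (equal anchor points)")
    if wcss < upper or wcss > lower:
        warnings.warn("WCSS outside anchor interval; score clamped")
    if wcss <= mid:
        if mid == upper:
            raise ValueError("degenerate score anchors (upper == pseudo mean)")
        score = (wcss - mid) / (mid - upper)
    else:
        if lower == mid:
            raise ValueError("degenerate score anchors (pseudo mean == lower)")
        score = (wcss - mid) / (lower - mid)
    return float(np.clip(score, -1.0, 1.0))


def independence_test(canonical_wcss: float, pseudo_null) -> float:
    """+1-corrected permutation p for the 'more independent' (higher WCSS) direction."""
    pseudo_null = np.asarray(pseudo_null, dtype=float)
    if pseudo_null.size < 19:
        raise ValueError("need >= 19 pseudo-networks")
    return float((1 + np.sum(pseudo_null >= canonical_wcss)) / (pseudo_null.size + 1))


def draw_pseudo_networks(pool, size: int, n_pseudo: int, seed: int, k: int):
    rng = spawn_rng(seed, 99)
    pool = np.asarray(pool)
    return [PseudoNetwork(nodes=sorted(rng.choice(pool, size=size, replace=False).tolist()), k=k)
            for _ in range(n_pseudo)]


def network_independence(
    dyn,
    partition,
    network,
    k: int,
    n_pseudo: int = 1000,
    restarts: int = 10,
    seed: int = 0,
) -> IndependenceReport:
    """Full WCSS-based independence assay for one canonical network."""
    node_idx = [i for i, nid in enumerate(dyn.node_ids) if partition.assignment.get(nid) == network]
    cortex_nodes = np.nonzero(dyn.is_cortical)[0]
    cortex_z = cortex_windows_z(dyn)
    wcss, model = subsystem_wcss(dyn, node_idx, k, restarts=restarts, seed=seed, cortex_z=cortex_z)

    # network edge columns inside the cortex-edge vector
    local = {g: i for i, g in enumerate(cortex_nodes)}
    net_local = np.array([local[i] for i in node_idx])
    net_cols = edge_columns_for_nodes(net_local, cortex_nodes.size)
    upper, lower = wcss_bounds(
        cortex_z, k, model.assignments, net_cols, fisher_z(model.centroids),
        restarts=restarts, seed=seed + 1,
    )
    null = np.empty(n_pseudo)
    for b, pn in enumerate(draw_pseudo_networks(cortex_nodes, len(node_idx), n_pseudo, seed + 2, k)):
        null[b], _ = subsystem_wcss(dyn, pn.nodes, k, restarts=restarts, seed=seed + 3 + b,
                                    cortex_z=cortex_z)
    return IndependenceReport(
        wcss=wcss,
        wcss_upper_bound=upper,
        wcss_lower_bound=lower,
        pseudo_null=null,
        p_value=independence_test(wcss, null),
        score=independence_score(wcss, upper, lower, null),
        network=network,
    )


def mean_concordance_independence(assign_net, assign_cortex) -> tuple:
    """(mean positive, mean negative) finite concordance with cortex states.

    More interdependent subsystems show larger-magnitude positive and
    negative concordances with whole-cortex states. Returns NaN for a sign
    with no finite cells.
    """
    c = context_mod.concordance(assign_net, assign_cortex).C
    finite = c[np.isfinite(c)]
    pos = finite[finite > 0]
    neg = finite[finite < 0]
    mean_pos = float(pos.mean()) if pos.size else float("nan")
    mean_neg = float(neg.mean()) if neg.size else float("nan")
    return mean_pos, mean_neg


def find_interdependent_system(
    dyn,
    pool,
    n_pseudo: int = 1000,
    size: int = 8,
    k: int = 8,
    restarts: int = 5,
    seed: int = 0,
):
    """Two-step search for the maximally interdependent (INT) node set.

    Step 1: draw ``n_pseudo`` pseudo-networks from the full pool, score
    their WCSS, and tally how often each node appears in the lowest-WCSS
    quintile. Step 2: restrict the pool to nodes with above-median tally,
    redraw ``n_pseudo`` pseudo-networks, and return the minimum-WCSS one.
    """
    if n_pseudo < 5:
        raise ValueError("n_pseudo must be >= 5 for a quintile")
    pool = np.asarray(pool)
    cortex_z = cortex_windows_z(dyn)

    def score_batch(p, base_seed):
        pns = draw_pseudo_networks(p, size, n_pseudo, base_seed, k)
        w = np.empty(n_pseudo)
        for b, pn in enumerate(pns):
            w[b], _ = subsystem_wcss(dyn, pn.nodes, k, restarts=restarts,
                                     seed=base_seed + 31 * b, cortex_z=cortex_z)
        return pns, w

    pns, wcss = score_batch(pool, seed)
    n_bottom = int(np.ceil(n_pseudo / 5))
    bottom = np.argsort(wcss)[:n_bottom]
    tally = {int(nidx): 0 for nidx in pool}
    for b in bottom:
        for nidx in pns[b].nodes:
            tally[int(nidx)] += 1
    counts = np.array([tally[int(nidx)] for nidx in pool])
    restricted = pool[counts > np.median(counts)]
    if restricted.size < size:
        # small-tally degeneracy: fall back to a non-strict cut
        warnings.warn(
            "above-median tally leaves too few nodes; relaxing to >= median"
        )
        restricted = pool[counts >= np.median(counts)]
    if restricted.size < size:
        raise ValueError(
            f"restricted pool ({restricted.size} nodes) smaller than requested size {size}"
        )
    pns2, wcss2 = score_batch(restricted, seed + 1_000_003)
    best = int(np.argmin(wcss2))
    int_nodes = pns2[best].nodes
    _, _, upper = correlation_kmeans(cortex_z, k, restarts=restarts, seed=seed + 5)
    report = IndependenceReport(
        wcss=float(wcss2[best]),
        wcss_upper_bound=upper,
        wcss_lower_bound=float("nan"),
        pseudo_null=wcss,
        p_value=float((1 + np.sum(wcss <= wcss2[best])) / (wcss.size + 1)),
        score=float("nan"),
        network="INT",
        extras={"tally": tally, "restricted_pool": restricted.tolist(),
                "restricted_wcss": wcss2},
    )
    return int_nodes, report
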