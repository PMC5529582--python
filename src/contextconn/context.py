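"""Whole-brain connectivity contexts (WBCCs) and state concordance.

A WBCC characterizes the global connectomic environment of one NC-state:
the community-allegiance matrix over all windows in which the state is
present, plus a contextual centroid (the inverse-Fisher of the mean
Fisher-z whole-cortex edge vector over those windows). Allegiance derives
from multilayer (time-coupled) Louvain community detection: entry (i, j) is
the probability that nodes i and j share a community label across the
selected windows.

Concordance quantifies temporal coupling of two state sequences:

    C(A_i, B_j) = ln( P(A_i | B_j) / P(A_i) )

zero-centred so 0 is chance, positive means states co-occur more often than
chance. Significance is assessed against three nulls (cross-subject
permutation, Markov simulation, circular shift); a cell counts as
significant only if significant under all three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg as la
import numpy as np

from . import nulls
from ._utils import fisher_z, fisher_z_inverse, pair_index, square_from_vec


@dataclass
class MultilayerLabels:
    """Per-subject node x window community labels from multilayer detection."""

    labels: dict  # subject -> (N, W_subject) int array over non-censored windows
    gamma: float
    omega: float

    def concatenated(self, subjects=None) -> np.ndarray:
        subs = subjects if subjects is not None else list(self.labels)
        return np.concatenate([self.labels[s] for s in subs], axis=1)


@dataclass
class AllegianceMatrix:
    """Co-assignment probability per node pair over a window set."""

    A: np.ndarray
    n_windows: int

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)


@dataclass
class WBCC:
    """Whole-brain connectivity context of one NC-state."""

    state: tuple  # (network, state index)
    allegiance: AllegianceMatrix
    contextual_centroid: np.ndarray  # cortical edge vector (r units)
    n_windows: int


@dataclass
class ConcordanceMatrix:
    C: np.ndarray              # k_a x k_b, natural-log units; NaN where joint count 0
    counts: np.ndarray         # joint co-occurrence table
    significant: np.ndarray | None = None


def _window_graph(vec: np.ndarray, n: int) -> ig.Graph:
    mat = square_from_vec(vec, n, diag=0.0)
    mat[mat < 0] = 0.0
    i, j = pair_index(n)
    keep = mat[i, j] > 0
    g = ig.Graph(n)
    g.vs["id"] = list(range(n))  # aligns nodes across layers
    g.add_edges(list(zip(i[keep].tolist(), j[keep].tolist())))
    g.es["weight"] = mat[i, j][keep].tolist()
    return g


def multilayer_communities(dyn, gamma: float = 1.0, omega: float = 1.0, seed: int = 0) -> MultilayerLabels:
    """Time-coupled Louvain-like community labels for every node and window.

    Each subject's non-censored windows form the ordered layers of a
    multilayer network (negative edges zeroed); consecutive layers are
    coupled with uniform weight ``omega``. Larger omega yields temporally
    smoother community membership.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    n = dyn.n_nodes
    labels = {}
    for s in dyn.subjects():
        rows = dyn.subject_rows(s)
        rows = rows[~dyn.censored[rows]]
        graphs = [_window_graph(dyn.windows[r], n) for r in rows]
        memberships, _ = la.find_partition_temporal(
            graphs,
            la.RBConfigurationVertexPartition,
            interslice_weight=omega,
            resolution_parameter=gamma,
            seed=int(seed) % (2**31 - 1),
        )
        labels[s] = np.asarray(memberships).T  # (N, W_subject)
    return MultilayerLabels(labels=labels, gamma=gamma, omega=omega)


def allegiance(labels: MultilayerLabels, window_mask=None, subjects=None) -> AllegianceMatrix:
    """Exact co-assignment frequency over the selected (pooled) windows."""
    lab = labels.concatenated(subjects)
    if window_mask is not None:
        window_mask = np.asarray(window_mask, dtype=bool)
        lab = lab[:, window_mask]
    if lab.shape[1] == 0:
        raise ValueError("empty window selection")
    n, w = lab.shape
    co = np.zeros((n, n))
    for t in range(w):
        co += lab[:, t][:, None] == lab[:, t][None, :]
    a = co / w
    np.fill_diagonal(a, 1.0)
    return AllegianceMatrix(A=a, n_windows=w)


def wbcc_for_state(dyn, labels: MultilayerLabels, model, state: int) -> WBCC:
    """Allegiance + Fisher-z contextual centroid over one state's windows.

    ``model.assignments`` indexes the non-censored windows in subject
    concatenation order, matching the layer order used by
    :func:`multilayer_communities`.
    """
    mask = model.assignments == state
    if not mask.any():
        raise ValueError(f"state {state} of network {model.network!r} has no windows")
    alle = allegiance(labels, window_mask=mask)
    cort_cols = dyn.cortical_edge_columns()
    win = dyn.windows[dyn.valid_mask()][:, cort_cols]
    centroid = fisher_z_inverse(fisher_z(win[mask]).mean(axis=0))
    return WBCC(
        state=(model.network, state),
        allegiance=alle,
        contextual_centroid=centroid,
        n_windows=int(mask.sum()),
    )


def allegiance_displacement(wbcc: WBCC, baseline: AllegianceMatrix, partition, node_ids) -> np.ndarray:
    """Ratio of block-mean allegiance in a WBCC to the all-time baseline.

    Rows/columns follow ``partition.networks`` order; diagonal blocks are
    within-network means (self-pairs excluded). Zero baseline blocks yield
    NaN ("missing").
    """
    nets = partition.networks
    idx = {g: [i for i, nid in enumerate(node_ids) if partition.assignment.get(nid) == g] for g in nets}
    k = len(nets)
    out = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            ia, ib = idx[nets[a]], idx[nets[b]]
            if not ia or not ib:
                continue
            blk_w = wbcc.allegiance.A[np.ix_(ia, ib)]
            blk_b = baseline.A[np.ix_(ia, ib)]
            if a == b:
                if len(ia) < 2:
                    continue
                off = ~np.eye(len(ia), dtype=bool)
                num, den = blk_w[off].mean(), blk_b[off].mean()
            else:
                num, den = blk_w.mean(), blk_b.mean()
            if den > 0:
                out[a, b] = num / den
    return out


def concordance(assign_a, assign_b) -> ConcordanceMatrix:
    """Empirical C(A_i, B_j) = ln(P(A_i|B_j)/P(A_i)) over aligned windows.

    Cells with zero joint count are NaN (excluded from summaries) rather
    than -inf.
    """
    a = np.asarray(assign_a)
    b = np.asarray(assign_b)
    if a.size != b.size:
        raise ValueError(f"sequence lengths differ: {a.size} vs {b.size}")
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    counts = np.zeros((ka, kb))
    np.add.at(counts, (a, b), 1.0)
    w = a.size
    p_a = counts.sum(axis=1) / w
    n_b = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = counts / n_b[None, :]
        c = np.log(p_cond / p_a[:, None])
    c[counts == 0] = np.nan
    return ConcordanceMatrix(C=c, counts=counts)


def _pool(assignments: dict) -> np.ndarray:
    return np.concatenate([np.asarray(v) for v in assignments.values()])


def concordance_significance(
    assign_a: dict,
    assign_b: dict,
    n_reps: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> ConcordanceMatrix:
    """Per-cell two-sided tests against three sequence nulls (intersection rule).

    ``assign_a``/``assign_b`` are dicts subject -> aligned state sequence.
    Null models: (1) permute network-A sequences across subjects, (2)
    simulate network-A sequences from their fitted Markov chain, (3)
    circularly shift network-A sequences. Each cell's p-value per null is
    the +1-corrected two-sided empirical p; the cell is significant iff
    p <= alpha under all three nulls.
    """
    obs = concordance(_pool(assign_a), _pool(assign_b))
    ka, kb = obs.C.shape
    if len(assign_a) < 2:
        warnings.warn("single subject: cross-subject permutation null skipped")
        null_fns = [nulls.markov_simulate, nulls.circular_shift]
    else:
        null_fns = [nulls.permute_across_subjects, nulls.markov_simulate, nulls.circular_shift]
    sig = np.ones((ka, kb), dtype=bool)
    pooled_b = _pool(assign_b)
    for fn_idx, fn in enumerate(null_fns):
        exceed = np.zeros((ka, kb))
        valid = np.zeros((ka, kb))
        for rep in range(n_reps):
            surr = fn(assign_a, seed=seed + 7919 * fn_idx + rep)
            c_null = concordance(_pool(surr), pooled_b).C
            both = np.isfinite(c_null) & np.isfinite(obs.C)
            exceed[both] += np.abs(c_null[both]) >= np.abs(obs.C[both])
            valid += both
        with np.errstate(invalid="ignore"):
            p = (1.0 + exceed) / (valid + 1.0)
        p[~np.isfinite(obs.C)] = 1.0
        sig &= p <= alpha
    sig[~np.isfinite(obs.C)] = False
    return ConcordanceMatrix(C=obs.C, counts=obs.counts, significant=sig)
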