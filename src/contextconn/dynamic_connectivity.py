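"""Tapered sliding-window connectivity as regularized-precision partial correlations.

Each window applies a taper (a unit rectangle convolved with a Gaussian) to
the samples it covers, computes the taper-weighted covariance, and estimates
a sparse inverse covariance by L1-penalized maximum likelihood (graphical
lasso). Edge weights are the partial correlations

    rho_ij = -P_ij / sqrt(P_ii * P_jj)

so every entry is bounded in (-1, 1). The regularization is what makes the
estimate well-posed when a window holds fewer observations than the
connectome has edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from sklearn.covariance import graphical_lasso

from ._utils import edge_columns_for_nodes, pair_index


@dataclass
class WindowSpec:
    """Sliding-window geometry: length and step in seconds, taper sigma in samples."""

    length_s: float = 44.64
    step_s: float = 0.72
    tr: float = 0.72
    taper_sigma_samples: float = 3.0

    def __post_init__(self):
        ratio = self.length_s / self.tr
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"length_s/tr must be an integer, got {ratio}")
        step = self.step_s / self.tr
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError(f"step_s/tr must be a positive integer, got {step}")

    @property
    def length_samples(self) -> int:
        return round(self.length_s / self.tr)

    @property
    def step_samples(self) -> int:
        return round(self.step_s / self.tr)


@dataclass
class DynamicConnectome:
    """Window-by-edge partial-correlation matrix with provenance and censoring.

    ``windows`` is W_total x E_total in the shared lexicographic pair order;
    ``provenance`` lists (subject, start_sample) per row; ``censored`` marks
    rows excluded from downstream statistics (kept in place so window
    indexing stays aligned with provenance).
    """

    windows: np.ndarray
    provenance: list
    censored: np.ndarray
    node_ids: list
    is_cortical: np.ndarray
    spec: WindowSpec
    lam: float

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.is_cortical = np.asarray(self.is_cortical, dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def subjects(self) -> list:
        seen = []
        for s, _ in self.provenance:
            if s not in seen:
                seen.append(s)
        return seen

    def subject_rows(self, subject) -> np.ndarray:
        return np.array([i for i, (s, _) in enumerate(self.provenance) if s == subject])

    def valid_mask(self) -> np.ndarray:
        return ~self.censored

    def cortical_edge_columns(self) -> np.ndarray:
        return edge_columns_for_nodes(np.nonzero(self.is_cortical)[0], self.n_nodes)


def make_taper(spec: WindowSpec) -> np.ndarray:
    """Rectangle-convolved-with-Gaussian taper, truncated to the window length.

    The discrete convolution of a unit rectangle of ``length_samples`` with a
    centred Gaussian kernel is evaluated at the window's sample positions and
    normalized to sum 1; the result is symmetric (palindromic).
    """
    L = spec.length_samples
    if L < 3:
        raise ValueError("window must span at least 3 samples")
    sigma = spec.taper_sigma_samples
    if sigma <= 0:
        raise ValueError("taper_sigma_samples must be > 0")
    # Conv of rect with Gaussian kernel, sampled on the window support.
    half = int(np.ceil(6 * sigma))
    k = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (k / sigma) ** 2)
    kern /= kern.sum()
    w = np.convolve(np.ones(L), kern, mode="same")
    return w / w.sum()


def _weighted_correlation(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Taper-weighted correlation matrix of an (L, N) window."""
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    d = np.sqrt(np.diag(cov))
    d[d < 1e-15] = 1.0
    return cov / np.outer(d, d)


def _partials_from_precision(prec: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(prec))
    rho = -prec / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def precision_to_partials(prec: np.ndarray) -> np.ndarray:
    """Partial correlations -P_ij / sqrt(P_ii P_jj), unit diagonal."""
    return _partials_from_precision(prec)


def _window_partials(corr: np.ndarray, lam: float, tol: float, max_iter: int) -> np.ndarray:
    if lam <= 0:
        return _partials_from_precision(pinvh(corr))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, prec = graphical_lasso(corr, alpha=lam, tol=tol, max_iter=max_iter)
    return _partials_from_precision(prec)


def windowed_partial_correlations(
    ts,
    spec: WindowSpec,
    lam: float = 0.1,
    censor=None,
    tol: float = 5e-3,
    max_iter: int = 200,
) -> DynamicConnectome:
    """Estimate per-window partial correlations for every subject.

    Windows are placed every ``step_samples`` within each subject (never
    spanning subjects). A window that fails to converge is retried with the
    penalty doubled; if that also fails it is marked censored with a warning.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    L = spec.length_samples
    step = spec.step_samples
    taper = make_taper(spec)
    n = ts.n_nodes
    i_idx, j_idx = pair_index(n)
    rows, prov, cens = [], [], []
    for s in ts.subjects:
        mat = ts.data[s]
        t = mat.shape[0]
        if t < L:
            raise ValueError(f"subject {s}: T={t} shorter than window ({L})")
        starts = np.arange(0, t - L + 1, step)
        sub_censor = None
        if censor is not None:
            sub_censor = censor.censored[s]
        for wi, st in enumerate(starts):
            prov.append((s, int(st)))
            if sub_censor is not None and sub_censor[wi]:
                rows.append(np.zeros(i_idx.size))
                cens.append(True)
                continue
            corr = _weighted_correlation(mat[st : st + L], taper)
            try:
                rho = _window_partials(corr, lam, tol, max_iter)
            except FloatingPointError:
                rho = None
            if rho is None or not np.all(np.isfinite(rho)):
                try:
                    rho = _window_partials(corr, max(2 * lam, 0.02), tol, max_iter)
                except FloatingPointError:
                    rho = None
            if rho is None or not np.all(np.isfinite(rho)):
                warnings.warn(f"subject {s}, window at {st}: estimation failed; censored")
                rows.append(np.zeros(i_idx.size))
                cens.append(True)
                continue
            rows.append(rho[i_idx, j_idx])
            cens.append(False)
    return DynamicConnectome(
        windows=np.asarray(rows),
        provenance=prov,
        censored=np.asarray(cens),
        node_ids=list(ts.node_ids),
        is_cortical=ts.is_cortical.copy(),
        spec=spec,
        lam=lam,
    )


def extract_network_windows(dyn: DynamicConnectome, partition, network) -> np.ndarray:
    """Within-network edge columns of all non-censored windows.

    Returns a W_valid x C(k, 2) matrix for a k-node network; the edge order
    is lexicographic in node index, consistent with the global pair order.
    """
    nodes = [i for i, nid in enumerate(dyn.node_ids) if partition.assignment.get(nid) == network]
    if not nodes:
        raise KeyError(f"network {network!r} not present in partition")
    if len(nodes) < 2:
        raise ValueError(f"network {network!r} has a single node: no edges")
    cols = edge_columns_for_nodes(np.array(nodes), dyn.n_nodes)
    return dyn.windows[dyn.valid_mask()][:, cols]


def network_edge_columns(dyn: DynamicConnectome, partition, network) -> np.ndarray:
    nodes = [i for i, nid in enumerate(dyn.node_ids) if partition.assignment.get(nid) == network]
    return edge_columns_for_nodes(np.array(nodes), dyn.n_nodes)


def edge_timeseries(dyn: DynamicConnectome, subject) -> np.ndarray:
    """E_total x W_subject edge-weight timeseries (censored windows dropped)."""
    rows = dyn.subject_rows(subject)
    if rows.size == 0:
        raise KeyError(f"unknown subject {subject!r}")
    keep = rows[~dyn.censored[rows]]
    return dyn.windows[keep].T


def expected_window_count(t: int, spec: WindowSpec) -> int:
    return (t - spec.length_samples) // spec.step_samples + 1


def write_dynamic_connectome(prefix, dyn: DynamicConnectome):
    """Persist windows plus provenance as a TSV pair (``<prefix>.tsv``, ``<prefix>.prov.tsv``)."""
    n = dyn.n_nodes
    i_idx, j_idx = pair_index(n)
    cols = [f"{i}_{j}" for i, j in zip(i_idx, j_idx)]
    pd.DataFrame(dyn.windows, columns=cols).to_csv(f"{prefix}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "subject": [s for s, _ in dyn.provenance],
            "start_sample": [st for _, st in dyn.provenance],
            "censored": dyn.censored.astype(int),
        }
    ).to_csv(f"{prefix}.prov.tsv", sep="\t", index=False)
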