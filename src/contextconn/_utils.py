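"""Shared helpers: edge-pair indexing, Fisher transforms, seeded RNG streams."""

from __future__ import annotations

import numpy as np

_FISHER_CLIP = 1.0 - 1e-7


def pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the unique node pairs (i < j), lexicographic.

    This ordering is the single source of truth for edge vectorization
    everywhere in the package: edge column ``e`` of any W x E matrix refers
    to the pair ``(pair_index(n)[0][e], pair_index(n)[1][e])``.
    """
    return np.triu_indices(n, k=1)


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def vectorize_sym(mat: np.ndarray) -> np.ndarray:
    """Upper-triangle (i < j) vector of a symmetric matrix, pair order."""
    i, j = pair_index(mat.shape[-1])
    return mat[..., i, j]


def square_from_vec(vec: np.ndarray, n: int, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_sym` with a fixed diagonal."""
    out = np.full((n, n), 0.0)
    i, j = pair_index(n)
    out[i, j] = vec
    out[j, i] = vec
    np.fill_diagonal(out, diag)
    return out


def edge_columns_for_nodes(nodes: np.ndarray, n: int) -> np.ndarray:
    """Edge-vector column indices of all pairs internal to ``nodes``.

    ``nodes`` are indices into the 0..n-1 node order that defines the global
    pair order.
    """
    nodes = np.asarray(sorted(nodes))
    i_all, j_all = pair_index(n)
    mask = np.isin(i_all, nodes) & np.isin(j_all, nodes)
    return np.nonzero(mask)[0]


def fisher_z(r: np.ndarray) -> np.ndarray:
    """arctanh with clipping so |r| -> 1 maps to a large finite z."""
    return np.arctanh(np.clip(r, -_FISHER_CLIP, _FISHER_CLIP))


def fisher_z_inverse(z: np.ndarray) -> np.ndarray:
    return np.tanh(z)


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent RNG stream derived from a base seed and integer keys."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def correlation_distance(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows of ``x`` (W x E) and rows of ``c`` (k x E).

    Rows with zero variance yield NaN distances (caller decides policy).
    """
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    cn = np.linalg.norm(cc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ cc.T) / np.outer(xn, cn)
    return 1.0 - r
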