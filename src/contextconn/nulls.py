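"""Surrogate and null-model generators.

Three families of nulls are used across the package:

* **Phase randomization** of edge-weight timeseries — preserves each
  series' amplitude spectrum (hence mean and variance) while destroying
  cross-series covariance structure.
* **Observation permutation** — shuffles each variable (edge column)
  independently, preserving marginal distributions while removing all
  inter-variable relations; used to validate clustering.
* **State-sequence nulls** for concordance testing: permutation of whole
  subject sequences across subjects, first-order Markov simulation from the
  observed transition matrix and initial states, and circular shifting of
  each subject's sequence. Each preserves a different aspect of the observed
  sequences while destroying moment-to-moment coupling between networks.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

import numpy as np

from ._utils import spawn_rng


def phase_randomize(series: np.ndarray, columns=None, seed: int = 0) -> np.ndarray:
    """Randomize Fourier phases of selected rows of an E x W matrix.

    Each selected row is Fourier transformed, its phases replaced by i.i.d.
    uniform phases under conjugate symmetry (DC and Nyquist bins stay real),
    and inverse transformed. Unselected rows are returned untouched.
    """
    series = np.asarray(series, dtype=float)
    single = series.ndim == 1
    if single:
        series = series[None, :]
    e, w = series.shape
    if w < 4:
        raise ValueError("need at least 4 time points")
    rows = np.arange(e) if columns is None else np.asarray(columns, dtype=int)
    out = series.copy()
    rng = spawn_rng(seed, 11)
    if rows.size:
        spec = np.fft.rfft(series[rows], axis=1)
        n_bins = spec.shape[1]
        # DC and (for even length) Nyquist bins must stay real: keep their
        # original phases (0 or pi) so means and signs are preserved exactly
        phases = rng.uniform(0, 2 * np.pi, size=(rows.size, n_bins))
        phases[:, 0] = np.angle(spec[:, 0])
        if w % 2 == 0:
            phases[:, -1] = np.angle(spec[:, -1])
        out[rows] = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=w, axis=1)
    return out[0] if single else out


def permute_observations(matrix: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently shuffle each column of a W x E matrix."""
    matrix = np.asarray(matrix)
    rng = spawn_rng(seed, 22)
    out = np.empty_like(matrix)
    for col in range(matrix.shape[1]):
        out[:, col] = matrix[rng.permutation(matrix.shape[0]), col]
    return out


def _as_subject_dict(assignments) -> dict:
    if not isinstance(assignments, dict):
        raise TypeError("assignments must be a dict subject -> state sequence")
    return {s: np.asarray(v) for s, v in assignments.items()}


def permute_across_subjects(assignments: dict, seed: int = 0) -> dict:
    """Reassign whole state sequences to subjects by a random permutation.

    Within-sequence order is untouched; requires equal per-subject lengths
    (align sequences to the intersection of non-censored windows upstream).
    """
    seqs = _as_subject_dict(assignments)
    subjects = list(seqs)
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    lengths = {s: v.size for s, v in seqs.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"per-subject lengths differ: {lengths}")
    rng = spawn_rng(seed, 33)
    perm = rng.permutation(len(subjects))
    return {subjects[i]: seqs[subjects[j]].copy() for i, j in enumerate(perm)}


def estimate_transition_matrix(assignments: dict, n_states: int | None = None):
    """Pooled ML first-order transition matrix and state list.

    A state with no observed outgoing transition receives a self-loop.
    """
    seqs = _as_subject_dict(assignments)
    if n_states is None:
        n_states = int(max(int(np.max(v)) for v in seqs.values())) + 1
    counts = np.zeros((n_states, n_states))
    for v in seqs.values():
        np.add.at(counts, (v[:-1], v[1:]), 1.0)
    rowsum = counts.sum(axis=1)
    for s in range(n_states):
        if rowsum[s] == 0:
            counts[s, s] = 1.0
            rowsum[s] = 1.0
    return counts / rowsum[:, None]


def markov_simulate(assignments: dict, seed: int = 0, per_subject: bool = False) -> dict:
    """Simulate each subject's sequence from the fitted first-order chain.

    Initial states match the observed initial states exactly; transition
    probabilities are pooled across subjects unless ``per_subject``.
    """
    seqs = _as_subject_dict(assignments)
    rng = spawn_rng(seed, 44)
    out = {}
    pooled = None if per_subject else estimate_transition_matrix(seqs)
    for s, v in seqs.items():
        P = estimate_transition_matrix({s: v}) if per_subject else pooled
        n_states = P.shape[0]
        sim = np.empty(v.size, dtype=v.dtype)
        sim[0] = v[0]
        for t in range(1, v.size):
            sim[t] = rng.choice(n_states, p=P[sim[t - 1]])
        out[s] = sim
    return out


def circular_shift(assignments: dict, seed: int = 0) -> dict:
    """Rotate each subject's sequence by an independent uniform offset.

    The categorical analogue of a random phase shift: marginal state
    frequencies and (up to one wrap-around) within-subject transition
    structure are preserved, while alignment with any other sequence is
    randomized.
    """
    seqs = _as_subject_dict(assignments)
    rng = spawn_rng(seed, 55)
    return {s: np.roll(v, int(rng.integers(0, v.size))) for s, v in seqs.items()}
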