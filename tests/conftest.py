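"""Shared fixtures: session-scoped synthetic datasets and their dynamic connectomes.

The default fixture matches the package's desk-scale study conditions
(3 networks x 12 cortical nodes, 6 subjects x 2000 samples, 62-sample
window stepped by 6); the hub fixture adds the 8-node interdependent hub
block at a smaller size. Both are computed once per session because the
per-window graphical lasso dominates runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from contextconn import synthetic
from contextconn.dynamic_connectivity import WindowSpec, windowed_partial_correlations
from contextconn.static_connectome import NetworkPartition

DESK_WINDOW = dict(length_s=44.64, step_s=4.32, tr=0.72, taper_sigma_samples=3.0)


@pytest.fixture(scope="session")
def window_spec():
    return WindowSpec(**DESK_WINDOW)


@pytest.fixture(scope="session")
def default_fixture(window_spec):
    spec = synthetic.default_spec(seed=0)
    ts, motion, truth = synthetic.generate(spec)
    dyn = windowed_partial_correlations(ts, window_spec, lam=0.1)
    partition = NetworkPartition(assignment=truth.partition)
    window_labels = truth.window_labels(window_spec.length_samples, window_spec.step_samples)
    return dict(
        spec=spec, ts=ts, motion=motion, truth=truth, dyn=dyn,
        partition=partition, window_labels=window_labels,
    )


@pytest.fixture(scope="session")
def hub_fixture(window_spec):
    spec = synthetic.default_spec(seed=0, hubs=True, n_subjects=4, T=1200)
    ts, motion, truth = synthetic.generate(spec)
    dyn = windowed_partial_correlations(ts, window_spec, lam=0.1)
    partition = NetworkPartition(assignment=truth.partition)
    return dict(spec=spec, ts=ts, truth=truth, dyn=dyn, partition=partition)


@pytest.fixture(scope="session")
def planted_sequences(default_fixture):
    """Planted per-network window-label sequences, concatenated across subjects."""
    ts = default_fixture["ts"]
    wl = default_fixture["window_labels"]
    return {
        key: np.concatenate([wl[s][key] for s in ts.subjects])
        for key in ["net0", "net1", "net2", "global"]
    }


@pytest.fixture(scope="session")
def small_dyn():
    """A small two-block dynamic connectome for multilayer/context tests."""
    spec = synthetic.SyntheticSpec(
        n_subjects=1,
        T=400,
        networks={"a": 6, "b": 6},
        n_subcortical=0,
        k_per_network={"a": 2, "b": 2},
        transition={g: np.array([[0.5, 0.5], [0.5, 0.5]]) for g in ("a", "b")},
        state_levels={g: [0.35, 0.7] for g in ("a", "b")},
        state_subblocks={g: [1, 2] for g in ("a", "b")},
        state_block_samples=80,
        seed=3,
    )
    ts, motion, truth = synthetic.generate(spec)
    ws = WindowSpec(length_s=28.8, step_s=7.2, tr=0.72, taper_sigma_samples=3.0)
    dyn = windowed_partial_correlations(ts, ws, lam=0.05)
    return dict(spec=spec, ts=ts, truth=truth, dyn=dyn, ws=ws)
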