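"""Ground-truthed synthetic multistable timeseries.

The generator emulates the statistical structure the pipeline is built to
detect: multivariate Gaussian node signals with planted block (network)
community structure, hidden-Markov switching of each network's within-block
correlation level (its connectivity state), optional temporal coupling
between specific state pairs of two networks, optional "hub" nodes whose
coupling to every network tracks that network's current state, and a
framewise-displacement trace with motion bursts.

The observation model is a per-block factor model. Each (network, state)
template splits the network's nodes into one or more contiguous sub-blocks;
node i inside a sub-block with factor f during network state s is

    x_i(t) = sqrt(w_{g,s}) f(t) + sqrt(b) c(t) [+ coupling/hub terms]
             + residual + measurement noise

with c a weak global factor and all factor loadings chosen so each node has
(near-)unit variance. Within-sub-block correlation during state s is
w_{g,s}; states differ both in cohesion level and in topology (how many
sub-blocks the network fractionates into), which is what makes them
distinguishable in the partial-correlation domain — equicorrelated blocks
differing only in level produce nearly identical partial correlations. The
factor construction guarantees a positive semi-definite covariance for any
admissible loading set, and the spec is rejected if any state combination
would demand negative residual variance.

States are constant over blocks of ``state_block_samples`` samples (at
least one window length) so that sliding windows are not systematically
mixing states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import spawn_rng
from .timeseries_io import MotionTrace, NodeTimeseriesSet


@dataclass
class Coupling:
    """Temporal + correlation coupling between one state pair of two networks.

    Whenever network_a enters ``state_a``, network_b is pulled into
    ``state_b`` with probability ``sync``; while the pair is co-active, a
    shared factor adds ``corr_boost`` between-block correlation.
    """

    network_a: str
    state_a: int
    network_b: str
    state_b: int
    corr_boost: float = 0.25
    sync: float = 0.8


@dataclass
class SyntheticSpec:
    n_subjects: int = 6
    tr: float = 0.72
    T: int = 2000
    networks: dict = field(default_factory=dict)        # label -> node count
    n_subcortical: int = 4
    k_per_network: dict = field(default_factory=dict)   # label -> state count
    transition: dict = field(default_factory=dict)      # label -> (k, k) row-stochastic
    state_levels: dict = field(default_factory=dict)    # label -> per-state within-sub-block corr
    state_subblocks: dict = field(default_factory=dict)  # label -> per-state sub-block count
    baseline_between: float = 0.05
    # global integration/segregation mode: during the integrated state a
    # planted random cross-network node matching carries pairwise factors
    global_pair_strength: float = 0.0
    global_transition: object = None   # 2x2 row-stochastic; None disables
    couplings: list = field(default_factory=list)
    hub_nodes: int = 0          # appended cortical nodes loading on every network
    hub_strength: float = 0.1   # per-network loading scale for hub nodes
    hub_pair_strength: float = 0.7  # loading of the reconfiguring hub pair factors
    state_block_samples: int = 124
    noise_sd: float = 0.1
    fd_baseline_sd: float = 0.04
    fd_spike_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if not self.networks:
            raise ValueError("at least one network required")
        for g, k in self.k_per_network.items():
            P = np.asarray(self.transition[g], dtype=float)
            if P.shape != (k, k) or not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError(f"network {g}: transition matrix must be {k}x{k} row-stochastic")
            levels = self.state_levels[g]
            if len(levels) != k or not all(0 <= w < 1 for w in levels):
                raise ValueError(f"network {g}: need {k} within-block levels in [0, 1)")
            if g not in self.state_subblocks:
                self.state_subblocks[g] = [1] * k
            if len(self.state_subblocks[g]) != k or any(
                not (1 <= c <= self.networks[g]) for c in self.state_subblocks[g]
            ):
                raise ValueError(f"network {g}: need {k} valid sub-block counts")
        self._validate_variance_budget()

    def _validate_variance_budget(self):
        """Reject any state combination demanding negative residual variance."""
        for g in self.networks:
            for s, w in enumerate(self.state_levels[g]):
                load = w + self.baseline_between
                for cpl in self.couplings:
                    if (cpl.network_a == g and cpl.state_a == s) or (
                        cpl.network_b == g and cpl.state_b == s
                    ):
                        load += cpl.corr_boost
                # integration loading adapts to the remaining budget, so only
                # the base load constrains positive-definiteness
                if load >= 1.0:
                    raise ValueError(
                        f"non-positive-definite assembly: network {g} state {s} "
                        f"total factor loading {load:.3f} >= 1"
                    )
        if self.hub_nodes:
            worst = sum(self.hub_strength * max(self.state_levels[g]) for g in self.networks)
            if self.global_transition is not None:
                worst += self.hub_pair_strength
            if worst + self.baseline_between >= 1.0 - 0.05:
                raise ValueError(
                    f"non-positive-definite assembly: hub loading {worst:.3f} too large"
                )

    # -- node layout -------------------------------------------------------
    def node_layout(self):
        """(node_ids, planted assignment dict, is_cortical array)."""
        node_ids, assignment, cortical = [], {}, []
        for g, size in self.networks.items():
            for i in range(size):
                nid = f"{g}_n{i:02d}"
                node_ids.append(nid)
                assignment[nid] = g
                cortical.append(True)
        for h in range(self.hub_nodes):
            nid = f"hub_n{h:02d}"
            node_ids.append(nid)
            assignment[nid] = "hub"
            cortical.append(True)
        for u in range(self.n_subcortical):
            nid = f"subcort_n{u:02d}"
            node_ids.append(nid)
            assignment[nid] = "subcortical"
            cortical.append(False)
        return node_ids, assignment, np.array(cortical, dtype=bool)


@dataclass
class GroundTruth:
    partition: dict                     # node_id -> planted label
    sample_states: dict                 # subject -> {network -> (T,) state per sample};
                                        # includes key "global" when the global mode is on
    couplings: list
    hub_node_ids: list
    global_groups: list = field(default_factory=list)  # integration groups (node indices)

    def window_labels(self, window_samples: int, step_samples: int = 1) -> dict:
        """Per-network planted label of each window (state at window centre)."""
        out = {}
        for s, per_net in self.sample_states.items():
            t = next(iter(per_net.values())).size
            starts = np.arange(0, t - window_samples + 1, step_samples)
            centre = starts + window_samples // 2
            out[s] = {g: seq[centre] for g, seq in per_net.items()}
        return out


def default_spec(seed: int = 0, hubs: bool = False, n_subjects: int = 6, T: int = 2000) -> SyntheticSpec:
    """Desk-scale study conditions: 3 networks x 12 nodes, 3 states each,
    one coupled state pair, optional 8-node hub set."""
    networks = {"net0": 12, "net1": 12, "net2": 12}
    k = {g: 3 for g in networks}
    P = np.full((3, 3), 0.3)
    np.fill_diagonal(P, 0.4)
    transition = {g: P.copy() for g in networks}
    # states differ in topology (fractionation) and cohesion level
    levels = {g: [0.25, 0.45, 0.65] for g in networks}
    subblocks = {g: [1, 2, 3] for g in networks}
    couplings = [Coupling("net0", 1, "net1", 1, corr_boost=0.15, sync=0.8)]
    return SyntheticSpec(
        n_subjects=n_subjects,
        T=T,
        networks=networks,
        k_per_network=k,
        transition=transition,
        state_levels=levels,
        state_subblocks=subblocks,
        global_pair_strength=0.45,
        global_transition=np.array([[0.7, 0.3], [0.3, 0.7]]),
        couplings=couplings,
        hub_nodes=8 if hubs else 0,
        hub_strength=0.08,
        seed=seed,
    )


def _simulate_states(spec: SyntheticSpec, rng) -> dict:
    """Blockwise Markov state sequences per network, with coupling sync."""
    n_blocks = int(np.ceil(spec.T / spec.state_block_samples))
    nets = list(spec.networks)
    seqs = {g: np.empty(n_blocks, dtype=int) for g in nets}
    for blk in range(n_blocks):
        for g in nets:
            k = spec.k_per_network[g]
            if blk == 0:
                seqs[g][blk] = rng.integers(k)
            else:
                seqs[g][blk] = rng.choice(k, p=np.asarray(spec.transition[g])[seqs[g][blk - 1]])
        for cpl in spec.couplings:
            if seqs[cpl.network_a][blk] == cpl.state_a and rng.random() < cpl.sync:
                seqs[cpl.network_b][blk] = cpl.state_b
    if spec.global_transition is not None:
        G = np.asarray(spec.global_transition, dtype=float)
        gseq = np.empty(n_blocks, dtype=int)
        for blk in range(n_blocks):
            gseq[blk] = rng.integers(2) if blk == 0 else rng.choice(2, p=G[gseq[blk - 1]])
        seqs["global"] = gseq
    per_sample = {}
    for g in seqs:
        expanded = np.repeat(seqs[g], spec.state_block_samples)[: spec.T]
        per_sample[g] = expanded
    return per_sample


def generate(spec: SyntheticSpec, seed: int | None = None):
    """Draw (NodeTimeseriesSet, MotionTrace, GroundTruth) from the spec."""
    seed = spec.seed if seed is None else seed
    node_ids, assignment, cortical = spec.node_layout()
    nets = list(spec.networks)
    n_nodes = len(node_ids)
    net_slices = {}
    offset = 0
    for g in nets:
        net_slices[g] = slice(offset, offset + spec.networks[g])
        offset += spec.networks[g]
    hub_slice = slice(offset, offset + spec.hub_nodes)
    offset += spec.hub_nodes

    # Planted expression of the global integration mode. Without hubs, the
    # two global states activate two different cross-network matchings (one
    # node per network per group): integration is a reconfiguration of
    # cross-network coupling, visible to any node subset that straddles
    # networks. With hubs, the mode is routed through the hub block instead:
    # each configuration partitions the hubs into groups whose shared-factor
    # strength is gated by a different canonical network's state, so hub-hub
    # edges jointly encode the global configuration AND the network states —
    # the planted analogue of a maximally interdependent subsystem.
    global_groups = []
    hub_groups = []      # per config: list of (member tuple, gate network)
    if spec.global_transition is not None and spec.global_pair_strength > 0:
        layout_rng = spawn_rng(seed, 0)
        if spec.hub_nodes >= 4:
            # hub_groups[config][gate_state] -> partition of the hub block;
            # the active partition depends on the global configuration and
            # on the state of that configuration's gate network
            hub_idx = np.arange(*hub_slice.indices(n_nodes))
            half = len(hub_idx) // 2
            for config in range(2):
                gate = nets[config % len(nets)]
                per_state = []
                for _s in range(spec.k_per_network[gate]):
                    order = layout_rng.permutation(hub_idx)
                    per_state.append([tuple(order[:half]), tuple(order[half:])])
                hub_groups.append((gate, per_state))
        else:
            for _config in range(2):
                per_net = [layout_rng.permutation(np.arange(sl.start, sl.stop)).tolist()
                           for sl in net_slices.values()]
                n_groups = min(len(lst) for lst in per_net)
                global_groups.append(
                    [tuple(lst.pop() for lst in per_net) for _ in range(n_groups)]
                )
    group_counts = []
    for config in range(len(global_groups)):
        c = np.zeros(n_nodes, dtype=int)
        for group in global_groups[config]:
            for node in group:
                c[node] += 1
        group_counts.append(c)

    data, fd, sample_states = {}, {}, {}
    for subj_idx in range(spec.n_subjects):
        subj = f"sub-{subj_idx:02d}"
        rng = spawn_rng(seed, 1, subj_idx)
        states = _simulate_states(spec, rng)
        sample_states[subj] = states
        x = np.empty((spec.T, n_nodes))
        t0 = 0
        while t0 < spec.T:
            t1 = min(t0 + spec.state_block_samples, spec.T)
            L = t1 - t0
            active = {g: int(states[g][t0]) for g in nets}
            g_factor = rng.standard_normal(L)
            blockx = np.zeros((n_nodes, L))
            resid_var = np.ones(n_nodes)
            b = spec.baseline_between
            blockx += np.sqrt(b) * g_factor[None, :]
            resid_var -= b
            for g in nets:
                s_g = active[g]
                w = spec.state_levels[g][s_g]
                n_sub = spec.state_subblocks[g][s_g]
                sl = net_slices[g]
                members = np.arange(sl.start, sl.stop)
                for chunk_idx, chunk in enumerate(np.array_split(members, n_sub)):
                    f_sub = rng.standard_normal(L)
                    blockx[chunk] += np.sqrt(w) * f_sub[None, :]
                    resid_var[chunk] -= w
                    if spec.hub_nodes and chunk_idx == 0:
                        v = spec.hub_strength * w
                        blockx[hub_slice] += np.sqrt(v) * f_sub[None, :]
                        resid_var[hub_slice] -= v
            for cpl in spec.couplings:
                if active[cpl.network_a] == cpl.state_a and active[cpl.network_b] == cpl.state_b:
                    shared = rng.standard_normal(L)
                    for sl in (net_slices[cpl.network_a], net_slices[cpl.network_b]):
                        blockx[sl] += np.sqrt(cpl.corr_boost) * shared[None, :]
                        resid_var[sl] -= cpl.corr_boost
            if global_groups:
                # integration: each cross-network group shares an additive
                # factor; a node contributes as much loading as its residual
                # variance budget allows (strongly cohesive states resist
                # integration), so within-network correlations are untouched
                p_max = spec.global_pair_strength
                config = int(states["global"][t0])
                remaining = group_counts[config].copy()
                for group in global_groups[config]:
                    fp = rng.standard_normal(L)
                    for node in group:
                        # budget split evenly across a node's group memberships
                        p_node = max(
                            0.0, min(p_max, (resid_var[node] - 0.05) / remaining[node])
                        )
                        blockx[node] += np.sqrt(p_node) * fp
                        resid_var[node] -= p_node
                        remaining[node] -= 1
            if hub_groups:
                config = int(states["global"][t0])
                gate, per_state = hub_groups[config]
                for members in per_state[active[gate]]:
                    # the active hub partition encodes (configuration, gate
                    # network state): hub-hub edges switch fully on/off
                    fp = rng.standard_normal(L)
                    for node in members:
                        p_node = max(
                            0.0, min(spec.hub_pair_strength, resid_var[node] - 0.05)
                        )
                        blockx[node] += np.sqrt(p_node) * fp
                        resid_var[node] -= p_node
            if np.any(resid_var <= 0):
                bad = node_ids[int(np.argmin(resid_var))]
                raise ValueError(f"negative residual variance at node {bad}")
            blockx += np.sqrt(resid_var)[:, None] * rng.standard_normal((n_nodes, L))
            x[t0:t1] = blockx.T
            t0 = t1
        x += spec.noise_sd * rng.standard_normal(x.shape)
        data[subj] = x
        # motion: folded-normal baseline plus burst-shaped spikes
        trace = np.abs(rng.normal(0, spec.fd_baseline_sd, size=spec.T))
        n_bursts = rng.poisson(spec.fd_spike_rate * spec.T)
        for _ in range(n_bursts):
            start = int(rng.integers(0, spec.T))
            dur = int(rng.geometric(0.05))
            amp = rng.lognormal(mean=np.log(0.3), sigma=0.4)
            trace[start : start + dur] += amp
        fd[subj] = trace

    ts = NodeTimeseriesSet(
        subjects=list(data),
        data=data,
        tr=spec.tr,
        node_ids=node_ids,
        is_cortical=cortical,
    )
    truth = GroundTruth(
        partition=assignment,
        sample_states=sample_states,
        couplings=list(spec.couplings),
        hub_node_ids=[node_ids[i] for i in range(*hub_slice.indices(n_nodes))],
        global_groups=global_groups,
    )
    return ts, MotionTrace(fd=fd), truth


def dwell_statistics(truth: GroundTruth, window_samples: int, step_samples: int = 1) -> dict:
    """Per-network mean dwell time (windows) and transition frequency.

    Computed by run-length encoding the planted per-window labels, pooled
    across subjects.
    """
    win = truth.window_labels(window_samples, step_samples)
    nets = list(next(iter(win.values())))
    out = {}
    for g in nets:
        runs, transitions, total = [], 0, 0
        for s in win:
            seq = win[s][g]
            change = np.nonzero(np.diff(seq) != 0)[0]
            bounds = np.concatenate([[-1], change, [seq.size - 1]])
            runs.extend(np.diff(bounds).tolist())
            transitions += change.size
            total += seq.size - 1
        out[g] = {
            "mean_dwell_windows": float(np.mean(runs)),
            "transition_frequency": float(transitions / total) if total else 0.0,
        }
    return out
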