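"""Node-timeseries I/O, preprocessing, and motion-based window censoring.

The package consumes parcel (node) timeseries as TSV — one column per node,
one row per sample by default — together with an optional framewise
displacement (FD) trace in millimetres. Preprocessing mirrors a standard
resting-state pipeline on parcel series: demean, detrend, despike, bandpass,
variance-normalize. Window censoring drops every sliding window whose mean
FD exceeds a threshold (default 0.18 mm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)


class TimeseriesFormatError(ValueError):
    """Malformed on-disk timeseries (ragged rows, non-numeric cells)."""


@dataclass
class NodeTimeseriesSet:
    """Per-subject node-by-time signal matrices with shared node metadata.

    Attributes
    ----------
    subjects : list of str
        Ordered subject identifiers.
    data : dict
        subject -> (T, N) float array. All subjects share N and tr.
    tr : float
        Sampling interval in seconds.
    node_ids : list of str
    is_cortical : (N,) bool array
        Cortical-node indicator; subcortical nodes are excluded from
        community detection and from cortex-edge analyses.
    """

    subjects: list
    data: dict
    tr: float
    node_ids: list
    is_cortical: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.node_ids)
        if self.is_cortical is None:
            self.is_cortical = np.ones(n, dtype=bool)
        self.is_cortical = np.asarray(self.is_cortical, dtype=bool)
        for s in self.subjects:
            mat = np.asarray(self.data[s], dtype=float)
            if mat.ndim != 2 or mat.shape[1] != n:
                raise ValueError(
                    f"subject {s}: expected T x {n} matrix, got {mat.shape}"
                )
            self.data[s] = mat

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[0]

    def cortical_indices(self) -> np.ndarray:
        return np.nonzero(self.is_cortical)[0]


@dataclass
class MotionTrace:
    """Per-subject framewise displacement, mm per sample (non-negative)."""

    fd: dict  # subject -> (T,) array

    def __post_init__(self):
        for s, v in self.fd.items():
            v = np.asarray(v, dtype=float)
            if np.any(v < 0):
                raise ValueError(f"subject {s}: FD must be non-negative")
            self.fd[s] = v


@dataclass
class CensorMask:
    """Per-subject boolean keep/censor flags, one per sliding window."""

    censored: dict  # subject -> (W,) bool, True = censored
    threshold_mm: float
    window_samples: int


def load_timeseries(
    path,
    orientation: str = "time-rows",
    tr: float = 0.72,
    subject: str = "sub-01",
    is_cortical=None,
) -> NodeTimeseriesSet:
    """Read a single-subject timeseries TSV.

    Parameters
    ----------
    orientation : {"time-rows", "node-rows"}
        On-disk layout. ``time-rows`` (default): header of node IDs, one row
        per sample. ``node-rows``: transpose, header of sample labels is
        absent and the first column holds node IDs.
    """
    if orientation not in ("time-rows", "node-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        if orientation == "time-rows":
            df = pd.read_csv(path, sep="\t")
            node_ids = [str(c) for c in df.columns]
            mat = df.to_numpy(dtype=float)
        else:
            df = pd.read_csv(path, sep="\t", header=None, index_col=0)
            node_ids = [str(c) for c in df.index]
            mat = df.to_numpy(dtype=float).T
    except pd.errors.ParserError as exc:
        raise TimeseriesFormatError(f"{path}: ragged or malformed TSV: {exc}") from exc
    except ValueError as exc:
        raise TimeseriesFormatError(f"{path}: non-numeric cell: {exc}") from exc
    bad = ~np.isfinite(mat)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise TimeseriesFormatError(
            f"{path}: non-numeric or missing value at data row {r}, column "
            f"{node_ids[c]!r}"
        )
    return NodeTimeseriesSet(
        subjects=[subject],
        data={subject: mat},
        tr=tr,
        node_ids=node_ids,
        is_cortical=is_cortical,
    )


def load_timeseries_set(paths: dict, tr: float, orientation="time-rows", is_cortical=None):
    """Read several subjects (subject -> path) into one set; nodes must match."""
    sets = {
        s: load_timeseries(p, orientation=orientation, tr=tr, subject=s)
        for s, p in paths.items()
    }
    subjects = list(paths)
    first = sets[subjects[0]]
    for s in subjects[1:]:
        if sets[s].node_ids != first.node_ids:
            raise TimeseriesFormatError(f"subject {s}: node IDs differ from {subjects[0]}")
    return NodeTimeseriesSet(
        subjects=subjects,
        data={s: sets[s].data[s] for s in subjects},
        tr=tr,
        node_ids=first.node_ids,
        is_cortical=is_cortical,
    )


def load_motion(path, subject: str = "sub-01") -> MotionTrace:
    """Read a single-column ``fd_mm`` TSV."""
    df = pd.read_csv(path, sep="\t")
    if "fd_mm" not in df.columns:
        raise TimeseriesFormatError(f"{path}: expected a column named 'fd_mm'")
    return MotionTrace(fd={subject: df["fd_mm"].to_numpy(dtype=float)})


def load_node_metadata(path):
    """Read node metadata TSV (columns node_id, is_cortical) -> (ids, bool array)."""
    df = pd.read_csv(path, sep="\t")
    return [str(x) for x in df["node_id"]], df["is_cortical"].to_numpy(dtype=bool)


def _despike(x: np.ndarray, z: float) -> np.ndarray:
    """Replace |robust z| > z samples by linear interpolation.

    Robust z uses the median and MAD (scaled to sigma); runs of outliers are
    bridged by interpolating from the nearest clean samples.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x
    rz = (x - med) / (1.4826 * mad)
    bad = np.abs(rz) > z
    if not bad.any():
        return x
    good = np.nonzero(~bad)[0]
    if good.size == 0:
        return x
    out = x.copy()
    out[bad] = np.interp(np.nonzero(bad)[0], good, x[good])
    return out


def preprocess_timeseries(
    ts: NodeTimeseriesSet,
    low_hz: float = 0.01,
    high_hz: float = 0.15,
    despike_z: float = 4.0,
) -> NodeTimeseriesSet:
    """Demean, detrend, despike, bandpass, and variance-normalize each node.

    The bandpass is a zero-phase 4th-order Butterworth applied forward and
    backward (no phase distortion). Constant node series are returned as
    zeros (with a warning) so node indexing stays stable.
    """
    nyq = 1.0 / (2.0 * ts.tr)
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq:.4f} Hz)"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    out = {}
    for s in ts.subjects:
        mat = ts.data[s]
        proc = np.empty_like(mat)
        for jcol in range(mat.shape[1]):
            x = mat[:, jcol]
            if np.ptp(x) == 0:
                warnings.warn(
                    f"subject {s}: node {ts.node_ids[jcol]!r} is constant; kept as zeros"
                )
                proc[:, jcol] = 0.0
                continue
            x = signal.detrend(x, type="linear")  # removes mean + linear trend
            x = _despike(x, despike_z)
            x = signal.sosfiltfilt(sos, x)
            sd = x.std()
            if sd < 1e-12:
                warnings.warn(
                    f"subject {s}: node {ts.node_ids[jcol]!r} constant after filtering; zeros"
                )
                proc[:, jcol] = 0.0
            else:
                proc[:, jcol] = (x - x.mean()) / sd
        out[s] = proc
    return NodeTimeseriesSet(
        subjects=list(ts.subjects),
        data=out,
        tr=ts.tr,
        node_ids=list(ts.node_ids),
        is_cortical=ts.is_cortical.copy(),
    )


def censor_windows(
    fd: MotionTrace,
    window_samples: int,
    threshold_mm: float = 0.18,
    step_samples: int = 1,
) -> CensorMask:
    """Censor every window whose mean FD exceeds ``threshold_mm``.

    Window w covers samples [w*step, w*step + window_samples); the mask has
    one entry per window position.
    """
    censored = {}
    for s, trace in fd.fd.items():
        t = trace.size
        if window_samples > t:
            raise ValueError(
                f"subject {s}: window_samples ({window_samples}) exceeds T ({t})"
            )
        starts = np.arange(0, t - window_samples + 1, step_samples)
        csum = np.concatenate([[0.0], np.cumsum(trace)])
        means = (csum[starts + window_samples] - csum[starts]) / window_samples
        censored[s] = means > threshold_mm
    return CensorMask(censored=censored, threshold_mm=threshold_mm, window_samples=window_samples)


def write_timeseries(path, ts: NodeTimeseriesSet, subject: str):
    pd.DataFrame(ts.data[subject], columns=ts.node_ids).to_csv(path, sep="\t", index=False)


def write_motion(path, motion: MotionTrace, subject: str):
    pd.DataFrame({"fd_mm": motion.fd[subject]}).to_csv(path, sep="\t", index=False)
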