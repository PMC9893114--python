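"""Time-resolved weighted directed effective network construction.

Each ordered channel pair (i, j) gets the edge weight
``a_ij(n) = gamma * dq_ij(n) * dQ_ij(n)`` when the directional growth rate
``dq_ij(n)`` is positive (channel i leading channel j inside the current
window) and 0 otherwise.  Self-connections are excluded (``a_ii = 0``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InsufficientEventsError
from .events import (
    DEFAULT_DELTA_N,
    DEFAULT_GAMMA,
    DetectionParams,
    EventTrain,
    cumulative_counts,
    delay_scale,
    detect_events,
    rate_series,
)
from .recording import Recording


@dataclass(frozen=True)
class EffectiveNetworkSnapshot:
    """The nonnegative weighted directed adjacency at one evaluation time.

    ``A[i, j]`` is the directed action of node i on node j; the diagonal is
    identically zero.
    """

    time: int
    A: np.ndarray
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        object.__setattr__(self, "A", A)


def adjacency(dq, dQ, gamma: float = DEFAULT_GAMMA):
    """Edge weight gamma * dq * dQ for positive dq, else 0 (scalar or array)."""
    dq = np.asarray(dq, dtype=float)
    dQ = np.asarray(dQ, dtype=float)
    out = np.where(dq > 0, gamma * dq * dQ, 0.0)
    return float(out) if out.ndim == 0 else out


def build_network(
    recording: Recording,
    params: DetectionParams = DetectionParams(),
    window: int = DEFAULT_DELTA_N,
    stride: int | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> list[EffectiveNetworkSnapshot]:
    """Build the sequence of effective-network snapshots for a recording.

    For every unordered channel pair the events are detected, the adaptive
    delay tau computed over the full recording, cumulative coincidence counts
    accumulated, and windowed rates evaluated at
    ``n = window, window + stride, ...``; both directed weights then follow
    from the sign split of dq.  Pairs where either channel has fewer than
    three events contribute all-zero entries.
    """
    n_ch = recording.n_channels
    if n_ch < 2:
        raise ValueError("build_network needs at least 2 channels")
    if stride is None:
        stride = window
    trains = [
        detect_events(recording.data[i], params, channel=recording.channel_names[i])
        for i in range(n_ch)
    ]
    if all(len(t) == 0 for t in trains):
        warnings.warn("no events detected on any channel; snapshots are all zero")
    L = recording.n_samples
    eval_times = np.arange(window, L + 1, stride, dtype=np.int64)
    W = np.zeros((eval_times.size, n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            try:
                tau = delay_scale(trains[i], trains[j]).tau
            except InsufficientEventsError:
                continue
            cum = cumulative_counts(trains[i], trains[j], tau)
            rs = rate_series(cum, trains[i], trains[j], window=window, stride=stride)
            k = min(eval_times.size, rs.times.size)
            W[:k, i, j] = adjacency(rs.dq[:k], rs.dQ[:k], gamma)
            W[:k, j, i] = adjacency(-rs.dq[:k], rs.dQ[:k], gamma)
    return [
        EffectiveNetworkSnapshot(time=int(n), A=W[k], gamma=gamma)
        for k, n in enumerate(eval_times)
    ]


# ---------------------------------------------------------------------------
# Snapshot files: one dense delimited matrix per evaluation time + a manifest
# ---------------------------------------------------------------------------

def write_snapshots(
    snapshots: list[EffectiveNetworkSnapshot], directory: str | Path
) -> Path:
    """Write each snapshot as a delimited matrix plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["time_sample,filename"]
    for snap in snapshots:
        fname = f"snapshot_{snap.time:010d}.txt"
        np.savetxt(directory / fname, snap.A, delimiter="\t")
        lines.append(f"{snap.time},{fname}")
    manifest = directory / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_snapshots(directory: str | Path) -> list[EffectiveNetworkSnapshot]:
    """Read snapshots written by :func:`write_snapshots`."""
    directory = Path(directory)
    snapshots = []
    for line in (directory / "manifest.csv").read_text().strip().splitlines()[1:]:
        time_s, fname = line.split(",")
        A = np.loadtxt(directory / fname, delimiter="\t", ndmin=2)
        snapshots.append(EffectiveNetworkSnapshot(time=int(time_s), A=A))
    return snapshots
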