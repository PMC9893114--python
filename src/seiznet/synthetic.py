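"""Synthetic multichannel recordings with ground-truth events and couplings.

The generator emulates the statistical structure the pipeline consumes, not
SEEG biophysics: each channel is zero-mean Gaussian noise plus smooth
Gaussian bumps at planted event times (so the local-maximum detector is
exercised on its real path), and directed couplings inject a follower bump on
the target channel a fixed lag after a source event, with a stated
propagation probability.  Seizure-phase regimes are parameter overrides
(event rates, coupling edges) on time windows, never new mechanisms:

* interictal / control — sparse, weakly reliable random couplings; the
  effective network is near-empty or acyclic and the balance index hovers
  around 0 (metastable balance);
* preictal — a moderately reliable recurrent loop forms over the focus
  channels (reduced switching flexibility);
* ictal — the focus loop becomes fully reliable (re-entrant propagation,
  i.e. several comparable eigenmodes: strong-local dominance) while
  background couplings across the whole network also densify, sustaining a
  dominant global mode outside the focus;
* postictal — return to the sparse background.

Identical config + seed reproduces the recording bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .recording import (
    PhaseWindow,
    Recording,
    read_annotations,
    read_recording_text,
    write_annotations,
    write_recording_text,
)

#: override keys a phase regime may carry
_ALLOWED_OVERRIDES = {"event_rate", "channel_rates", "coupling_edges", "extra_edges"}


@dataclass(frozen=True)
class CouplingEdge:
    """A directed coupling: source events propagate to the target after ``lag``."""

    source: int
    target: int
    probability: float
    lag: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ConfigurationError("coupling probability must be in [0, 1]")
        if self.lag < 1:
            raise ConfigurationError("coupling lag must be >= 1 sample")
        if self.source == self.target:
            raise ConfigurationError("self-coupling is not allowed")


@dataclass(frozen=True)
class PhaseRegime:
    """A phase window plus its parameter overrides."""

    label: str
    start: int
    end: int
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - _ALLOWED_OVERRIDES
        if unknown:
            raise ConfigurationError(f"unknown regime overrides: {sorted(unknown)}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic recording.

    Defaults give an event amplitude (100) far above the detection margin
    (h = 30) relative to the background noise (sd = 5), so planted events are
    recovered reliably; ``detection_M``/``detection_h`` mirror the companion
    detector and set the collision-thinning spacing (2 M).
    """

    n_channels: int = 8
    fs: float = 512.0
    duration: float = 60.0
    event_rate: float = 1.0
    event_amplitude: float = 100.0
    event_halfwidth: int = 5
    noise_sd: float = 5.0
    coupling_edges: tuple = ()
    phase_plan: tuple = ()
    focus_channels: tuple = ()
    seed: int = 0
    detection_M: int = 10
    detection_h: float = 30.0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_channels < 1 or self.duration <= 0:
            raise ConfigurationError("fs, n_channels and duration must be positive")
        if self.event_rate < 0 or self.noise_sd < 0 or self.event_halfwidth < 1:
            raise ConfigurationError("invalid rate / noise / halfwidth")
        for e in self.coupling_edges:
            _check_edge_channels(e, self.n_channels)
        for ch in self.focus_channels:
            if not (0 <= ch < self.n_channels):
                raise ConfigurationError(f"focus channel {ch} out of range")
        plan = tuple(self.phase_plan)
        if not plan:
            plan = (PhaseRegime("interictal", 0, self.n_samples),)
        prev_end = 0
        for reg in plan:
            PhaseWindow(reg.label, reg.start, reg.end)  # label/order validation
            if reg.start != prev_end:
                raise ConfigurationError(
                    "phase windows must be ordered, disjoint and cover the recording"
                )
            prev_end = reg.end
            for e in reg.overrides.get("coupling_edges", ()):  # replaces base edges
                _check_edge_channels(e, self.n_channels)
            for e in reg.overrides.get("extra_edges", ()):
                _check_edge_channels(e, self.n_channels)
        if prev_end != self.n_samples:
            raise ConfigurationError("phase plan must cover [0, duration*fs)")
        object.__setattr__(self, "phase_plan", plan)


def _check_edge_channels(edge: CouplingEdge, n_channels: int) -> None:
    if not (0 <= edge.source < n_channels and 0 <= edge.target < n_channels):
        raise ConfigurationError(f"coupling edge {edge} out of channel range")


@dataclass
class GroundTruth:
    """Planted events, realized couplings and per-sample phase labels."""

    true_event_times: list  # per-channel int arrays, strictly increasing
    realized_couplings: list  # (source_time, target_time, CouplingEdge)
    phase_labels: np.ndarray  # per-sample label


def _thin(times: np.ndarray, min_spacing: int) -> np.ndarray:
    """Greedy keep-earliest thinning so no two events are closer than min_spacing."""
    kept: list[int] = []
    for t in np.sort(np.unique(times)):
        if not kept or t - kept[-1] >= min_spacing:
            kept.append(int(t))
    return np.asarray(kept, dtype=np.int64)


def generate_recording(config: SyntheticConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording plus its ground truth (deterministic per seed)."""
    if config.event_amplitude <= config.detection_h:
        warnings.warn(
            "event_amplitude <= detection margin h: the detector will miss events"
        )
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_samples
    sigma = float(config.event_halfwidth)
    margin = config.detection_M + int(np.ceil(4 * sigma))
    min_spacing = 2 * config.detection_M

    # 1. own events per channel, per phase window (rates may be overridden)
    own: list[np.ndarray] = []
    for ch in range(config.n_channels):
        times: list[int] = []
        for reg in config.phase_plan:
            rate = reg.overrides.get("event_rate", config.event_rate)
            rate = reg.overrides.get("channel_rates", {}).get(ch, rate)
            lam = rate * (reg.end - reg.start) / config.fs
            n_ev = rng.poisson(lam) if lam > 0 else 0
            if n_ev:
                times.extend(rng.integers(reg.start, reg.end, size=n_ev).tolist())
        times_arr = np.asarray(times, dtype=np.int64)
        times_arr = times_arr[(times_arr >= margin) & (times_arr < n_samples - margin)]
        own.append(_thin(times_arr, min_spacing))

    # 2. propagate own source events along the edges active in each window
    injected: list[list[int]] = [[] for _ in range(config.n_channels)]
    proposals: list[tuple[int, int, CouplingEdge]] = []
    for reg in config.phase_plan:
        edges = reg.overrides.get("coupling_edges", config.coupling_edges)
        edges = tuple(edges) + tuple(reg.overrides.get("extra_edges", ()))
        for edge in edges:
            src_times = own[edge.source]
            src_times = src_times[(src_times >= reg.start) & (src_times < reg.end)]
            fired = rng.random(src_times.size) < edge.probability
            for t in src_times[fired]:
                t_target = int(t) + edge.lag
                if margin <= t_target < n_samples - margin:
                    injected[edge.target].append(t_target)
                    proposals.append((int(t), t_target, edge))

    # 3. final per-channel trains: merge + keep-earliest thinning
    final: list[np.ndarray] = []
    for ch in range(config.n_channels):
        merged = np.concatenate([own[ch], np.asarray(injected[ch], dtype=np.int64)])
        final.append(_thin(merged, min_spacing))
    final_sets = [set(t.tolist()) for t in final]
    realized = [
        (ts, tt, e)
        for ts, tt, e in proposals
        if ts in final_sets[e.source] and tt in final_sets[e.target]
    ]

    # 4. signal synthesis: Gaussian noise + smooth unimodal bumps
    if config.noise_sd > 0:
        data = rng.normal(0.0, config.noise_sd, size=(config.n_channels, n_samples))
    else:
        data = np.zeros((config.n_channels, n_samples))
    half_support = int(np.ceil(4 * sigma))
    offsets = np.arange(-half_support, half_support + 1)
    bump = config.event_amplitude * np.exp(-0.5 * (offsets / sigma) ** 2)
    for ch in range(config.n_channels):
        for t in final[ch]:
            data[ch, t - half_support : t + half_support + 1] += bump

    phase_labels = np.empty(n_samples, dtype="<U10")
    annotations = []
    for reg in config.phase_plan:
        phase_labels[reg.start : reg.end] = reg.label
        annotations.append(PhaseWindow(reg.label, reg.start, reg.end))

    recording = Recording(data=data, fs=config.fs, annotations=annotations)
    truth = GroundTruth(
        true_event_times=final, realized_couplings=realized, phase_labels=phase_labels
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Study-condition factories
# ---------------------------------------------------------------------------

def sparse_background_edges(
    n_channels: int,
    rng: np.random.Generator,
    density: float = 0.15,
    probability: float = 0.4,
    lag_range: tuple[int, int] = (3, 9),
) -> tuple:
    """Random single-orientation couplings over a fraction of channel pairs.

    Each unordered pair is coupled with probability ``density``; the direction
    is random and the lag uniform over ``lag_range`` (inclusive).
    """
    edges = []
    for i in range(n_channels):
        for j in range(i + 1, n_channels):
            if rng.random() < density:
                src, tgt = (i, j) if rng.random() < 0.5 else (j, i)
                lag = int(rng.integers(lag_range[0], lag_range[1] + 1))
                edges.append(CouplingEdge(src, tgt, probability, lag))
    return tuple(edges)


def focus_loop_edges(focus_channels, probability: float = 1.0, lag: int = 5) -> tuple:
    """A directed ring over the focus channels (re-entrant propagation loop)."""
    focus = list(focus_channels)
    if len(focus) < 3:
        raise ConfigurationError("a propagation loop needs >= 3 focus channels")
    return tuple(
        CouplingEdge(focus[k], focus[(k + 1) % len(focus)], probability, lag)
        for k in range(len(focus))
    )


def control_config(
    n_channels: int = 8,
    duration: float = 320.0,
    seed: int = 0,
    n_windows: int = 4,
    **kwargs,
) -> SyntheticConfig:
    """Control (healthy resting-state analogue): sparse background all along."""
    rng = np.random.default_rng(seed)
    edges = sparse_background_edges(n_channels, rng)
    n_samples = int(round(duration * kwargs.get("fs", 512.0)))
    bounds = np.linspace(0, n_samples, n_windows + 1).astype(int)
    plan = tuple(
        PhaseRegime("interictal", int(a), int(b)) for a, b in zip(bounds, bounds[1:])
    )
    return SyntheticConfig(
        n_channels=n_channels,
        duration=duration,
        coupling_edges=edges,
        phase_plan=plan,
        seed=seed,
        **kwargs,
    )


def patient_config(
    n_channels: int = 8,
    duration: float = 480.0,
    focus_channels: tuple = (0, 1, 2, 3),
    seed: int = 0,
    **kwargs,
) -> SyntheticConfig:
    """Patient analogue: interictal, preictal, ictal and postictal regimes.

    The ictal window carries a fully reliable propagation loop over the focus
    channels on top of the sparse background (the loop's injected followers
    themselves double the focus discharge rate, emulating hypersynchronous
    recruitment); the preictal window carries a half-reliable focus loop.
    """
    rng = np.random.default_rng(seed)
    base = sparse_background_edges(n_channels, rng)
    loop_full = focus_loop_edges(focus_channels, probability=1.0, lag=5)
    loop_half = focus_loop_edges(focus_channels, probability=0.5, lag=5)
    n_samples = int(round(duration * kwargs.get("fs", 512.0)))
    b = [int(round(f * n_samples)) for f in (0.0, 0.4, 0.6, 0.8, 1.0)]
    plan = (
        PhaseRegime("interictal", b[0], b[1]),
        PhaseRegime("preictal", b[1], b[2], {"extra_edges": loop_half}),
        PhaseRegime("ictal", b[2], b[3], {"extra_edges": loop_full}),
        PhaseRegime("postictal", b[3], b[4]),
    )
    return SyntheticConfig(
        n_channels=n_channels,
        duration=duration,
        coupling_edges=base,
        phase_plan=plan,
        focus_channels=tuple(focus_channels),
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Fixture files
# ---------------------------------------------------------------------------

def write_fixture(recording: Recording, truth: GroundTruth, directory: str | Path) -> Path:
    """Write recording, annotations and ground truth as plain-text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_recording_text(recording, directory / "recording.txt")
    write_annotations(recording.annotations or [], directory / "annotations.csv")
    ev_lines = ["channel,event_sample"]
    for ch, times in enumerate(truth.true_event_times):
        ev_lines += [f"{ch},{int(t)}" for t in times]
    (directory / "events.csv").write_text("\n".join(ev_lines) + "\n")
    cp_lines = ["source_channel,target_channel,source_sample,target_sample,probability,lag"]
    for ts, tt, e in truth.realized_couplings:
        cp_lines.append(f"{e.source},{e.target},{ts},{tt},{e.probability},{e.lag}")
    (directory / "couplings.csv").write_text("\n".join(cp_lines) + "\n")
    return directory


def read_fixture(directory: str | Path) -> tuple[Recording, list, list]:
    """Read back a fixture directory: (recording, event list, coupling rows)."""
    directory = Path(directory)
    recording = read_recording_text(directory / "recording.txt")
    recording.annotations = read_annotations(directory / "annotations.csv")
    events = []
    for line in (directory / "events.csv").read_text().strip().splitlines()[1:]:
        ch, t = line.split(",")
        events.append((int(ch), int(t)))
    couplings = []
    text = (directory / "couplings.csv").read_text().strip().splitlines()[1:]
    for line in text:
        s, t, ts, tt, p, lag = line.split(",")
        couplings.append((int(s), int(t), int(ts), int(tt), float(p), int(lag)))
    return recording, events, couplings
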