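"""Phase segmentation, per-phase kernel densities of H_sb, and plunge tracking.

The balance index H_sb is collected per analysis interval (each seizure phase
split into equal sub-intervals, mirroring a two-interictal + split-phase
scheme), smoothed with a Gaussian kernel density over [-1, 1], and the grid
location of the density maximum (``peak_x``) is tracked across intervals.
A *plunge* is a drop of ``peak_x`` by more than a threshold followed by a
rebound — the signature of a transient dive into strong-local dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sp_signal

from .eigenmodes import OscillationIndices, index_time_course
from .errors import ConfigurationError, InsufficientSamplesError
from .events import DEFAULT_DELTA_N, DetectionParams
from .network import build_network
from .recording import PhaseWindow, Recording

DEFAULT_PLUNGE_THRESHOLD = 0.3
DEFAULT_GRID_SIZE = 512
#: minimum relative prominence for a density local maximum to count as a mode
MODE_PROMINENCE_FRACTION = 0.05


@dataclass(frozen=True)
class PhaseSegmentation:
    """Validated, ordered, non-overlapping phase windows."""

    windows: tuple[PhaseWindow, ...]


@dataclass(frozen=True)
class DensitySummary:
    """Kernel-density curve of H_sb over one interval, with peak statistics."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak_x: float
    peak_density: float
    n_modes: int


@dataclass(frozen=True)
class PlungeStats:
    """Drop-and-rebound episodes of the per-interval KDE peak location."""

    interval_ids: tuple
    peak_x: np.ndarray
    peak_density: np.ndarray
    plunge_interval: tuple[float, float, float]  # (min peak_x, max peak_x, length)
    plunge_times: tuple  # interval ids where a plunge bottomed out
    plunge_count: int


@dataclass(frozen=True)
class NetworkScope:
    """A named channel subset analyzed as its own sub-network."""

    name: str
    channels: tuple

    def __post_init__(self) -> None:
        if not self.channels:
            raise ConfigurationError(f"scope {self.name!r} has no channels")


def segment_phases(
    annotations: Iterable[PhaseWindow | tuple],
) -> PhaseSegmentation:
    """Validate and order annotation windows into a PhaseSegmentation.

    Accepts PhaseWindow objects or (label, start, end) tuples; windows are
    sorted by start and must not overlap.
    """
    windows = [
        w if isinstance(w, PhaseWindow) else PhaseWindow(*w) for w in annotations
    ]
    windows.sort(key=lambda w: w.start)
    for prev, cur in zip(windows, windows[1:]):
        if cur.start < prev.end:
            raise ConfigurationError(
                f"overlapping phase windows: {prev} and {cur}"
            )
    return PhaseSegmentation(windows=tuple(windows))


def analysis_intervals(
    segmentation: PhaseSegmentation, splits_per_phase: int = 2
) -> list[tuple[str, str, int, int]]:
    """Split each phase window into equal sub-intervals.

    Returns ``(interval_id, label, start, end)`` tuples; the id is
    ``label#k`` with k the sub-interval index within that window occurrence.
    """
    out = []
    seen: dict[str, int] = {}
    for w in segmentation.windows:
        edges = np.linspace(w.start, w.end, splits_per_phase + 1).astype(int)
        for k in range(splits_per_phase):
            n = seen.get(w.label, 0) * splits_per_phase + k + 1
            out.append((f"{w.label}#{n}", w.label, int(edges[k]), int(edges[k + 1])))
        seen[w.label] = seen.get(w.label, 0) + 1
    return out


def kde_hsb(
    values: Sequence[float],
    bandwidth: str | float = "silverman",
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensitySummary:
    """Gaussian kernel density of H_sb values on a fixed grid over [-1, 1].

    The curve is renormalized to unit trapezoidal integral over the grid so
    that boundary mass loss cannot bias peak heights.  The Silverman
    bandwidth is floored at the grid resolution (0.02) so that degenerate or
    tightly clustered samples still yield a well-resolved, delta-like peak.
    Modes are local maxima (grid boundaries included) with prominence at
    least 5% of the peak density.  A float ``bandwidth`` is taken as the
    absolute kernel standard deviation.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InsufficientSamplesError("kernel density needs >= 2 values")
    grid = np.linspace(-1.0, 1.0, grid_size)
    bw_floor = 5.0 * (grid[1] - grid[0])  # ~0.02 on the default grid
    if isinstance(bandwidth, str):
        if bandwidth != "silverman":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        sigma = float(np.std(v))
        bw = max(sigma * (4.0 / (3.0 * v.size)) ** 0.2, bw_floor)
    else:
        bw = max(float(bandwidth), 1e-6)
    density = np.exp(
        -0.5 * ((grid[:, None] - v[None, :]) / bw) ** 2
    ).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise InsufficientSamplesError("degenerate density (all mass outside [-1, 1])")
    density = density / area
    peak_idx = int(np.argmax(density))
    peak_density = float(density[peak_idx])
    padded = np.concatenate(([-np.inf], density, [-np.inf]))
    peaks, _ = sp_signal.find_peaks(
        padded, prominence=MODE_PROMINENCE_FRACTION * peak_density
    )
    return DensitySummary(
        grid=grid,
        density=density,
        bandwidth=bw,
        peak_x=float(grid[peak_idx]),
        peak_density=peak_density,
        n_modes=int(peaks.size),
    )


def peak_track(
    summaries: Sequence[tuple],
    threshold: float = DEFAULT_PLUNGE_THRESHOLD,
) -> PlungeStats:
    """Track per-interval peak locations and count plunge episodes.

    ``summaries`` is a sequence of ``(interval_id, peak_x, peak_density)``.
    An episode is a strict drop of peak_x below the running reference level by
    more than ``threshold``, followed by a rebound above the reference minus
    ``threshold / 2``; after a rebound the search restarts from the rebound
    point.  The plunge interval spans the observed peak_x extremes.
    """
    if len(summaries) < 3:
        raise ValueError("peak tracking needs >= 3 intervals")
    ids = tuple(s[0] for s in summaries)
    px = np.array([s[1] for s in summaries], dtype=float)
    pd = np.array([s[2] for s in summaries], dtype=float)

    plunge_ids: list = []
    ref = px[0]
    j = 1
    while j < px.size:
        if px[j] > ref:
            ref = px[j]
            j += 1
            continue
        if ref - px[j] > threshold:
            # bottom of the candidate drop: deepest point before the rebound
            k = j
            bottom = j
            rebound = None
            while k < px.size:
                if px[k] < px[bottom]:
                    bottom = k
                if px[k] > ref - threshold / 2:
                    rebound = k
                    break
                k += 1
            if rebound is None:
                break
            plunge_ids.append(ids[bottom])
            ref = px[rebound]
            j = rebound + 1
        else:
            j += 1
    lo, hi = float(px.min()), float(px.max())
    return PlungeStats(
        interval_ids=ids,
        peak_x=px,
        peak_density=pd,
        plunge_interval=(lo, hi, hi - lo),
        plunge_times=tuple(plunge_ids),
        plunge_count=len(plunge_ids),
    )


@dataclass
class ScopeResult:
    """Pipeline outputs for one network scope."""

    scope: NetworkScope
    indices: list[OscillationIndices]
    interval_summaries: list[tuple]  # (interval_id, peak_x, peak_density)
    densities: dict = field(default_factory=dict)  # interval_id -> DensitySummary
    plunge: PlungeStats | None = None


def interval_peak_summaries(
    indices: Sequence[OscillationIndices],
    segmentation: PhaseSegmentation,
    splits_per_phase: int = 2,
    bandwidth: str | float = "silverman",
    grid_size: int = DEFAULT_GRID_SIZE,
) -> tuple[list[tuple], dict]:
    """Per-interval KDE summaries of H_sb_norm from an index time course.

    Evaluation times falling in each analysis interval supply the sample;
    intervals with fewer than two values are skipped.
    """
    times = np.array([ix.time for ix in indices])
    hsb = np.array([ix.H_sb_norm for ix in indices])
    summaries: list[tuple] = []
    densities: dict = {}
    for iid, _label, start, end in analysis_intervals(segmentation, splits_per_phase):
        mask = (times >= start) & (times < end)
        if mask.sum() < 2:
            continue
        summary = kde_hsb(hsb[mask], bandwidth=bandwidth, grid_size=grid_size)
        summaries.append((iid, summary.peak_x, summary.peak_density))
        densities[iid] = summary
    return summaries, densities


def scoped_analysis(
    recording: Recording,
    scopes: Sequence[NetworkScope],
    params: DetectionParams = DetectionParams(),
    window: int = DEFAULT_DELTA_N,
    stride: int | None = None,
    gamma: float = 1000.0,
    splits_per_phase: int = 2,
    plunge_threshold: float = DEFAULT_PLUNGE_THRESHOLD,
    hsb_normalization: str = "ratio",
) -> dict[str, ScopeResult]:
    """Run the full pipeline independently on each channel-subset scope.

    All scopes share the recording's evaluation grid (same window/stride and
    length), so their index time courses are aligned for comparison.  The
    recording must carry phase annotations.
    """
    if not recording.annotations:
        raise ConfigurationError("scoped analysis needs phase annotations")
    segmentation = segment_phases(recording.annotations)
    results: dict[str, ScopeResult] = {}
    for scope in scopes:
        sub = recording.subset(list(scope.channels))
        snapshots = build_network(sub, params, window=window, stride=stride, gamma=gamma)
        indices = index_time_course(snapshots, hsb_normalization=hsb_normalization)
        summaries, densities = interval_peak_summaries(
            indices, segmentation, splits_per_phase=splits_per_phase
        )
        plunge = peak_track(summaries, threshold=plunge_threshold) if len(summaries) >= 3 else None
        results[scope.name] = ScopeResult(
            scope=scope,
            indices=indices,
            interval_summaries=summaries,
            densities=densities,
            plunge=plunge,
        )
    return results
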