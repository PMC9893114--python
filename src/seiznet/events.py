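"""Event detection and event-synchronization / directionality statistics.

The effective-network method works on point processes extracted from each
channel: transient local maxima ("events") standing at least ``h`` units above
their ``±M``-sample surroundings.  For two event trains the method counts
quasi-coincident events within an adaptive delay ``tau`` (half the smallest
inter-event interval of either train), splits the count by temporal order to
obtain a synchronization strength ``Q`` in [0, 1] and a directionality index
``q`` in [-1, 1], and tracks both cumulatively through time so that windowed
growth rates (over ``delta_n`` samples) yield a time-resolved coupling
estimate per ordered channel pair.

Direction convention (used consistently everywhere): for a channel pair
``(a, b)``, ``q > 0`` means events of ``a`` tend to precede matching events of
``b``, i.e. ``a`` drives ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import InsufficientEventsError, SeriesTooShortError

#: default detection window half-width, in samples
DEFAULT_M = 10
#: default detection margin, in signal units
DEFAULT_H = 30.0
#: default rate window, in samples (10 s at 512 Hz)
DEFAULT_DELTA_N = 5120
#: default adjacency amplification factor
DEFAULT_GAMMA = 1000.0


@dataclass(frozen=True)
class DetectionParams:
    """Control parameters of the local-maximum event detector.

    ``M`` sets the half-width of the strict-maximum neighbourhood (samples),
    ``h`` the margin by which the peak must exceed the signal M samples away.
    """

    M: int = DEFAULT_M
    h: float = DEFAULT_H

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.h < 0:
            raise ValueError("h must be >= 0")


@dataclass(frozen=True)
class EventTrain:
    """Ordered event sample indices of one channel."""

    channel: str
    times: np.ndarray
    series_length: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.int64)
        object.__setattr__(self, "times", times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DelayScale:
    """The adaptive delay ``tau`` for one channel pair.

    ``tau`` is the minimum over all interior event pairs (r, s) of
    ``tau_rs = 0.5 * min`` of the four neighbour gaps around r and s, which
    decouples into half the smallest inter-event interval of either train.
    """

    tau: float
    local_taus: dict | None = None


@dataclass(frozen=True)
class PairCounts:
    """Directional quasi-coincidence counts for one channel pair.

    ``e_ab`` counts events of ``b`` followed within tau by an event of ``a``
    (drive of b onto a); exact coincidences contribute one half to each side
    to prevent double counting.
    """

    e_ab: float
    e_ba: float
    m_a: int
    m_b: int


@dataclass(frozen=True)
class SyncCausality:
    """Normalized synchronization strength Q and directionality q.

    ``normalization_mode='sqrt_mm'`` (default) divides by sqrt(m_a * m_b) so
    that Q = 1 exactly when every event of both trains coincides;
    ``'product_mm'`` divides by m_a * m_b.
    """

    Q: float
    q: float
    normalization_mode: str = "sqrt_mm"


class CumulativeCounts:
    """Step functions of the cumulative coincidence counts.

    ``e_n(a|b)`` at time n sums every coincidence pair whose a-side event lies
    strictly before n.  ``Q(n)`` is the total count (nondecreasing) and
    ``q(n)`` the directional balance e_n(b|a) - e_n(a|b), positive when a
    leads.  The steps are stored as breakpoints so both can be evaluated at
    arbitrary n.
    """

    def __init__(self, a: EventTrain, b: EventTrain, tau: float) -> None:
        if tau <= 0:
            raise ValueError("tau must be positive")
        ta = a.times.astype(np.int64)
        tb = b.times.astype(np.int64)
        if ta.size and tb.size:
            d = ta[:, None] - tb[None, :]
            E_ab = ((d > 0) & (d <= tau)) + 0.5 * (d == 0)   # b precedes a
            E_ba = ((-d > 0) & (-d <= tau)) + 0.5 * (d == 0)  # a precedes b
            w_a = E_ab.sum(axis=1)  # attributed to the a-side event time
            w_b = E_ba.sum(axis=0)  # attributed to the b-side event time
        else:
            w_a = np.zeros(ta.size)
            w_b = np.zeros(tb.size)
        self._ta, self._cum_ab = ta, np.concatenate(([0.0], np.cumsum(w_a)))
        self._tb, self._cum_ba = tb, np.concatenate(([0.0], np.cumsum(w_b)))
        self.tau = float(tau)
        self.series_length = max(a.series_length, b.series_length)

    def e_ab(self, n) -> np.ndarray | float:
        """Cumulative count of b-precedes-a pairs with a-event time < n."""
        return self._cum_ab[np.searchsorted(self._ta, np.asarray(n), side="left")]

    def e_ba(self, n) -> np.ndarray | float:
        return self._cum_ba[np.searchsorted(self._tb, np.asarray(n), side="left")]

    def Q(self, n) -> np.ndarray | float:
        """Cumulative coincidence count Q(n) = e_n(b|a) + e_n(a|b)."""
        return self.e_ba(n) + self.e_ab(n)

    def q(self, n) -> np.ndarray | float:
        """Cumulative directional balance q(n) = e_n(b|a) - e_n(a|b)."""
        return self.e_ba(n) - self.e_ab(n)


@dataclass(frozen=True)
class RateSeries:
    """Windowed growth rates of synchronization and directionality.

    At each evaluation time ``n``, ``dQ = (Q(n) - Q(n - window)) / (dn1*dn2)``
    where dn1, dn2 count the events of each train in [n - window, n); zero by
    convention when either count is zero.  Same form for ``dq``.
    """

    times: np.ndarray
    dQ: np.ndarray
    dq: np.ndarray
    window: int
    dn1: np.ndarray = field(repr=False, default=None)
    dn2: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def detect_events(
    signal: Iterable[float],
    params: DetectionParams = DetectionParams(),
    channel: str = "",
) -> EventTrain:
    """Extract transient local-maximum events from one channel.

    A sample ``t`` is an event when it is a strict maximum over the
    ``±(M-1)``-sample neighbourhood and exceeds both samples ``±M`` away by at
    least the margin ``h``.  Samples within ``M`` of either end are never
    events (their neighbourhood is incomplete).
    """
    x = np.asarray(signal, dtype=float).ravel()
    L = x.size
    M, h = params.M, params.h
    if L < 2 * M + 1:
        raise SeriesTooShortError(f"series of length {L} too short for M={M}")
    idx = np.arange(M, L - M)
    ok = np.ones(idx.size, dtype=bool)
    centre = x[idx]
    for m in range(1, M):
        ok &= (centre > x[idx - m]) & (centre > x[idx + m])
    ok &= (centre > x[idx - M] + h) & (centre > x[idx + M] + h)
    return EventTrain(channel=channel, times=idx[ok], series_length=L)


def delay_scale(a: EventTrain, b: EventTrain, keep_local: bool = False) -> DelayScale:
    """Adaptive delay tau for a channel pair.

    For every interior event pair (r, s) the local delay is half the smallest
    of the four neighbour gaps around r and s; tau is the minimum over all
    such pairs, which equals half the smallest consecutive gap of either
    train.  Both trains need at least three events (an interior event each).
    """
    if len(a) < 3 or len(b) < 3:
        raise InsufficientEventsError(
            f"delay scale needs >= 3 events per train (got {len(a)}, {len(b)})"
        )
    gaps_a = np.diff(a.times)
    gaps_b = np.diff(b.times)
    tau = 0.5 * float(min(gaps_a.min(), gaps_b.min()))
    local = None
    if keep_local:
        local = {}
        for r in range(1, len(a) - 1):
            for s in range(1, len(b) - 1):
                local[(r, s)] = 0.5 * float(
                    min(gaps_a[r - 1], gaps_a[r], gaps_b[s - 1], gaps_b[s])
                )
    return DelayScale(tau=tau, local_taus=local)


def pair_counts(a: EventTrain, b: EventTrain, tau: float) -> PairCounts:
    """Directional quasi-coincidence counts within the delay tau.

    A pair (r, s) contributes 1 to ``e_ab`` when the b-event precedes the
    a-event by at most tau (0 < t_a - t_b <= tau), symmetrically for
    ``e_ba``; an exact coincidence contributes one half to each.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if len(a) == 0 or len(b) == 0:
        return PairCounts(0.0, 0.0, len(a), len(b))
    d = a.times[:, None] - b.times[None, :]
    ties = 0.5 * float((d == 0).sum())
    e_ab = float(((d > 0) & (d <= tau)).sum()) + ties
    e_ba = float(((-d > 0) & (-d <= tau)).sum()) + ties
    return PairCounts(e_ab=e_ab, e_ba=e_ba, m_a=len(a), m_b=len(b))


def sync_causality(counts: PairCounts, mode: str = "sqrt_mm") -> SyncCausality:
    """Normalize pair counts into Q (symmetric) and q (antisymmetric).

    ``q > 0`` means the first train drives the second.  Degenerate pairs
    (either train empty) return Q = q = 0.
    """
    if mode not in ("sqrt_mm", "product_mm"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if counts.m_a < 1 or counts.m_b < 1:
        return SyncCausality(Q=0.0, q=0.0, normalization_mode=mode)
    mm = counts.m_a * counts.m_b
    denom = np.sqrt(mm) if mode == "sqrt_mm" else float(mm)
    return SyncCausality(
        Q=(counts.e_ba + counts.e_ab) / denom,
        q=(counts.e_ba - counts.e_ab) / denom,
        normalization_mode=mode,
    )


def cumulative_counts(a: EventTrain, b: EventTrain, tau: float) -> CumulativeCounts:
    """Cumulative coincidence step functions for a channel pair (see class docs)."""
    return CumulativeCounts(a, b, tau)


def rate_series(
    cum: CumulativeCounts,
    a: EventTrain,
    b: EventTrain,
    window: int = DEFAULT_DELTA_N,
    stride: int | None = None,
) -> RateSeries:
    """Windowed growth rates dQ(n), dq(n) at n = window, window+stride, ...

    The normalizer is the product of per-train event counts inside
    [n - window, n); evaluation points with an eventless train give 0.
    """
    if window < 1 or (stride is not None and stride < 1):
        raise ValueError("window and stride must be >= 1")
    if stride is None:
        stride = window
    L = max(cum.series_length, a.series_length, b.series_length)
    times = np.arange(window, L + 1, stride, dtype=np.int64)
    dQ_raw = cum.Q(times) - cum.Q(times - window)
    dq_raw = cum.q(times) - cum.q(times - window)
    dn1 = (
        np.searchsorted(a.times, times, side="left")
        - np.searchsorted(a.times, times - window, side="left")
    )
    dn2 = (
        np.searchsorted(b.times, times, side="left")
        - np.searchsorted(b.times, times - window, side="left")
    )
    norm = (dn1 * dn2).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dQ = np.where(norm > 0, dQ_raw / np.where(norm > 0, norm, 1.0), 0.0)
        dq = np.where(norm > 0, dq_raw / np.where(norm > 0, norm, 1.0), 0.0)
    return RateSeries(times=times, dQ=dQ, dq=dq, window=window, dn1=dn1, dn2=dn2)
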