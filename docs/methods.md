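# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of the seiznet pipeline, in the order the
data flows through it.

## Event detection

A sample is an event when it is a strict local maximum over the
±(M−1)-sample neighbourhood **and** exceeds the signal M samples away on both
sides by the margin h. Defaults: M = 10 samples, h = 30 signal units — the
method's published operating point at 512 Hz. Consequences we rely on
elsewhere:

* two events on one channel are always ≥ M+1 samples apart (no tie-breaking
  is ever needed within a train);
* indices within M of either boundary have incomplete neighbourhoods and are
  never events;
* a series shorter than 2M+1 samples is rejected outright.

## Pair statistics and their conventions

* **Adaptive delay.** τ_rs = ½·min of the four neighbour gaps around an
  interior event pair (r, s); the pair delay τ is the minimum over all
  interior pairs, which decouples into half the smallest inter-event interval
  of either train. We deliberately evaluate the minimum over *all* interior
  pairs rather than only temporally closest pairs: the closest partner of an
  interior event can be a boundary event (which has no neighbour gap), in
  which case a closest-pair rule produces no valid pair at all, while the
  exhaustive minimum is always defined once both trains have ≥ 3 events.
  Pairs where either train has < 3 events carry no delay information and are
  treated as "no evidence": Q = q = 0 and all-zero adjacency entries.
* **τ scope.** τ is computed once per channel pair over the full analyzed
  segment, not per window; the windowed rates below reuse it.
* **Normalization.** Q and q divide by √(m₁·m₂). This is the convention
  under which the printed bounds hold with equality (Q = 1 exactly when every
  event of both trains coincides; q = 1 for a perfect one-to-one lagged
  pairing). Dividing by the raw product m₁·m₂ is retained as
  `normalization_mode="product_mm"` for comparison.
* **Direction.** For a pair (a, b), q > 0 means a's events tend to precede
  b's matching events — a drives b — and the snapshot entry A[i, j] encodes
  the action of node i on node j. This convention is fixed here once and used
  consistently in the builder, the generator and every test.
* **Half-open windows.** Sample indices are 0-based and all windows are
  half-open [start, end), including the rate window: dQ(n) spans event times
  in [n − Δn, n), matching the cumulative step function Θ(n − t) (t < n).

## Windowed rates and the effective network

Rates are evaluated at n = Δn, Δn + stride, … with Δn = 5120 samples (10 s at
512 Hz) and stride defaulting to Δn; the normalizer is the product of the two
per-window event counts, and windows with an eventless train yield 0.
Edge weights a_ij = γ·dq·dQ (dq > 0), γ = 1000, zero diagonal. Note that the
event-count product in the denominator makes weights scale like
(reliability/m)²: flooding a channel with extra events *weakens* its incoming
edge weights — a property that shaped the synthetic seizure regime (below).

## Eigenmode hierarchy

* Eigenvalue "size" is the squared **modulus** |Λ|² (a complex eigenvalue's
  stretch), never the real part alone. Rotation angles are computed and kept
  on the decomposition object but do not enter any index.
* Layers sort by modulus descending; ties break by angle ascending so the
  order (and everything downstream) is deterministic. Both members of a
  conjugate pair enter the H_se sum — they have identical component moduli
  and hence identical layer measures, and the sum over layers 2..N makes no
  exclusion.
* Eigenvectors are normalized to unit 2-norm before component moduli are
  taken. Banding thresholds AVG + SD and AVG + 2·SD use the mean and
  population standard deviation of that eigenvector's own component moduli
  (not pooled over vectors). Bands are left-open/right-closed; a component of
  exactly zero falls in the weak band by convention. An undivided layer is
  one module of size N, so M₁ = 1 and p₁ = 0 and H_in reduces to |Λ₁|²/N².
* **H_sb normalization.** The per-time-point ratio
  (H_in − H_se)/(H_in + H_se), defined as 0 when both vanish. It is bounded
  in [−1, 1] by construction for the nonnegative H's, sign-preserving, and
  needs no look-ahead over the recording. A recording-max alternative
  (divide H_sb raw by max |H_sb raw| over the time course) is available as
  `hsb_normalization="global_max"` for comparison; it is *not* per-time-point
  and is never the default.

## Phase dynamics

* Each annotated phase window is split into `splits_per_phase` (default 2)
  equal sub-intervals; the H_sb values at the evaluation times inside each
  sub-interval feed one Gaussian KDE on a 512-point grid over [−1, 1] with
  Silverman bandwidth. The bandwidth is floored at five grid steps (0.02) so
  degenerate samples (e.g. H_sb exactly 0 throughout a quiet interval, a
  common and meaningful outcome) produce a sharp, well-resolved peak instead
  of a numerically singular one. The curve is renormalized to unit
  trapezoidal integral over the grid, which also absorbs kernel mass falling
  outside [−1, 1] near the boundaries.
* Modes are local maxima (grid endpoints included) with prominence ≥ 5% of
  the peak density.
* **Plunges.** An episode is a drop of the per-interval peak location below
  the running reference by more than the threshold (default 0.3 in
  normalized H_sb units — the data-derived scale at which the synthetic ictal
  fixture registers exactly one episode; exposed in config and reported with
  results), followed by a rebound above the reference minus half the
  threshold; tracking then restarts at the rebound. A monotone decline never
  counts (no rebound), and duplicated intervals add no episodes.

## Synthetic study conditions

The generator emulates the *statistical* structure the pipeline consumes:
Gaussian background noise (sd 5), smooth Gaussian bumps (amplitude 100,
half-width 5 samples) at planted event times, per-channel event rate
1 event/s at 512 Hz, events thinned to ≥ 2M = 20 samples apart, and directed
couplings that inject a follower bump at source time + lag with a stated
probability. It does **not** model neural-mass dynamics, 1/f spectra,
filtering artifacts or electrode geometry, so passing regime tests shows the
pipeline responds correctly to event-level coupling structure — not that it
reproduces any particular patient's electrophysiology.

Regimes are parameter overrides on phase windows:

* **control / interictal** — a sparse random background (each channel pair
  coupled with probability 0.15, single random orientation, propagation
  probability 0.4, lags 3–9 samples). The resulting effective network is
  near-empty or acyclic at most evaluation times, so H_sb hovers around 0.
* **preictal** — a half-reliable directed loop over the focus channels.
* **ictal** — the focus loop at propagation probability 1 (re-entrant
  propagation over the focus subset). A directed loop of f channels
  contributes f comparable eigenmodes, so H_se ≈ (f−1)·H_in and H_sb drops
  toward (2−f)/f (−0.5 for the default 4-channel focus) — the strong-local
  signature. The loop's injected followers double the focus discharge rate,
  emulating hypersynchronous recruitment. A densified all-pair background
  was considered for this regime and rejected: extra injected events inflate
  the per-window event-count normalizer and wash out the focal loop rather
  than strengthening global synchrony.
* **postictal** — back to the sparse background.

Default durations: control 320 s (4 interictal windows), patient 480 s
(interictal 40%, preictal/ictal/postictal 20% each). These sizes give every
analysis sub-interval a handful of 10-s evaluation points while keeping a
full 50-replicate regime experiment at desk scale (tens of seconds).

## Numerical and degenerate-input choices

* Identical config + seed reproduces recordings bit-exactly
  (`numpy.random.default_rng` throughout; iteration order over windows,
  channels and edges is fixed).
* Eigendecomposition uses LAPACK via `numpy.linalg.eig`; conjugate-pair
  moduli agree to 1e−9 and all invariance tests use that tolerance.
* All-zero adjacency snapshots yield H_in = H_se = 0 and H_sb = 0 by
  convention (metastable balance, not missingness).
* Generated events closer than 2M samples are thinned keep-earliest, so the
  detector's spacing guarantee also holds for planted ground truth.

## Known limitations

* Q can in principle exceed 1 under the √(m₁m₂) normalization if an event
  sits exactly half the minimal gap from two consecutive partner events (both
  directions then count); this needs exact integer alignment at the τ
  boundary and was never observed across the random ensembles, but is not
  excluded analytically.
* τ per recording (not per window) means a single very close event pair
  anywhere in the recording tightens coincidence matching everywhere.
* The plunge threshold is a declared stand-in for an operational definition
  of "drastic" peak drops; results tables always report the threshold used.
* KDE peak locations from short intervals (few evaluation points) are noisy;
  the interval scheme trades temporal resolution against peak stability.
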