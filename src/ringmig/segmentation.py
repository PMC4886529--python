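"""Run/rest state segmentation of tangential-velocity series.

Two-step procedure:

1. *Change-point detection.*  Iterative (binary-segmentation) CUSUM analysis:
   within a segment the cumulative sum of deviations from the segment mean,
   ``S_k = sum_{i<=k} (v_i - vbar)``, peaks where the underlying mean
   velocity changes.  A candidate change point is accepted when the CUSUM
   decision statistic exceeds what random permutations of the segment
   produce (permutation bootstrap), and the procedure recurses into the
   resulting pieces.  The default statistic combines the standardized
   single-split CUSUM with a short-window scan over partial-sum increments,
   so brief states embedded in long segments remain detectable.

2. *State classification.*  Each inter-change-point segment is classified by
   the log-log slope ``alpha`` of its time-averaged mean squared displacement
   along the lane: ballistic runs have alpha near 2, diffusive rests near 1;
   the cut is at ``alpha_threshold`` (default 1.5, the midpoint).

Segments tile the velocity series exactly; adjacent segments with equal
labels are merged, so labels alternate — except that two run states of
opposite direction stay distinct, since the zero-crossing between them is a
genuine reorientation even when the intervening rest was too brief to
resolve at the frame rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import PolarTrack, VelocitySeries, arc_distance, tangential_velocity

__all__ = [
    "SegmentationConfig",
    "ChangePointResult",
    "StateSegment",
    "MsdCurve",
    "detect_change_points",
    "msd",
    "classify_segment",
    "segment_track",
    "frame_labels",
]

RUN = "run"
REST = "rest"


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs of the segmentation procedure.

    cp_alpha
        Significance level of the permutation test for each change point.
    n_permutations
        Bootstrap size B of the permutation test.
    min_segment_length
        Minimum segment length in velocity samples (3 samples = 30 min at
        the default 10-min frame interval).
    alpha_threshold
        MSD log-log slope separating rest (below) from run (at or above).
    max_lag_fraction
        MSD lags go up to this fraction of the segment length (at least 2).
    statistic
        CUSUM decision statistic.  ``"scan"`` (default) combines the
        variance-standardized single-split statistic |S_k| / sqrt(k(n-k)/n)
        with a windowed scan over partial-sum increments (window lengths up
        to ``scan_max_window``), both in noise-SD units; the scan term keeps
        power for short states embedded in long segments, which a plain
        single-change statistic misses.  ``"range"`` tests the raw CUSUM
        range max S - min S.
    scan_max_window
        Largest scan-window length in velocity samples (default 12, i.e.
        2 h at 10-min frames); only used by the ``"scan"`` statistic.
    smooth_window
        Optional centered moving-average window on the velocity series
        before change-point detection; 1 disables smoothing (default: no
        smoothing is applied).
    censor_horizon
        States starting within this many hours of the track end are flagged
        censored (excluded later from survival estimation), default 20 h.
    seed
        Seed of the permutation bootstrap (required for reproducibility).
    """

    cp_alpha: float = 0.05
    n_permutations: int = 1000
    min_segment_length: int = 3
    alpha_threshold: float = 1.5
    max_lag_fraction: float = 0.25
    statistic: str = "scan"
    scan_max_window: int = 12
    smooth_window: int = 1
    censor_horizon: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic not in ("scan", "range"):
            raise ValueError("statistic must be 'scan' or 'range'")


@dataclass
class ChangePointResult:
    """Detected change points (velocity-sample indices) and their bootstrap
    confidence levels (1 - permutation p-value)."""

    indices: list[int]
    significance: list[float]

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class StateSegment:
    """A maximal run or rest interval of one track.

    ``start_idx``/``end_idx`` index velocity samples, half-open [start, end);
    velocity sample ``i`` covers the frame interval [t_i, t_{i+1}), so a
    segment of ``k`` samples spans ``k`` frame intervals and k+1 frames.
    """

    track_id: str
    start_idx: int
    end_idx: int
    label: str
    mean_velocity: float
    duration: float
    t_start: float
    censored: bool

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class MsdCurve:
    """Time-averaged MSD of a 1D position series and its log-log slope."""

    lag: np.ndarray
    msd: np.ndarray
    loglog_slope: float


# ---------------------------------------------------------------------------
# change-point detection


def _split_z(c: np.ndarray, n: int) -> np.ndarray:
    """Standardized single-split CUSUM |S_k| / sqrt(k(n-k)/n), k = 1..n-1.

    ``c`` holds partial sums with a leading zero (last axis length n + 1).
    """
    k = np.arange(1, n)
    return np.abs(c[..., 1:n]) / np.sqrt(k * (n - k) / n)


def _window_lengths(n: int, min_len: int, max_window: int) -> range:
    return range(min_len, min(max_window, n - min_len) + 1)


def _observed_split(values: np.ndarray, min_len: int, config: SegmentationConfig):
    """Candidate change point(s) and decision statistic for one segment.

    Returns ``(candidates, stat)`` where candidates are velocity-sample
    indices at which new segments would start (one for a plain split, two
    for a short embedded state found by the scan term), restricted so all
    resulting pieces have at least ``min_len`` samples; or ``None`` when no
    valid split exists.
    """
    n = len(values)
    if n < 2 * min_len:
        return None
    c = np.concatenate([[0.0], np.cumsum(values - values.mean())])
    k = np.arange(1, n)
    valid = (k >= min_len) & (k <= n - min_len)
    if not np.any(valid):
        return None
    if config.statistic == "range":
        stat = float(max(c.max(), 0.0) - min(c.min(), 0.0))
        masked = np.where(valid, np.abs(c[1:n]), -np.inf)
        return [int(np.argmax(masked)) + 1], stat

    z = np.where(valid, _split_z(c, n), -np.inf)
    best_k = int(np.argmax(z)) + 1
    best = (float(z[best_k - 1]), [best_k])
    for L in _window_lengths(n, min_len, config.scan_max_window):
        w = np.abs(c[L:] - c[:-L]) / np.sqrt(L * (1.0 - L / n))
        i = int(np.argmax(w))
        if w[i] > best[0]:
            cands = [j for j in (i, i + L) if min_len <= j <= n - min_len]
            if cands:
                best = (float(w[i]), cands)
    return best[1], best[0]


def _permutation_pvalue(
    values: np.ndarray, observed: float, min_len: int,
    config: SegmentationConfig, rng,
) -> float:
    """Monte Carlo p-value of the CUSUM statistic under random reshuffling.

    Uses the standard (1 + #{perm >= obs}) / (B + 1) estimator, which keeps
    the test level at or below alpha under exchangeability.
    """
    n = len(values)
    b = config.n_permutations
    dev = values - values.mean()
    mat = np.tile(dev, (b, 1))
    rng.permuted(mat, axis=1, out=mat)
    c = np.concatenate([np.zeros((b, 1)), np.cumsum(mat, axis=1)], axis=1)
    if config.statistic == "range":
        stats = np.maximum(c.max(axis=1), 0.0) - np.minimum(c.min(axis=1), 0.0)
    else:
        k = np.arange(1, n)
        valid = (k >= min_len) & (k <= n - min_len)
        stats = _split_z(c, n)[:, valid].max(axis=1)
        for L in _window_lengths(n, min_len, config.scan_max_window):
            w = np.abs(c[:, L:] - c[:, :-L]) / np.sqrt(L * (1.0 - L / n))
            np.maximum(stats, w.max(axis=1), out=stats)
    return (1.0 + np.count_nonzero(stats >= observed)) / (b + 1.0)


def detect_change_points(
    vs: VelocitySeries | np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    rng: np.random.Generator | None = None,
) -> ChangePointResult:
    """Iterative CUSUM change-point detection on a velocity series.

    Binary segmentation: the best split of the whole series is tested by
    permutation bootstrap; if accepted the procedure recurses left and right
    until no split is significant or segments reach ``min_segment_length``.
    Detection is invariant to sign flips and translations of the series.
    """
    v = np.asarray(vs.v if isinstance(vs, VelocitySeries) else vs, dtype=float)
    min_len = config.min_segment_length
    if len(v) < 2 * min_len:
        warnings.warn(
            f"series of length {len(v)} too short for change-point detection "
            f"(need >= {2 * min_len})",
            stacklevel=2,
        )
        return ChangePointResult(indices=[], significance=[])
    if rng is None:
        rng = np.random.default_rng(config.seed)

    found: list[tuple[int, float]] = []

    def recurse(a: int, b: int) -> None:
        seg = v[a:b]
        split = _observed_split(seg, min_len, config)
        if split is None:
            return
        cands, observed = split
        if observed <= 0.0:  # constant segment
            return
        p = _permutation_pvalue(seg, observed, min_len, config, rng)
        if p <= config.cp_alpha:
            cuts = [a, *(a + k for k in cands), b]
            for cp in cuts[1:-1]:
                found.append((cp, 1.0 - p))
            for lo, hi in zip(cuts[:-1], cuts[1:]):
                recurse(lo, hi)

    recurse(0, len(v))
    found.sort()
    return ChangePointResult(
        indices=[c for c, _ in found], significance=[s for _, s in found]
    )


# ---------------------------------------------------------------------------
# MSD classification


def msd(
    positions: np.ndarray, dt: float, max_lag_fraction: float = 0.25
) -> MsdCurve:
    """Time-averaged MSD of a 1D position series with its log-log slope.

    MSD(j*dt) averages (x_{i+j} - x_i)^2 over all frame pairs; lags run from
    1 up to ``max_lag_fraction`` of the series length, but always at least 5
    (or all available lags on shorter series) so that brief segments still
    yield a usable slope.  The slope is the least-squares line through
    (log lag, log MSD); zero MSD values (strictly stationary series) are
    excluded, and a series with fewer than 2 usable lags gets slope 0.
    """
    x = np.asarray(positions, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 positions for an MSD slope")
    max_lag = min(n - 1, max(5, int(np.floor(n * max_lag_fraction))))
    lags = np.arange(0, max_lag + 1)
    vals = np.empty(max_lag + 1)
    vals[0] = 0.0
    for j in range(1, max_lag + 1):
        d = x[j:] - x[:-j]
        vals[j] = np.mean(d * d)
    usable = vals[1:] > 0
    if np.count_nonzero(usable) < 2:
        slope = 0.0
    else:
        ll = np.log(lags[1:][usable] * dt)
        lm = np.log(vals[1:][usable])
        slope = float(np.polyfit(ll, lm, 1)[0])
    return MsdCurve(lag=lags * dt, msd=vals, loglog_slope=slope)


def classify_segment(
    positions: np.ndarray,
    dt: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> str:
    """Classify a segment (1D arc positions) as run or rest by MSD slope."""
    curve = msd(positions, dt, config.max_lag_fraction)
    return RUN if curve.loglog_slope >= config.alpha_threshold else REST


# ---------------------------------------------------------------------------
# full per-track segmentation


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return v
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(v, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(v)]


def _merge_adjacent_short(bounds: list[int], min_samples: int) -> list[int]:
    """Fuse runs of consecutive short pieces left by over-splitting.

    Adjacent pieces that are *both* shorter than ``min_samples`` are joined
    so classification sees one window long enough for a stable MSD slope;
    isolated short segments (a brief genuine state between two long ones)
    are left untouched.
    """
    bounds = list(bounds)
    while True:
        lengths = np.diff(bounds)
        pair = next(
            (
                j
                for j in range(len(lengths) - 1)
                if lengths[j] < min_samples and lengths[j + 1] < min_samples
            ),
            None,
        )
        if pair is None:
            return bounds
        del bounds[pair + 1]


def _merge_short_segments(bounds: list[int], v: np.ndarray, min_samples: int) -> list[int]:
    """Remove boundaries so every segment has >= ``min_samples`` velocity
    samples, merging each short segment into the neighbor whose mean
    velocity is closest."""
    bounds = list(bounds)
    while True:
        lengths = np.diff(bounds)
        if len(lengths) <= 1 or np.all(lengths >= min_samples):
            break
        i = int(np.argmin(lengths))
        a, b = bounds[i], bounds[i + 1]
        seg_mean = v[a:b].mean()
        left = v[bounds[i - 1] : a].mean() if i > 0 else None
        right = v[b : bounds[i + 2]].mean() if i + 1 < len(lengths) else None
        if left is None:
            drop = i + 1  # merge right
        elif right is None:
            drop = i
        elif abs(seg_mean - left) <= abs(seg_mean - right):
            drop = i
        else:
            drop = i + 1
        del bounds[drop]
    return bounds


def segment_track(
    pt: PolarTrack, config: SegmentationConfig = SegmentationConfig()
) -> list[StateSegment]:
    """Segment one polar track into alternating run and rest states.

    Returns segments that tile the velocity series exactly.  Each carries
    the signed within-state mean tangential velocity, its duration, and a
    censoring flag (state starts within ``censor_horizon`` hours of the
    track end).
    """
    vs = tangential_velocity(pt)
    v = _smooth(vs.v, config.smooth_window)
    d_arc = arc_distance(pt)
    dt = vs.dt

    cps = detect_change_points(v, config)
    bounds = [0, *cps.indices, len(v)]
    # MSD classification needs >= 4 frames (3 velocity samples)
    bounds = _merge_short_segments(bounds, v, min_samples=3)
    bounds = _merge_adjacent_short(bounds, min_samples=6)

    def same_direction(x: tuple[int, int], a: int, b: int) -> bool:
        return np.sign(v[x[0] : x[1]].mean()) == np.sign(v[a:b].mean())

    # MSD classification first, on every piece that can support a slope;
    # the slope of very short pieces is unreliable, so they are re-assigned
    # afterwards from the run/rest velocity bimodality calibrated on the
    # long pieces of the same track (runs cluster at +-v_run, rests at 0)
    pieces = list(zip(bounds[:-1], bounds[1:]))
    labels = []
    for a, b in pieces:
        if b - a >= 3:
            labels.append(classify_segment(d_arc[a : b + 1], dt, config))
        else:  # single short segment spanning the whole (short) series
            labels.append(REST)
    long_run_speeds = [
        abs(v[a:b].mean())
        for (a, b), lab in zip(pieces, labels)
        if lab == RUN and b - a >= 8
    ]
    if long_run_speeds:
        v_scale = float(np.median(long_run_speeds))
        labels = [
            (RUN if abs(v[a:b].mean()) >= v_scale / 2 else REST)
            if b - a < 8
            else lab
            for (a, b), lab in zip(pieces, labels)
        ]

    # merge same-label neighbors; run states are directional, so two runs
    # of opposite sign stay distinct (the change point between them is a
    # genuine reorientation even when the intervening rest was too brief
    # to resolve)
    merged: list[tuple[int, int, str]] = []
    for (a, b), lab in zip(zip(bounds[:-1], bounds[1:]), labels):
        if merged and merged[-1][2] == lab and (
            lab == REST or same_direction(merged[-1], a, b)
        ):
            merged[-1] = (merged[-1][0], b, lab)
        else:
            merged.append((a, b, lab))

    track_end = pt.t[-1]
    segments = []
    for a, b, lab in merged:
        segments.append(
            StateSegment(
                track_id=pt.track_id,
                start_idx=a,
                end_idx=b,
                label=lab,
                mean_velocity=float(vs.v[a:b].mean()),
                duration=(b - a) * dt,
                t_start=float(pt.t[a]),
                censored=bool(pt.t[a] > track_end - config.censor_horizon),
            )
        )
    return segments


def frame_labels(segments: list[StateSegment], n_frames: int) -> np.ndarray:
    """Per-frame state labels implied by a segment tiling.

    Frame ``i`` takes the label of the velocity interval containing it; the
    final frame inherits the last segment's label.
    """
    out = np.empty(n_frames, dtype=object)
    for seg in segments:
        out[seg.start_idx : seg.end_idx] = seg.label
    if segments:
        out[n_frames - 1] = segments[-1].label
    return out
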