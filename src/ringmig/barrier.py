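"""Cell-barrier interaction statistics on ring-shaped lanes.

A PEGylated (non-adhesive) gap of width ``d_gap`` interrupts the adhesive
lane.  An *encounter* opens when the nucleus enters the zone within 50 um of
the barrier and closes when it leaves the zone again: leaving on the entry
side is a *reversal*, on the far side a *transit*.  From encounter counts at
several gap widths this module computes

* per-width turning/transit probabilities with exact (Clopper-Pearson)
  binomial confidence intervals,
* the transit-decay length ``mu_trans`` of the exponential model
  ``P_trans(d_gap) = (1 - P_turn(0)) * exp(-d_gap / mu_trans)``,
* the spontaneous turning probability ``P_turn(0)`` from virtual zones on
  barrier-free rings,
* run/rest occupancy versus distance to the barrier,
* and the invasion-depth survival law ``S_inv(d) = s0 * exp(-d / mu_inv)``
  from independently measured lamellipodium invasion depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .geometry import PolarTrack
from .segmentation import RUN, StateSegment, frame_labels

__all__ = [
    "BarrierSpec",
    "BarrierEncounter",
    "TurnEstimate",
    "TransitCurve",
    "TransitDecayFit",
    "InvasionFit",
    "BarrierAnalysisError",
    "clopper_pearson",
    "signed_arc_offset",
    "detect_encounters",
    "turning_probability",
    "turning_probability_from_counts",
    "spontaneous_turning",
    "transit_curve",
    "fit_transit_decay",
    "state_occupancy_profile",
    "fit_invasion_survival",
]

TRANSIT = "transit"
REVERSAL = "reversal"
CENSORED = "censored"


class BarrierAnalysisError(ValueError):
    """Raised when barrier statistics cannot be computed."""


@dataclass(frozen=True)
class BarrierSpec:
    """Location and size of a PEGylated gap on the ring.

    ``zone_half_width`` is the encounter-zone extent measured from the gap
    edge (``reference="edge"``, default) or from the gap center
    (``reference="center"``).
    """

    angular_position: float
    d_gap: float
    zone_half_width: float = 50.0
    reference: str = "edge"

    def __post_init__(self) -> None:
        if self.d_gap < 0:
            raise ValueError("d_gap must be >= 0")
        if self.zone_half_width <= self.d_gap / 2:
            raise ValueError("zone_half_width must exceed d_gap / 2")
        if self.reference not in ("edge", "center"):
            raise ValueError("reference must be 'edge' or 'center'")

    @property
    def zone_arc(self) -> float:
        """Arc distance from the gap center to the zone boundary, um."""
        if self.reference == "edge":
            return self.d_gap / 2 + self.zone_half_width
        return self.zone_half_width


@dataclass
class BarrierEncounter:
    """One entry of a cell into the barrier zone and its outcome."""

    track_id: str
    entry_frame: int
    exit_frame: int | None
    entry_side: int
    exit_side: int | None
    outcome: str


@dataclass
class TurnEstimate:
    """Turning probability with an exact 95% binomial CI."""

    p_turn: float
    ci95: tuple[float, float]
    n_reversals: int
    n_transits: int

    @property
    def n(self) -> int:
        return self.n_reversals + self.n_transits


@dataclass
class TransitDecayFit:
    """One-parameter exponential fit of P_trans(d_gap)."""

    mu_trans: float
    ci95: tuple[float, float]
    p_turn0: float


@dataclass
class TransitCurve:
    """Per-width transit statistics plus the exponential decay fit."""

    table: pd.DataFrame
    fit: TransitDecayFit
    p_turn0: float


@dataclass
class InvasionFit:
    """Exponential fit of the invasion-depth survival S_inv(d)."""

    depths: np.ndarray
    s0: float
    mu_inv: float
    ci95: tuple[float, float]

    @property
    def n(self) -> int:
        return len(self.depths)


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes out of n."""
    if n <= 0:
        raise BarrierAnalysisError("n must be positive")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=conf, method="exact")
    return (float(ci.low), float(ci.high))


def signed_arc_offset(pt: PolarTrack, spec: BarrierSpec) -> np.ndarray:
    """Arc position relative to the gap center, wrapped to (-pi R, pi R]."""
    rel = np.mod(pt.phi - spec.angular_position + np.pi, 2 * np.pi) - np.pi
    return pt.geometry.radius * rel


def detect_encounters(pt: PolarTrack, spec: BarrierSpec) -> list[BarrierEncounter]:
    """Find all zone entries of one track and classify their outcomes.

    An encounter opens at the first frame with arc distance to the gap
    center below the zone boundary and closes at the first frame outside
    again; a track ending inside the zone leaves the encounter censored.
    A track that *starts* inside the zone has no observed entry (the
    approach side is unknown), so frames before its first exit are skipped.
    """
    s = signed_arc_offset(pt, spec)
    inside = np.abs(s) < spec.zone_arc
    encounters: list[BarrierEncounter] = []
    open_entry: int | None = None
    start = 0
    while start < len(s) and inside[start]:
        start += 1
    for i in range(start, len(s)):
        if inside[i] and open_entry is None:
            open_entry = i
        elif not inside[i] and open_entry is not None:
            entry_side = 1 if s[open_entry] >= 0 else -1
            exit_side = 1 if s[i] >= 0 else -1
            encounters.append(
                BarrierEncounter(
                    track_id=pt.track_id,
                    entry_frame=open_entry,
                    exit_frame=i,
                    entry_side=entry_side,
                    exit_side=exit_side,
                    outcome=REVERSAL if exit_side == entry_side else TRANSIT,
                )
            )
            open_entry = None
    if open_entry is not None:
        encounters.append(
            BarrierEncounter(
                track_id=pt.track_id,
                entry_frame=open_entry,
                exit_frame=None,
                entry_side=1 if s[open_entry] >= 0 else -1,
                exit_side=None,
                outcome=CENSORED,
            )
        )
    return encounters


def turning_probability_from_counts(n_reversals: int, n_transits: int) -> TurnEstimate:
    """P_turn = reversals / (reversals + transits) with Clopper-Pearson CI."""
    n = n_reversals + n_transits
    if n == 0:
        raise BarrierAnalysisError("no non-censored encounters")
    return TurnEstimate(
        p_turn=n_reversals / n,
        ci95=clopper_pearson(n_reversals, n),
        n_reversals=n_reversals,
        n_transits=n_transits,
    )


def turning_probability(encounters: list[BarrierEncounter]) -> TurnEstimate:
    """Turning probability over a set of encounters (censored ones excluded)."""
    r = sum(1 for e in encounters if e.outcome == REVERSAL)
    t = sum(1 for e in encounters if e.outcome == TRANSIT)
    return turning_probability_from_counts(r, t)


@dataclass
class SpontaneousTurning:
    """Spontaneous turning probability from virtual zones, with pooled CI."""

    p_turn0: float
    ci95: tuple[float, float]
    per_zone: pd.DataFrame


def spontaneous_turning(
    polar_tracks: list[PolarTrack],
    n_regions: int = 8,
    region_width: float = 50.0,
) -> SpontaneousTurning:
    """P_turn(0): mean spontaneous turning probability over ``n_regions``
    equally spaced virtual regions of total arc width ``region_width`` um on
    barrier-free rings, with a pooled Clopper-Pearson 95% CI."""
    rows = []
    total_r = total_t = 0
    for k in range(n_regions):
        spec = BarrierSpec(
            angular_position=2 * np.pi * k / n_regions,
            d_gap=0.0,
            zone_half_width=region_width / 2,
        )
        r = t = 0
        for pt in polar_tracks:
            for e in detect_encounters(pt, spec):
                if e.outcome == REVERSAL:
                    r += 1
                elif e.outcome == TRANSIT:
                    t += 1
        rows.append({"region": k, "n_reversals": r, "n_transits": t,
                     "p_turn": r / (r + t) if r + t else np.nan})
        total_r += r
        total_t += t
    if total_r + total_t == 0:
        raise BarrierAnalysisError("no virtual-zone encounters on barrier-free rings")
    per_zone = pd.DataFrame(rows)
    p0 = float(np.nanmean(per_zone["p_turn"]))
    return SpontaneousTurning(
        p_turn0=p0,
        ci95=clopper_pearson(total_r, total_r + total_t),
        per_zone=per_zone,
    )


def _binomial_se(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    # shrunken proportion keeps weights finite at k = 0 or k = n
    p = (k + 0.5) / (n + 1.0)
    return np.sqrt(p * (1.0 - p) / n)


def fit_transit_decay(
    d_gaps: np.ndarray,
    n_encounters: np.ndarray,
    n_transits: np.ndarray,
    p_turn0: float,
) -> TransitDecayFit:
    """Weighted one-parameter fit of P_trans(d) = (1 - P_turn0) exp(-d/mu).

    The intercept is fixed at 1 - P_turn0; weights are inverse binomial
    variances of the per-width transit fractions; the 95% CI comes from the
    fit covariance.
    """
    d = np.asarray(d_gaps, dtype=float)
    n = np.asarray(n_encounters, dtype=float)
    k = np.asarray(n_transits, dtype=float)
    if len(np.unique(d)) < 2:
        raise BarrierAnalysisError("need >= 2 distinct gap widths")
    if np.all(k == 0):
        raise BarrierAnalysisError("all transit counts are zero; no decay length")
    p_hat = k / n
    amp = 1.0 - p_turn0

    def model(dd, mu):
        return amp * np.exp(-dd / mu)

    popt, pcov = optimize.curve_fit(
        model, d, p_hat, p0=[np.median(d)], sigma=_binomial_se(k, n),
        absolute_sigma=True, maxfev=10000,
    )
    mu = float(popt[0])
    se = float(np.sqrt(pcov[0, 0]))
    return TransitDecayFit(
        mu_trans=mu, ci95=(mu - 1.96 * se, mu + 1.96 * se), p_turn0=float(p_turn0)
    )


def transit_curve(
    encounters_by_gap: dict[float, list[BarrierEncounter]], p_turn0: float
) -> TransitCurve:
    """Per-width transit table plus the exponential decay-length fit."""
    rows = []
    for d_gap in sorted(encounters_by_gap):
        est = turning_probability(encounters_by_gap[d_gap])
        ci = clopper_pearson(est.n_transits, est.n)
        rows.append(
            {
                "d_gap": d_gap,
                "n_encounters": est.n,
                "n_transits": est.n_transits,
                "p_trans": est.n_transits / est.n,
                "p_turn": est.p_turn,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    table = pd.DataFrame(rows)
    fit = fit_transit_decay(
        table["d_gap"].to_numpy(),
        table["n_encounters"].to_numpy(),
        table["n_transits"].to_numpy(),
        p_turn0,
    )
    return TransitCurve(table=table, fit=fit, p_turn0=float(p_turn0))


def state_occupancy_profile(
    segments_by_track: dict[str, list[StateSegment]],
    polar_by_track: dict[str, PolarTrack],
    spec: BarrierSpec,
    bin_width: float = 10.0,
) -> pd.DataFrame:
    """Run/rest occupancy versus arc distance to the barrier.

    For each distance bin the fraction of cell-frames in the run versus the
    rest state is reported (fractions in a bin sum to 1).  Distance is
    measured from the gap edge along the arc.
    """
    dists, is_run = [], []
    for tid, segs in segments_by_track.items():
        pt = polar_by_track[tid]
        s = signed_arc_offset(pt, spec)
        dist = np.maximum(np.abs(s) - spec.d_gap / 2, 0.0)
        labels = frame_labels(segs, pt.n_frames)
        dists.append(dist)
        is_run.append(labels == RUN)
    dist = np.concatenate(dists)
    run = np.concatenate(is_run).astype(float)
    edges = np.arange(0.0, dist.max() + bin_width, bin_width)
    idx = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        mask = idx == b
        if not np.any(mask):
            continue
        f_run = float(run[mask].mean())
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "run_frac": f_run,
                "rest_frac": 1.0 - f_run,
                "n_frames": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_invasion_survival(depths: np.ndarray) -> InvasionFit:
    """Fit S_inv(d) = s0 * exp(-d / mu_inv) to measured invasion depths.

    The empirical survival is evaluated at the observed depths; the linear
    fit of log S runs over the support where S > 0, i.e. every unique depth
    below the largest one.  The 95% CI on mu_inv comes from the OLS slope.
    """
    d = np.sort(np.asarray(depths, dtype=float))
    if len(d) < 10:
        raise BarrierAnalysisError("need >= 10 invasion depths")
    uniq = np.unique(d)
    if len(uniq) < 3:
        raise BarrierAnalysisError("invasion depths are (nearly) degenerate")
    pts = uniq[:-1]  # S > 0 strictly below the largest depth
    S = np.array([np.mean(d > p) for p in pts])
    y = np.log(S)
    res = sm.OLS(y, sm.add_constant(pts)).fit()
    slope = res.params[1]
    if slope >= 0:
        raise BarrierAnalysisError("invasion-depth survival does not decay")
    lo, hi = res.conf_int(alpha=0.05)[1]
    mu = -1.0 / slope
    ci = (-1.0 / lo, (-1.0 / hi) if hi < 0 else np.inf)
    return InvasionFit(
        depths=d,
        s0=float(np.exp(res.params[0])),
        mu_inv=float(mu),
        ci95=(float(ci[0]), float(ci[1])),
    )
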