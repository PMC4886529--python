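"""Motility parameters: run velocity and run/rest persistence times.

From a segmented ensemble of tracks this module estimates

* ``v_run``  -- mean over run states of the absolute within-state mean
  tangential velocity, with its SEM across states;
* ``v_mean`` -- per-cell mean frame speed along the lane, averaged across
  cells (includes rest periods, hence smaller than ``v_run``);
* ``tau_run``, ``tau_rest`` -- exponential persistence times from the tail
  of the state-duration survival function S(t) = P(T > t).

Censoring: to avoid bias from finite observation windows, only states that
start at least 20 h before the end of their track enter the survival
estimate, and the fit window ends at 20 h.  The tail fit starts where the
survival is clearly exponential: above 5 h for runs, 2.5 h for rests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .segmentation import RUN, REST, StateSegment

__all__ = [
    "SurvivalCurve",
    "ExponentialFit",
    "VelocitySummary",
    "MotilityError",
    "survival_function",
    "fit_exponential_tail",
    "run_velocity",
    "mean_velocity",
    "motility_parameters",
    "RUN_FIT_TMIN",
    "REST_FIT_TMIN",
    "FIT_TMAX",
]

#: lower edge of the exponential-tail fit window, hours
RUN_FIT_TMIN = 5.0
REST_FIT_TMIN = 2.5
#: upper edge of the fit window (also the censoring horizon), hours
FIT_TMAX = 20.0


class MotilityError(ValueError):
    """Raised when survival curves or fits cannot be computed."""


@dataclass
class SurvivalCurve:
    """Empirical survival S(t) = P(T > t) of uncensored state durations."""

    durations: np.ndarray
    t_grid: np.ndarray
    S: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.durations)

    def evaluate(self, t):
        """S(t) for arbitrary t (step function; scalar in, scalar out)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        s = np.mean(self.durations[None, :] > t_arr[:, None], axis=1)
        return s if np.ndim(t) else float(s[0])


@dataclass
class ExponentialFit:
    """Exponential-tail fit S(t) ~ exp(-t/tau) with a 99% CI on tau."""

    tau: float
    ci99: tuple[float, float]
    fit_range: tuple[float, float]
    n_states: int


@dataclass
class VelocitySummary:
    """Run-velocity and/or mean-velocity summary of an ensemble."""

    v_run: float = np.nan
    v_run_sem: float = np.nan
    v_mean: float = np.nan
    v_mean_sem: float = np.nan
    n_run_states: int = 0
    n_cells: int = 0


def survival_function(segments: list[StateSegment]) -> SurvivalCurve:
    """Empirical survival of state durations, censored states excluded.

    ``segments`` should all carry one label (run or rest); censoring was
    flagged at segmentation time (state starts within 20 h of track end).
    """
    durations = np.sort([s.duration for s in segments if not s.censored])
    if len(durations) == 0:
        raise MotilityError("insufficient uncensored states")
    t_grid = np.concatenate([[0.0], np.unique(durations)])
    S = np.array([np.mean(durations > t) for t in t_grid])
    return SurvivalCurve(durations=durations, t_grid=t_grid, S=S)


def fit_exponential_tail(
    sc: SurvivalCurve, t_min: float, t_max: float = FIT_TMAX
) -> ExponentialFit:
    """Fit log S(t) by ordinary least squares over (t_min, t_max].

    The support points are the observed duration values inside the window
    where S > 0; the slope is -1/tau and the 99% confidence interval of tau
    comes from the slope's OLS interval.
    """
    if sc.evaluate(t_min) <= 0.0:
        raise MotilityError(f"survival reaches zero at or before t_min = {t_min} h")
    pts = sc.t_grid[(sc.t_grid > t_min) & (sc.t_grid <= t_max) & (sc.S > 0)]
    if len(pts) < 5:
        raise MotilityError(
            f"only {len(pts)} support points in ({t_min}, {t_max}] h; need >= 5"
        )
    y = np.log(sc.evaluate(pts))
    res = sm.OLS(y, sm.add_constant(pts)).fit()
    slope = res.params[1]
    if slope >= 0:
        raise MotilityError("survival tail does not decay; tau undefined")
    lo, hi = res.conf_int(alpha=0.01)[1]
    tau = -1.0 / slope
    ci = (-1.0 / lo, (-1.0 / hi) if hi < 0 else np.inf)
    n_states = int(np.count_nonzero((sc.durations > t_min) & (sc.durations <= t_max)))
    return ExponentialFit(
        tau=float(tau), ci99=(float(ci[0]), float(ci[1])),
        fit_range=(t_min, t_max), n_states=n_states,
    )


def run_velocity(segments: list[StateSegment]) -> VelocitySummary:
    """v_run = mean over run states of |within-state mean velocity|, with SEM.

    Censored run states still contribute: the censoring rule applies only to
    persistence-time estimation.
    """
    runs = [s for s in segments if s.label == RUN]
    if not runs:
        raise MotilityError("no run states")
    speeds = np.array([abs(s.mean_velocity) for s in runs])
    sem = speeds.std(ddof=1) / np.sqrt(len(speeds)) if len(speeds) > 1 else np.nan
    return VelocitySummary(
        v_run=float(speeds.mean()),
        v_run_sem=float(sem),
        n_run_states=len(speeds),
        n_cells=len({s.track_id for s in runs}),
    )


def mean_velocity(velocity_by_track: dict[str, np.ndarray]) -> VelocitySummary:
    """v_mean: per cell the mean of |v_i| over the whole track, then the
    mean and SEM across cells."""
    if not velocity_by_track:
        raise MotilityError("no tracks")
    per_cell = np.array([np.mean(np.abs(v)) for v in velocity_by_track.values()])
    sem = per_cell.std(ddof=1) / np.sqrt(len(per_cell)) if len(per_cell) > 1 else np.nan
    return VelocitySummary(
        v_mean=float(per_cell.mean()), v_mean_sem=float(sem), n_cells=len(per_cell)
    )


def motility_parameters(
    segments: list[StateSegment],
    velocity_by_track: dict[str, np.ndarray] | None = None,
) -> dict:
    """Assemble the trajectory-parameter JSON for one condition.

    Returns a dict with v_run (+SEM), tau_run / tau_rest (+99% CIs), and,
    when per-track velocity series are supplied, v_mean (+SEM).
    """
    runs = [s for s in segments if s.label == RUN]
    rests = [s for s in segments if s.label == REST]
    fit_run = fit_exponential_tail(survival_function(runs), RUN_FIT_TMIN)
    fit_rest = fit_exponential_tail(survival_function(rests), REST_FIT_TMIN)
    vel = run_velocity(segments)
    params = {
        "v_run": vel.v_run,
        "v_run_sem": vel.v_run_sem,
        "tau_run": fit_run.tau,
        "tau_run_ci99": list(fit_run.ci99),
        "tau_rest": fit_rest.tau,
        "tau_rest_ci99": list(fit_rest.ci99),
        "n_run_states": vel.n_run_states,
        "n_rest_states": len(rests),
        "n_cells": len({s.track_id for s in segments}),
    }
    if velocity_by_track is not None:
        vm = mean_velocity(velocity_by_track)
        params["v_mean"] = vm.v_mean
        params["v_mean_sem"] = vm.v_mean_sem
    return params
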