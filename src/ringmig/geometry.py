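"""Ring geometry: circle fit, polar projection, tangential velocity.

Cells confined to a ring-shaped adhesive lane move quasi-one-dimensionally
along the lane.  All downstream analysis therefore works on the arc-length
coordinate: the track is projected onto polar coordinates around the ring
center, and the signed tangential velocity ``v_i = R * (phi_{i+1} - phi_i) / dt``
(um/h, counterclockwise positive) is the primary observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RingGeometry",
    "PolarTrack",
    "VelocitySeries",
    "CircleFitError",
    "PolarProjectionError",
    "fit_circle",
    "to_polar",
    "tangential_velocity",
    "arc_distance",
    "polar_to_xy",
    "ring_from_tracks",
]


class CircleFitError(ValueError):
    """Raised when points do not determine a circle."""


class PolarProjectionError(ValueError):
    """Raised when a track cannot be projected to polar coordinates."""


@dataclass(frozen=True)
class RingGeometry:
    """Center and radius of the ring-shaped micropattern, in um."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"ring radius must be positive, got {self.radius}")

    @property
    def perimeter(self) -> float:
        return 2.0 * np.pi * self.radius


@dataclass
class PolarTrack:
    """A track in polar coordinates around the ring center.

    ``phi`` is unwrapped so that consecutive differences lie in (-pi, pi];
    ``r`` is the radial distance from the center in um.
    """

    track_id: str
    t: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    geometry: RingGeometry

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class VelocitySeries:
    """Signed tangential velocity per frame interval.

    ``v[i]`` (um/h) is assigned to the half-open interval [t[i], t[i] + dt).
    """

    t: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.t) != len(self.v):
            raise ValueError("t and v must have equal length")

    def __len__(self) -> int:
        return len(self.v)


def fit_circle(points: np.ndarray) -> RingGeometry:
    """Algebraic (Kasa) least-squares circle through ``points`` (n, 2).

    Solves the linear system 2*cx*x + 2*cy*y + d = x^2 + y^2.  Adequate at
    the few-um noise level of nucleus tracking; validated against a full
    geometric (nonlinear) fit in the test suite.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise CircleFitError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2.0 * x, 2.0 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise CircleFitError("points are collinear or otherwise degenerate")
    cx, cy, d = sol
    r2 = d + cx * cx + cy * cy
    if not np.isfinite(r2) or r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    return RingGeometry(center=(float(cx), float(cy)), radius=float(np.sqrt(r2)))


def ring_from_tracks(tracks, nominal_radius: float | None = None) -> RingGeometry:
    """Fit the ring center to all positions of one or more tracks.

    When ``nominal_radius`` is given (the design radius of the micropattern,
    50 um in the reference assay) it replaces the fitted radius, which is the
    radius actually used to convert angular to arc-length displacement.
    """
    pts = np.concatenate([np.column_stack([tr.x, tr.y]) for tr in tracks])
    g = fit_circle(pts)
    if nominal_radius is not None:
        g = RingGeometry(center=g.center, radius=float(nominal_radius))
    return g


def to_polar(track, geometry: RingGeometry) -> PolarTrack:
    """Project a Cartesian track to (r, phi) around the ring center.

    phi is unwrapped, so multi-revolution tracks accumulate angle
    monotonically rather than jumping at +-pi.
    """
    dx = np.asarray(track.x, dtype=float) - geometry.center[0]
    dy = np.asarray(track.y, dtype=float) - geometry.center[1]
    r = np.hypot(dx, dy)
    if np.any(r == 0.0):
        raise PolarProjectionError(
            f"track {track.track_id}: frame coincides with ring center, phi undefined"
        )
    phi = np.unwrap(np.arctan2(dy, dx))
    return PolarTrack(
        track_id=track.track_id,
        t=np.asarray(track.t, dtype=float),
        r=r,
        phi=phi,
        geometry=geometry,
    )


def tangential_velocity(pt: PolarTrack) -> VelocitySeries:
    """Signed tangential velocity v_i = R * (phi_{i+1} - phi_i) / dt in um/h."""
    if pt.n_frames < 2:
        raise ValueError("need at least 2 frames for a velocity")
    dt_steps = np.diff(pt.t)
    v = pt.geometry.radius * np.diff(pt.phi) / dt_steps
    return VelocitySeries(t=pt.t[:-1], v=v, dt=float(np.median(dt_steps)))


def arc_distance(pt: PolarTrack) -> np.ndarray:
    """Arc-length displacement d_arc_i = R * (phi_i - phi_0), um (d_arc_0 = 0)."""
    return pt.geometry.radius * (pt.phi - pt.phi[0])


def polar_to_xy(pt: PolarTrack) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct Cartesian positions from a polar track (inverse of to_polar)."""
    cx, cy = pt.geometry.center
    return cx + pt.r * np.cos(pt.phi), cy + pt.r * np.sin(pt.phi)
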