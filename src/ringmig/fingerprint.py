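"""The five-parameter migratory fingerprint and its radar-chart rendering.

The fingerprint {v_run, tau_run, tau_rest, P_turn(8), P_turn(0)} is a
compact signature of a condition's migratory behavior: run speed, run and
rest persistence, the reversal probability at a standardized 8-um barrier,
and the spontaneous reversal probability.  Plotted on a radar chart with
v_run and tau_run on upward axes and tau_rest / turning probabilities on
downward axes, more motile conditions form polygons shifted toward the top.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["Fingerprint", "FingerprintError", "compute_fingerprint", "radar_chart", "AXES"]

AXES = ("v_run", "tau_run", "tau_rest", "p_turn_8", "p_turn_0")
#: axes on which a larger value means *more* motility (drawn upward)
UPWARD_AXES = frozenset({"v_run", "tau_run"})


class FingerprintError(ValueError):
    """Raised on missing or non-finite fingerprint parameters."""


@dataclass(frozen=True)
class Fingerprint:
    """Migratory signature of one condition.

    Velocities in um/h, times in hours, turning probabilities in [0, 1].
    ``partial`` marks fingerprints assembled without barrier data.
    """

    label: str
    v_run: float
    v_run_sem: float
    tau_run: float
    tau_run_ci99: tuple[float, float]
    tau_rest: float
    tau_rest_ci99: tuple[float, float]
    p_turn_8: float
    p_turn_8_ci95: tuple[float, float]
    p_turn_0: float
    p_turn_0_ci95: tuple[float, float]
    n_cells: int
    partial: bool = False

    def __post_init__(self) -> None:
        for name in ("p_turn_8", "p_turn_0"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise FingerprintError(f"{name} = {v} outside [0, 1]")
        if not self.partial:
            for name in AXES:
                if not np.isfinite(getattr(self, name)):
                    raise FingerprintError(f"non-finite parameter {name}")

    def values(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in AXES}

    def to_dict(self) -> dict:
        return asdict(self)


def compute_fingerprint(
    motility_params: dict, barrier_params: dict | None, label: str
) -> Fingerprint:
    """Assemble a fingerprint from motility and barrier parameter dicts.

    ``motility_params`` must carry v_run / tau_run / tau_rest (as produced
    by :func:`ringmig.motility.motility_parameters`); missing barrier data
    yields a fingerprint flagged ``partial``.  Assembly is deterministic.
    """
    for key in ("v_run", "tau_run", "tau_rest"):
        if key not in motility_params:
            raise FingerprintError(f"missing motility parameter {key}")
    barrier_params = barrier_params or {}
    partial = not {"p_turn_8", "p_turn_0"} <= set(barrier_params)
    nan_ci = (np.nan, np.nan)
    return Fingerprint(
        label=label,
        v_run=float(motility_params["v_run"]),
        v_run_sem=float(motility_params.get("v_run_sem", np.nan)),
        tau_run=float(motility_params["tau_run"]),
        tau_run_ci99=tuple(motility_params.get("tau_run_ci99", nan_ci)),
        tau_rest=float(motility_params["tau_rest"]),
        tau_rest_ci99=tuple(motility_params.get("tau_rest_ci99", nan_ci)),
        p_turn_8=float(barrier_params.get("p_turn_8", np.nan)),
        p_turn_8_ci95=tuple(barrier_params.get("p_turn_8_ci95", nan_ci)),
        p_turn_0=float(barrier_params.get("p_turn_0", np.nan)),
        p_turn_0_ci95=tuple(barrier_params.get("p_turn_0_ci95", nan_ci)),
        n_cells=int(motility_params.get("n_cells", 0)),
        partial=partial,
    )


def _axis_radius(name: str, value: float, axis_max: float) -> float:
    frac = value / axis_max if axis_max > 0 else 0.0
    return frac if name in UPWARD_AXES else 1.0 - frac


def radar_chart(
    fingerprints,
    path=None,
    axis_max: dict[str, float] | None = None,
):
    """Render fingerprints as radar-chart polygons; returns vertex data.

    Axis scaling is shared across all polygons (comparability contract):
    each axis maps [0, 1.25 x max observed] (overridable per axis via
    ``axis_max``) to radius.  Upward axes grow outward with the value;
    downward axes (tau_rest and the turning probabilities) shrink, so that
    more motile conditions form polygons shifted toward the top.

    When ``path`` is given an SVG is written there, plus a machine-readable
    JSON of vertex coordinates next to it (same stem, .json).
    """
    fps = list(fingerprints)
    if not fps:
        raise FingerprintError("need at least one fingerprint")
    for fp in fps:
        for name in AXES:
            if not np.isfinite(getattr(fp, name)):
                raise FingerprintError(
                    f"fingerprint {fp.label!r}: non-finite {name}"
                )
    maxima = {
        name: 1.25 * max(getattr(fp, name) for fp in fps) for name in AXES
    }
    if axis_max:
        maxima.update(axis_max)
    angles = np.pi / 2 - 2 * np.pi * np.arange(len(AXES)) / len(AXES)
    vertices: dict[str, dict] = {}
    for fp in fps:
        vertices[fp.label] = {
            name: {
                "value": float(getattr(fp, name)),
                "radius": _axis_radius(name, getattr(fp, name), maxima[name]),
                "angle": float(a),
            }
            for name, a in zip(AXES, angles)
        }

    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
        ax.set_theta_zero_location("N")
        ax.set_theta_direction(-1)
        theta = 2 * np.pi * np.arange(len(AXES)) / len(AXES)
        for fp in fps:
            radii = [vertices[fp.label][name]["radius"] for name in AXES]
            closed_t = np.concatenate([theta, theta[:1]])
            closed_r = np.concatenate([radii, radii[:1]])
            ax.plot(closed_t, closed_r, label=fp.label)
            ax.fill(closed_t, closed_r, alpha=0.15)
        ax.set_xticks(theta)
        ax.set_xticklabels(
            ["v_run", "tau_run", "tau_rest", "P_turn(8)", "P_turn(0)"]
        )
        ax.set_yticklabels([])
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right", bbox_to_anchor=(1.15, -0.1), fontsize=8)
        path = Path(path)
        fig.savefig(path, format=path.suffix.lstrip(".") or "svg")
        plt.close(fig)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(vertices, fh, indent=1)
    return vertices
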