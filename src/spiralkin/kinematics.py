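"""Derived kinematic series for a spiral trial.

Every feature consumes one of these per-trial series:

* ``dt``     — inter-sample time differences (s, length n-1);
* ``speed``  — drawing speed, chord length over dt (px/s, length n-1);
* ``r``      — distance of each sample from the origin (px, length n);
* ``phi``    — unwrapped four-quadrant polar angle (rad, length n);
* ``rv``     — radial velocity, d(r)/dt (px/s, length n-1; negative
  means the pen moves toward the spiral centre);
* ``av``     — angular velocity, d(phi)/dt (rad/s, length n-1).

Per-interval quantities are indexed to the left endpoint.  The default
origin is the first drawn sample; the template centre may be supplied
instead when it is known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from spiralkin.errors import DegenerateTrialError
from spiralkin.spiral_data import SpiralTrial

logger = logging.getLogger(__name__)

__all__ = ["KinematicSeries", "compute_kinematics", "polar_series"]


@dataclass(frozen=True)
class KinematicSeries:
    n: int
    origin: tuple[float, float]
    dt: np.ndarray
    speed: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    rv: np.ndarray
    av: np.ndarray


def polar_series(
    x: np.ndarray,
    y: np.ndarray,
    origin: tuple[float, float],
    warn: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius and unwrapped angle of the samples about ``origin``.

    A sample coincident with the origin has an undefined angle; it
    inherits the nearest defined angle (previous if any, else next) so
    that unwrapping never sees an artificial jump.
    """
    ox, oy = origin
    dx = x - ox
    dy = y - oy
    r = np.hypot(dx, dy)
    raw = np.arctan2(dy, dx)
    undefined = r == 0.0
    if undefined.any():
        if undefined.all():
            # every sample sits on the origin: angle is arbitrary
            return r, np.zeros_like(raw)
        if warn:
            logger.warning(
                "%d sample(s) coincide with the origin; using neighbouring angle",
                int(undefined.sum()),
            )
        defined_idx = np.flatnonzero(~undefined)
        # index of the previous defined sample, clipped so leading
        # undefined samples borrow the first defined angle
        pos = np.searchsorted(defined_idx, np.arange(x.size), side="right") - 1
        pos = np.clip(pos, 0, defined_idx.size - 1)
        raw = np.where(undefined, raw[defined_idx[pos]], raw)
    phi = np.unwrap(raw)
    return r, phi


def compute_kinematics(
    trial: SpiralTrial, origin="first_sample", warn: bool = True
) -> KinematicSeries:
    """Compute all derived series for one trial.

    Parameters
    ----------
    trial : the drawing.
    origin : ``"first_sample"`` or an explicit ``(x, y)`` point; the
        reference for radius, angle, radial and angular velocity.
    """
    if trial.n < 2:
        raise DegenerateTrialError("kinematics need >= 2 samples")
    first_sample_origin = origin == "first_sample"
    if first_sample_origin:
        o = (float(trial.x[0]), float(trial.y[0]))
    else:
        o = (float(origin[0]), float(origin[1]))
    dt = np.diff(trial.t)
    speed = np.hypot(np.diff(trial.x), np.diff(trial.y)) / dt
    r, phi = polar_series(trial.x, trial.y, o, warn=False)
    if warn:
        # the first sample trivially coincides with a first-sample origin
        coincident = np.flatnonzero(r == 0.0)
        unexpected = coincident[coincident > 0] if first_sample_origin else coincident
        if unexpected.size:
            logger.warning(
                "%d sample(s) coincide with the origin; angle carried over",
                unexpected.size,
            )
    rv = np.diff(r) / dt
    av = np.diff(phi) / dt
    return KinematicSeries(
        n=trial.n, origin=o, dt=dt, speed=speed, r=r, phi=phi, rv=rv, av=av
    )
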