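"""Polar least-squares spiral fits and the four fit-error features.

A drawn spiral is compared with the ideal Archimedean model
``r = a + b * phi`` in polar coordinates about a chosen origin.  The
root mean squared radial residual measures how far the drawing deviates
from its own best-fitting ideal spiral:

* ``Err``    — unconstrained fit (a free) about the first drawn point;
* ``Err0``   — fit constrained through the origin (a = 0), same origin;
* ``errBF``  — unconstrained fit after translating the drawing so that
  its *virtual optimal origin* Ou sits at (0, 0);
* ``err0BF`` — constrained fit after the same translation.

Ou is the translation that minimises the unconstrained fit error; it is
found by differential evolution over the drawing's (expanded) bounding
box.  Subjects often start the trace slightly off the template centre:
the translated errors discount that start offset while the untranslated
ones include it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from spiralkin.config import DEParams, FeatureConfig
from spiralkin.errors import DegenerateTrialError, FitError
from spiralkin.kinematics import polar_series
from spiralkin.spiral_data import SpiralTrial

logger = logging.getLogger(__name__)

__all__ = [
    "SpiralFitResult",
    "fit_ideal_spiral",
    "optimal_origin_search",
    "spiral_error_features",
]


@dataclass(frozen=True)
class SpiralFitResult:
    """Ideal-spiral fit: ``r = a + b*phi`` with RMS radial residual."""

    a: float
    b: float
    rmse: float
    constrained: bool
    origin: tuple[float, float] | None = None
    converged: bool = True


def fit_ideal_spiral(
    r: np.ndarray, phi: np.ndarray, constrain_origin: bool = False
) -> SpiralFitResult:
    """Least-squares Archimedean fit in polar space.

    Unconstrained: ``(a, b)`` minimise ``sum((r - a - b*phi)**2)``
    (normal equations).  Constrained: ``a = 0`` and
    ``b = sum(phi*r) / sum(phi**2)``.
    """
    r = np.asarray(r, float)
    phi = np.asarray(phi, float)
    if r.size < 2:
        raise DegenerateTrialError("spiral fit needs >= 2 samples")
    if np.ptp(phi) == 0.0:
        raise FitError("all angles identical; spiral fit undefined")
    if constrain_origin:
        denom = float(phi @ phi)
        if denom == 0.0:
            raise FitError("constrained fit undefined: all angles zero")
        a = 0.0
        b = float(phi @ r) / denom
    else:
        A = np.column_stack([np.ones_like(phi), phi])
        (a, b), *_ = np.linalg.lstsq(A, r, rcond=None)
        a, b = float(a), float(b)
    resid = r - a - b * phi
    rmse = float(np.sqrt(np.mean(resid**2)))
    return SpiralFitResult(a=a, b=b, rmse=rmse, constrained=constrain_origin)


def _polar_about(x: np.ndarray, y: np.ndarray, origin):
    """Polar series for fitting: samples on the origin itself have no
    defined angle and are excluded from the fit."""
    r, phi = polar_series(x, y, origin, warn=False)
    keep = r > 0.0
    return r[keep], phi[keep]


def _rmse_about(x: np.ndarray, y: np.ndarray, origin, constrained: bool = False) -> float:
    r, phi = _polar_about(x, y, origin)
    if r.size < 2 or np.ptp(phi) == 0.0:
        return float("inf")
    return fit_ideal_spiral(r, phi, constrain_origin=constrained).rmse


def _search_bounds(trial: SpiralTrial, pad_frac: float = 0.25):
    xmin, xmax = float(trial.x.min()), float(trial.x.max())
    ymin, ymax = float(trial.y.min()), float(trial.y.max())
    px = max(1.0, pad_frac * (xmax - xmin))
    py = max(1.0, pad_frac * (ymax - ymin))
    return [(xmin - px, xmax + px), (ymin - py, ymax + py)]


def optimal_origin_search(
    trial: SpiralTrial,
    de_params: DEParams = DEParams(),
    seed: int | None = None,
    constrain_origin: bool = False,
) -> SpiralFitResult:
    """Find the virtual optimal origin Ou by differential evolution.

    The objective is the polar-fit RMSE (unconstrained, or with the
    ideal spiral forced through the candidate origin when
    ``constrain_origin``) after recomputing radius and (re-unwrapped)
    angle about each candidate origin; the search box is the drawing's
    bounding box expanded by 25% per side.  Deterministic given the
    seed.  The first-sample origin is always evaluated as well, so the
    returned fit is never worse than the default-origin fit.
    """
    if trial.n < 10:
        raise DegenerateTrialError("origin search needs >= 10 samples")
    if seed is None:
        seed = de_params.seed
    x, y = trial.x, trial.y

    def objective(p):
        return _rmse_about(x, y, (p[0], p[1]), constrained=constrain_origin)

    bounds = _search_bounds(trial)
    result = differential_evolution(
        objective,
        bounds,
        popsize=de_params.popsize,
        mutation=de_params.mutation,
        recombination=de_params.recombination,
        maxiter=de_params.maxiter,
        tol=de_params.tol,
        seed=seed,
        polish=True,
    )
    if not result.success:
        logger.warning("origin search did not converge: %s", result.message)
    ou = (float(result.x[0]), float(result.x[1]))
    best = float(result.fun)
    # the default origin is a legal candidate; keep it if DE did worse
    first = (float(x[0]), float(y[0]))
    first_rmse = _rmse_about(x, y, first, constrained=constrain_origin)
    if first_rmse < best:
        ou, best = first, first_rmse
    r, phi = _polar_about(x, y, ou)
    fit = fit_ideal_spiral(r, phi, constrain_origin=constrain_origin)
    return SpiralFitResult(
        a=fit.a,
        b=fit.b,
        rmse=best,
        constrained=constrain_origin,
        origin=ou,
        converged=bool(result.success),
    )


def spiral_error_features(
    trial: SpiralTrial,
    seed: int | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """The four spiral-fit error features of one trial.

    ``Err``/``Err0`` use the first drawn point as origin;
    ``errBF``/``err0BF`` each translate the drawing to its own virtual
    optimal origin before refitting (unconstrained and constrained
    objective respectively), so neither can exceed its untranslated
    counterpart.
    """
    if config.origin == "first_sample":
        base = (float(trial.x[0]), float(trial.y[0]))
    else:
        base = (float(config.origin[0]), float(config.origin[1]))
    r, phi = _polar_about(trial.x, trial.y, base)
    err = fit_ideal_spiral(r, phi, constrain_origin=False).rmse
    err0 = fit_ideal_spiral(r, phi, constrain_origin=True).rmse
    best = optimal_origin_search(trial, de_params=config.de, seed=seed)
    best0 = optimal_origin_search(
        trial, de_params=config.de, seed=seed, constrain_origin=True
    )
    return {"Err": err, "Err0": err0, "errBF": best.rmse, "err0BF": best0.rmse}
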