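"""Spatiotemporal features of spiral drawings.

The feature set targets the drawing signatures that separate
bradykinesia (slow, hesitant tracing with festination after arrests)
from choreatic dyskinesia (fast tracing with high-frequency spatial
irregularity):

* speed moments — mean, coefficient of variation and skewness of the
  drawing speed, plus the mean inter-sample interval (``Dt.mean``);
* wavelet band statistics — a 1-level discrete wavelet transform
  (Daubechies 10) splits each series at half the Nyquist rate, so at
  10 Hz sampling the detail coefficients carry the 2.5–5 Hz band where
  dyskinetic irregularity lives;
* approximate entropy (``ApEn``) of radial velocity and speed — a
  regularity statistic; complex, multi-component series score high;
* peak statistics — mean/sd of the absolute differences between
  neighbouring local extremes of a series (``avgP``/``stdP``), the
  extreme count normalised by series length (``nPeaks``), and the rank
  correlation of windowed extreme variability with time (``incDev``);
* ``Rv.pn005`` — the percentage of drawn path length over which the pen
  moves toward the spiral centre (radial velocity below a small
  negative threshold);
* ``TOTSYMM`` — total horizontal plus vertical extent asymmetry of the
  drawing about its origin;
* ``Err``/``Err0``/``errBF``/``err0BF`` — polar-space spiral-fit errors
  (see :mod:`spiralkin.spiral_fit`).

All features are returned under their canonical names (see
:data:`FEATURE_NAMES`); a feature whose preconditions fail is emitted
as ``nan`` and downstream analysis excludes incomplete trials.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from spiralkin.config import FeatureConfig
from spiralkin.errors import DegenerateTrialError
from spiralkin.kinematics import compute_kinematics
from spiralkin.spiral_data import SpiralTrial
from spiralkin import spiral_fit

logger = logging.getLogger(__name__)

#: Canonical feature order, used for CSV headers and PCA input.
FEATURE_NAMES = [
    "Sp.mean",
    "Sp.cv",
    "Sp.skew",
    "Dt.mean",
    "Rv.hf.cv",
    "Ds.hf.min",
    "Ds.hf.max",
    "Rv.apen",
    "Ds.apen",
    "R.avgP",
    "R.stdP",
    "R.nPeaks",
    "R.incDev",
    "Ads.avgP",
    "Ads.stdP",
    "Ads.nPeaks",
    "Rv.avgP",
    "Rv.stdP",
    "Rv.nPeaks",
    "Rv.pn005",
    "Av.avgP",
    "Av.stdP",
    "Av.nPeaks",
    "Angle.incDev",
    "TOTSYMM",
    "Err",
    "Err0",
    "errBF",
    "err0BF",
]

__all__ = [
    "FEATURE_NAMES",
    "ExtremeSet",
    "moment_features",
    "wavelet_band_features",
    "approximate_entropy",
    "find_extremes",
    "peak_features",
    "inc_dev",
    "inward_fraction",
    "total_asymmetry",
    "extract_feature_vector",
]


# ---------------------------------------------------------------- moments


def moment_features(speed: np.ndarray, dt: np.ndarray) -> dict[str, float]:
    """First three moments of drawing speed plus the mean time step.

    ``Sp.cv`` is sd/mean (nan when the mean speed is zero); ``Sp.skew``
    is the third central moment over the cubed standard deviation and
    is 0 for a zero-spread series.  Sample (n-1) standard deviations
    throughout.
    """
    speed = np.asarray(speed, float)
    dt = np.asarray(dt, float)
    if speed.size < 3:
        raise DegenerateTrialError("speed moments need >= 3 intervals")
    mean = float(speed.mean())
    sd = float(speed.std(ddof=1))
    cv = sd / abs(mean) if mean != 0.0 else math.nan
    if sd == 0.0:
        skew = 0.0
    else:
        m3 = float(np.mean((speed - mean) ** 3))
        skew = m3 / sd**3
    return {
        "Sp.mean": mean,
        "Sp.cv": cv,
        "Sp.skew": skew,
        "Dt.mean": float(dt.mean()),
    }


# ---------------------------------------------------------------- wavelets


def dwt_detail(series: np.ndarray, wavelet: str = "db10", mode: str = "symmetric") -> np.ndarray:
    """High-frequency (detail) coefficients of a 1-level DWT."""
    _, cd = pywt.dwt(np.asarray(series, float), wavelet, mode=mode)
    return cd


def wavelet_band_features(
    rv: np.ndarray,
    speed: np.ndarray,
    config: FeatureConfig = FeatureConfig(),
) -> dict[str, float]:
    """Band statistics from 1-level DWT detail coefficients.

    ``Rv.hf.cv`` is the coefficient of variation of the radial-velocity
    detail coefficients (heavy-tailed by construction: detail
    coefficients have near-zero mean).  ``Ds.hf.min``/``Ds.hf.max`` are
    the extreme detail coefficients of the speed series.
    """
    out = {"Rv.hf.cv": math.nan, "Ds.hf.min": math.nan, "Ds.hf.max": math.nan}
    rv = np.asarray(rv, float)
    speed = np.asarray(speed, float)
    if rv.size < config.min_wavelet_len or speed.size < config.min_wavelet_len:
        logger.info(
            "series too short for %s wavelet features (%d < %d)",
            config.wavelet,
            min(rv.size, speed.size),
            config.min_wavelet_len,
        )
        return out
    cd_rv = dwt_detail(rv, config.wavelet, config.wavelet_mode)
    cd_sp = dwt_detail(speed, config.wavelet, config.wavelet_mode)
    mean = float(cd_rv.mean())
    sd = float(cd_rv.std(ddof=1))
    out["Rv.hf.cv"] = sd / abs(mean) if mean != 0.0 else math.nan
    out["Ds.hf.min"] = float(cd_sp.min())
    out["Ds.hf.max"] = float(cd_sp.max())
    return out


# ------------------------------------------------------------------ ApEn


def approximate_entropy(series: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy (Pincus) with Chebyshev distance.

    Tolerance ``r = r_frac * sd(series)``; template self-matches are
    included, so the statistic is always finite.  A constant series
    (sd = 0) is maximally regular and returns 0.
    """
    u = np.asarray(series, float)
    n = u.size
    if n < m + 2:
        raise DegenerateTrialError(f"ApEn needs >= {m + 2} points, got {n}")
    sd = float(u.std(ddof=1))
    if sd == 0.0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        nwin = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(u, mm)  # (nwin, mm)
        # Chebyshev distances between all window pairs
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        c = (d <= r).sum(axis=1) / nwin
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


# -------------------------------------------------------------- extremes


@dataclass(frozen=True)
class ExtremeSet:
    """Local extremes of a series, endpoints always included.

    ``delta_peaks`` holds the absolute differences between the values
    at consecutive extremes.
    """

    indices: np.ndarray
    values: np.ndarray

    @property
    def delta_peaks(self) -> np.ndarray:
        return np.abs(np.diff(self.values))


def find_extremes(series: np.ndarray) -> ExtremeSet:
    """Local minima/maxima of a series plus its first and last points.

    Runs of equal consecutive values collapse to their first element,
    after which an interior point is an extreme iff the differences to
    its neighbours have opposite signs.
    """
    v = np.asarray(series, float)
    n = v.size
    if n < 2:
        raise DegenerateTrialError("extreme detection needs >= 2 points")
    keep = np.concatenate([[True], np.diff(v) != 0.0])
    cidx = np.flatnonzero(keep)  # original indices of collapsed series
    cv = v[cidx]
    ext: list[int] = [0]
    if cv.size >= 3:
        d = np.diff(cv)
        turning = np.flatnonzero(d[:-1] * d[1:] < 0.0) + 1
        ext.extend(int(cidx[i]) for i in turning)
    if ext[-1] != n - 1:
        ext.append(n - 1)
    idx = np.array(sorted(set(ext)), dtype=int)
    return ExtremeSet(indices=idx, values=v[idx])


def peak_features(series: np.ndarray) -> dict[str, float]:
    """Mean/sd of the extreme-to-extreme jumps and normalised count.

    ``nPeaks`` divides the number of extremes (endpoints included) by
    the series length, so it lies in (0, 1].
    """
    ext = find_extremes(series)
    dp = ext.delta_peaks
    n = np.asarray(series).size
    return {
        "avgP": float(dp.mean()),
        "stdP": float(dp.std(ddof=1)) if dp.size > 1 else 0.0,
        "nPeaks": ext.indices.size / n,
    }


def inc_dev(series: np.ndarray, n_windows: int = 30) -> float:
    """Drift of irregularity: rank correlation of windowed sd with time.

    The extreme-to-extreme jumps (delta-peaks) of the series are swept
    by ``n_windows`` overlapping windows of length
    ``max(2, len(dp) // 3)`` whose starts are spaced as evenly as
    possible; the statistic is the Spearman correlation between window
    position and window standard deviation.  Positive values mean the
    drawing grows more erratic over the trial.  A series with fewer
    than 4 delta-peaks (e.g. a monotone radius or angle) carries no
    measurable variability trend and scores 0.
    """
    dp = find_extremes(series).delta_peaks
    if dp.size < 4:
        return 0.0
    w = max(2, dp.size // 3)
    max_start = dp.size - w
    starts = np.unique(np.round(np.linspace(0, max_start, n_windows)).astype(int))
    sds = np.array([dp[s : s + w].std(ddof=1) for s in starts])
    if np.unique(sds).size < 2:
        return 0.0
    rho = stats.spearmanr(starts, sds).statistic
    return float(rho) if np.isfinite(rho) else 0.0


# ------------------------------------------------------- path-level feats


def inward_fraction(
    rv: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    threshold: float = -0.05,
) -> float:
    """Percentage of drawn path length spent moving toward the centre.

    Each inter-sample segment is weighted by its Euclidean length; a
    segment counts as inward when its radial velocity is below
    ``threshold`` (px/s, slightly negative to absorb noise).  An ideal
    outward trace scores 0; the same trace drawn in reverse scores 100.
    """
    seg = np.hypot(np.diff(np.asarray(x, float)), np.diff(np.asarray(y, float)))
    total = float(seg.sum())
    if total == 0.0:
        return 0.0
    inward = float(seg[np.asarray(rv, float) < threshold].sum())
    return 100.0 * inward / total


def total_asymmetry(
    x: np.ndarray, y: np.ndarray, origin: tuple[float, float]
) -> float:
    """Total extent asymmetry of the drawing about the origin.

    Horizontal asymmetry is |d_left - d_right| / (d_left + d_right)
    where d_left/d_right are the distances of the leftmost/rightmost
    points from the vertical axis through the origin; vertical is
    analogous.  A side with no points contributes its full asymmetry of
    1; a drawing collapsed onto the origin contributes 0.
    """
    ox, oy = origin

    def axis_asym(coord: np.ndarray, o: float) -> float:
        lo = max(0.0, o - float(np.min(coord)))
        hi = max(0.0, float(np.max(coord)) - o)
        s = lo + hi
        if s == 0.0:
            return 0.0
        return abs(lo - hi) / s

    return axis_asym(np.asarray(x, float), ox) + axis_asym(np.asarray(y, float), oy)


# ------------------------------------------------------------ orchestration


def extract_feature_vector(
    trial: SpiralTrial, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """All named features for one trial, keyed by canonical name.

    Deterministic given the trial and config (the differential-
    evolution seed is part of the config).  Features whose
    preconditions fail are nan.
    """
    k = compute_kinematics(trial, origin=config.origin)
    out: dict[str, float] = {name: math.nan for name in FEATURE_NAMES}

    if k.speed.size >= 3:
        out.update(moment_features(k.speed, k.dt))
    out.update(wavelet_band_features(k.rv, k.speed, config))

    m, rf = config.apen_m, config.apen_r_frac
    if k.rv.size >= m + 2:
        out["Rv.apen"] = approximate_entropy(k.rv, m, rf)
    if k.speed.size >= m + 2:
        out["Ds.apen"] = approximate_entropy(k.speed, m, rf)

    ads = np.abs(k.speed)
    for prefix, series in (("R", k.r), ("Ads", ads), ("Rv", k.rv), ("Av", k.av)):
        if series.size >= 2:
            pf = peak_features(series)
            out[f"{prefix}.avgP"] = pf["avgP"]
            out[f"{prefix}.stdP"] = pf["stdP"]
            out[f"{prefix}.nPeaks"] = pf["nPeaks"]
    out["R.incDev"] = inc_dev(k.r, config.incdev_windows)
    out["Angle.incDev"] = inc_dev(k.phi, config.incdev_windows)

    out["Rv.pn005"] = inward_fraction(
        k.rv, trial.x, trial.y, config.rv_inward_threshold
    )
    out["TOTSYMM"] = total_asymmetry(trial.x, trial.y, k.origin)

    if trial.n >= 10:
        out.update(spiral_fit.spiral_error_features(trial, config=config))

    return out


def feature_table(trials, config: FeatureConfig = FeatureConfig()):
    """Feature vectors for many trials as a pandas DataFrame.

    Identifier columns (subject, occasion, trial index, group, label,
    mean impairment) precede the feature columns.
    """
    import pandas as pd

    rows = []
    for trial in trials:
        row = {
            "subject_id": trial.subject_id,
            "occasion_id": trial.occasion_id,
            "trial_index": trial.trial_index,
            "group": trial.group,
            "label": trial.label,
            "mean_impairment": trial.mean_impairment,
        }
        row.update(extract_feature_vector(trial, config))
        rows.append(row)
    return pd.DataFrame(rows)
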