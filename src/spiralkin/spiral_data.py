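"""Data model and I/O for spiral-tracing trials.

A trial is one spiral drawing: an ordered sequence of pen samples
``(x px, y px, t)`` recorded by a touch-screen device at a nominal
10 Hz.  Timestamps are stored in milliseconds on disk (device
convention) and converted to seconds in memory, where all kinematic
formulas expect them.

Two on-disk dialects are supported:

* CSV with header ``x,y,t_ms``, one sample per row;
* JSON with a metadata block and a ``samples`` array of
  ``{"x": …, "y": …, "t_ms": …}`` objects.

Pen lifts are not encoded by the device format; a trial is a single
continuous stroke and pauses appear only as large inter-sample time
differences.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from spiralkin.errors import DegenerateTrialError, TrialParseError

logger = logging.getLogger(__name__)

__all__ = [
    "SpiralTrial",
    "SpiralTemplate",
    "archimedes_template",
    "read_trial",
    "write_trial",
]


@dataclass(frozen=True)
class SpiralTrial:
    """One spiral drawing with its acquisition metadata.

    Coordinates are screen pixels (y increases downward); ``t`` is in
    seconds and strictly increasing.  ``mean_impairment`` is externally
    supplied metadata (an overall 0–10 impairment score for the test
    occasion) used only to filter cases for classification.
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    subject_id: str = ""
    occasion_id: str = ""
    trial_index: int = 1
    group: str = "PD"
    nominal_rate: float = 10.0
    mean_impairment: float | None = None
    label: str | None = None

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)
        if not (x.shape == y.shape == t.shape) or x.ndim != 1:
            raise ValueError("x, y, t must be 1-D arrays of equal length")
        if x.size < 2:
            raise DegenerateTrialError(
                f"trial needs >= 2 samples, got {x.size}"
            )
        if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(t).all()):
            raise ValueError("trial contains non-finite coordinates or timestamps")
        if not (np.diff(t) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def with_samples(self, x, y, t) -> "SpiralTrial":
        return replace(self, x=np.asarray(x, float), y=np.asarray(y, float), t=np.asarray(t, float))


@dataclass(frozen=True)
class SpiralTemplate:
    """The pre-drawn Archimedean spiral shown on screen.

    Radius grows linearly with the polar angle: ``r(phi) = pitch * phi``
    with ``phi`` in [0, 2*pi*turns].
    """

    center: tuple[float, float]
    pitch: float
    turns: float
    phi: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return self.pitch * self.phi

    @property
    def max_radius(self) -> float:
        return self.pitch * 2.0 * math.pi * self.turns


def archimedes_template(
    center: tuple[float, float] = (0.0, 0.0),
    pitch: float = 10.0,
    turns: float = 3.0,
    n_points: int = 400,
) -> SpiralTemplate:
    """Sample an ideal Archimedean spiral at equal angle increments.

    Parameters
    ----------
    center : reference point (px).
    pitch : radius growth per radian (px/rad), > 0.
    turns : number of revolutions, > 0.
    n_points : number of sampled points (>= 2) over [0, 2*pi*turns].
    """
    if pitch <= 0:
        raise ValueError(f"pitch must be positive, got {pitch}")
    if turns <= 0:
        raise ValueError(f"turns must be positive, got {turns}")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    phi = np.linspace(0.0, 2.0 * math.pi * turns, int(n_points))
    r = pitch * phi
    cx, cy = center
    return SpiralTemplate(
        center=(float(cx), float(cy)),
        pitch=float(pitch),
        turns=float(turns),
        phi=phi,
        x=cx + r * np.cos(phi),
        y=cy + r * np.sin(phi),
    )


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer dialect from {path.name!r}; pass dialect=")


def _finalize_samples(
    xs: Sequence[float], ys: Sequence[float], ts_ms: Sequence[float], origin: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort by time, collapse duplicate timestamps, convert ms -> s."""
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    t = np.asarray(ts_ms, float) / 1000.0
    order = np.argsort(t, kind="stable")
    x, y, t = x[order], y[order], t[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    dropped = int((~keep).sum())
    if dropped:
        # zero dt would make every per-interval quantity undefined
        logger.warning("%s: dropped %d duplicate-timestamp sample(s)", origin, dropped)
        x, y, t = x[keep], y[keep], t[keep]
    if t.size < 2:
        raise DegenerateTrialError(f"{origin}: fewer than 2 usable samples")
    return x, y, t


def read_trial(path, dialect: str | None = None) -> SpiralTrial:
    """Read one trial from a CSV or JSON file.

    Timestamps are converted from device milliseconds to seconds;
    samples are sorted by time and duplicate timestamps collapsed
    (first sample kept).
    """
    path = Path(path)
    kind = _dialect_for(path, dialect)
    if kind == "csv":
        return _read_csv(path)
    return _read_json(path)


def _read_csv(path: Path) -> SpiralTrial:
    xs, ys, ts = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise TrialParseError(f"{path}: empty file")
        cols = [c.strip().lower() for c in header]
        try:
            ix, iy, it = cols.index("x"), cols.index("y"), cols.index("t_ms")
        except ValueError:
            raise TrialParseError(
                f"{path}: line 1: expected header with columns x,y,t_ms, got {header!r}"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                xs.append(float(row[ix]))
                ys.append(float(row[iy]))
                ts.append(float(row[it]))
            except (ValueError, IndexError) as exc:
                raise TrialParseError(f"{path}: line {lineno}: malformed row {row!r}") from exc
    x, y, t = _finalize_samples(xs, ys, ts, str(path))
    return SpiralTrial(x=x, y=y, t=t)


def _read_json(path: Path) -> SpiralTrial:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TrialParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    samples = doc.get("samples")
    if not isinstance(samples, list):
        raise TrialParseError(f"{path}: missing 'samples' array")
    xs, ys, ts = [], [], []
    for i, s in enumerate(samples):
        try:
            xs.append(float(s["x"]))
            ys.append(float(s["y"]))
            ts.append(float(s["t_ms"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise TrialParseError(f"{path}: sample {i}: malformed entry {s!r}") from exc
    x, y, t = _finalize_samples(xs, ys, ts, str(path))
    mi = doc.get("mean_impairment")
    return SpiralTrial(
        x=x,
        y=y,
        t=t,
        subject_id=str(doc.get("subject_id", "")),
        occasion_id=str(doc.get("occasion_id", "")),
        trial_index=int(doc.get("trial_index", 1)),
        group=str(doc.get("group", "PD")),
        nominal_rate=float(doc.get("nominal_rate", 10.0)),
        mean_impairment=None if mi is None else float(mi),
        label=doc.get("label"),
    )


def write_trial(trial: SpiralTrial, path, dialect: str | None = None) -> None:
    """Write a trial; ``read_trial`` recovers the samples to 6 decimals.

    The JSON dialect preserves metadata; CSV stores samples only.
    """
    path = Path(path)
    kind = _dialect_for(path, dialect)
    t_ms = trial.t * 1000.0
    if kind == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "t_ms"])
            for xi, yi, ti in zip(trial.x, trial.y, t_ms):
                writer.writerow([repr(float(xi)), repr(float(yi)), repr(float(ti))])
        return
    doc = {
        "subject_id": trial.subject_id,
        "occasion_id": trial.occasion_id,
        "trial_index": trial.trial_index,
        "group": trial.group,
        "nominal_rate": trial.nominal_rate,
        "mean_impairment": trial.mean_impairment,
        "label": trial.label,
        "samples": [
            {"x": float(xi), "y": float(yi), "t_ms": float(ti)}
            for xi, yi, ti in zip(trial.x, trial.y, t_ms)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
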