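"""Run configuration: every tunable of the feature pipeline in one place.

A :class:`FeatureConfig` fully determines feature extraction for a given
trial (the differential-evolution seed included), so repeated runs with
the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class DEParams:
    """Differential-evolution settings for the optimal-origin search.

    A two-parameter search over candidate origins; the defaults are
    deliberately generous so the search converges robustly on every
    trial shape the simulator produces.
    """

    popsize: int = 20
    mutation: float = 0.8
    recombination: float = 0.9
    maxiter: int = 100
    tol: float = 0.01
    seed: int = 17


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the spatiotemporal feature extraction.

    Attributes
    ----------
    origin:
        Reference point for radius/angle series: ``"first_sample"``
        (default — the origin is placed on the first drawn point) or an
        explicit ``(x, y)`` pair such as the template centre.
    apen_m, apen_r_frac:
        Approximate-entropy window length and similarity tolerance as a
        fraction of the series standard deviation.
    wavelet, wavelet_mode:
        Mother wavelet and boundary extension for the 1-level DWT. With
        10 Hz sampling the detail band covers 2.5–5 Hz.
    min_wavelet_len:
        Minimum series length for wavelet features (db10 filter support).
    incdev_windows:
        Number of overlapping windows for the drift-in-irregularity
        (incDev) statistic.
    rv_inward_threshold:
        Radial velocity (px/s) below which the pen is counted as moving
        toward the centre; slightly below zero to absorb measurement
        noise.
    max_duration:
        Longest admissible trial (s); the drawing protocol targets 10 s.
    """

    origin: object = "first_sample"
    apen_m: int = 2
    apen_r_frac: float = 0.2
    wavelet: str = "db10"
    wavelet_mode: str = "symmetric"
    min_wavelet_len: int = 21
    incdev_windows: int = 30
    rv_inward_threshold: float = -0.05
    max_duration: float = 15.0
    de: DEParams = field(default_factory=DEParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["origin"], tuple):
            d["origin"] = list(d["origin"])
        return d

    def config_hash(self) -> str:
        """Short stable hash used to tag run logs and outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        de = d.pop("de", None)
        if isinstance(d.get("origin"), list):
            d["origin"] = tuple(d["origin"])
        cfg = cls(**d, de=DEParams(**de) if de else DEParams())
        return cfg
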