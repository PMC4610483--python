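"""Synthetic spiral-tracing trials with known motor-state labels.

The simulator emulates the acquisition protocol — a pre-drawn
Archimedean spiral traced from the centre outward on a touch screen
sampled at 10 Hz for about 10 s (~100 samples per trial) — and the
drawing signatures of the motor states it stands in for:

* **healthy** — steady outward tracing with mild multiplicative speed
  noise and sub-pixel positional jitter;
* **bradykinetic** — globally slowed tracing with Poisson-placed
  drawing arrests, each followed by a brief festinating burst;
* **dyskinetic** — fast tracing with a band-limited (2.5–5 Hz) radial
  perturbation, placed by construction in the band that the 1-level
  DWT detail coefficients measure;
* **tremor** — a sinusoidal radial oscillation below the 5 Hz Nyquist
  limit of the device.

Each state also carries an ``asymmetry_bias`` that skews the drawing's
horizontal extent, mirroring the lateralised distortion seen in
impaired tracings.  Trials are deterministic given their seed; cohorts
are deterministic given the base seed.

The simulator targets the statistical signatures that the features
measure, not limb biomechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from spiralkin.spiral_data import SpiralTrial

__all__ = ["SimProfile", "PRESETS", "simulate_trial", "simulate_cohort"]


@dataclass(frozen=True)
class SimProfile:
    """Generative parameters for one simulated drawing condition.

    ``base_angular_rate`` (rad/s) and ``pitch`` (px/rad) describe the
    nominal trace — defaults give ~3 turns of a 190 px spiral in 10 s.
    The pen advances along the spiral at roughly constant *linear*
    speed (as real tracing does): ``speed_scale`` multiplies the
    nominal mean linear speed (<1 slows the whole trace, >1 speeds it
    up).  ``hesitation_rate`` is the expected number of drawing arrests
    per trial; each lasts ``hesitation_duration`` seconds and is
    followed by a festinating burst.  ``hf_irregularity_amp`` (px, sd)
    drives an isotropic band-limited (2.5–5 Hz) positional
    perturbation; ``tremor_freq``/``tremor_amp`` add a rhythmic radial
    oscillation; ``jitter_sd`` is white positional noise;
    ``asymmetry_bias`` drifts the drawing centre rightward in
    proportion to the radius, skewing the horizontal extent.
    """

    label: str = "healthy"
    base_angular_rate: float = 2.0 * math.pi * 3.0 / 10.0
    pitch: float = 10.0
    speed_scale: float = 1.0
    speed_noise_sd: float = 0.15
    hesitation_rate: float = 0.0
    hesitation_duration: float = 0.8
    festination_boost: float = 1.8
    hf_irregularity_amp: float = 0.0
    tremor_freq: float = 4.0
    tremor_amp: float = 0.0
    asymmetry_bias: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "pitch",
            "speed_scale",
            "speed_noise_sd",
            "hesitation_rate",
            "hesitation_duration",
            "hf_irregularity_amp",
            "tremor_amp",
            "jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.base_angular_rate <= 0:
            raise ValueError("base_angular_rate must be positive")
        if self.tremor_amp > 0 and not (0 < self.tremor_freq < 5.0):
            raise ValueError("tremor_freq must lie below the 5 Hz Nyquist limit")


#: Default condition presets.  Magnitudes are calibrated so that the
#: bradykinetic and dyskinetic presets reproduce the characteristic
#: separations in mean drawing speed (tens vs hundreds of px/s),
#: detail-band variability, speed entropy and asymmetry seen in rated
#: patient drawings.
PRESETS: dict[str, SimProfile] = {
    "healthy": SimProfile(
        label="healthy",
        speed_scale=1.0,
        speed_noise_sd=0.1,
        hf_irregularity_amp=0.5,
        asymmetry_bias=0.02,
        jitter_sd=0.3,
    ),
    # bradykinesia: slow, small (micrographic), smooth trace with
    # arrests and a laterally skewed extent
    "bradykinetic": SimProfile(
        label="bradykinetic",
        pitch=4.5,
        speed_scale=0.75,
        speed_noise_sd=0.02,
        hesitation_rate=3.0,
        hesitation_duration=0.8,
        hf_irregularity_amp=0.05,
        asymmetry_bias=0.3,
        jitter_sd=0.05,
    ),
    # dyskinesia: fast trace with choreatic pace fluctuation and a
    # strong 2.5-5 Hz positional perturbation
    "dyskinetic": SimProfile(
        label="dyskinetic",
        speed_scale=1.55,
        speed_noise_sd=0.25,
        hf_irregularity_amp=2.8,
        asymmetry_bias=0.02,
        jitter_sd=0.3,
    ),
    "tremor": SimProfile(
        label="tremor",
        pitch=8.0,
        speed_scale=0.6,
        tremor_freq=4.0,
        tremor_amp=3.0,
        hf_irregularity_amp=0.4,
        asymmetry_bias=0.1,
        jitter_sd=0.3,
    ),
}


def _bandlimited_noise(n: int, rate: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-sd white noise restricted to the [lo, hi] Hz band."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    band = np.fft.irfft(spec, n)
    sd = band.std()
    return band / sd if sd > 0 else band


def simulate_trial(
    profile: SimProfile,
    duration: float = 10.0,
    rate: float = 10.0,
    seed: int | None = None,
    center: tuple[float, float] = (0.0, 0.0),
    **metadata,
) -> SpiralTrial:
    """Generate one labelled spiral trial.

    With every noise and perturbation parameter at zero the output is
    an exact Archimedean trace starting at the centre.  Deterministic
    given the seed (``profile.seed`` unless overridden).
    """
    n = int(round(duration * rate))
    if n < 21:
        raise ValueError("duration * rate must give at least 21 samples")
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    dt = 1.0 / rate
    t = np.arange(n) * dt

    # nominal mean linear speed of a constant-angular-rate trace of the
    # same duration: v = mean(r * omega) = pitch * omega^2 * T / 2
    v_nom = profile.pitch * profile.base_angular_rate**2 * duration / 2.0

    # per-interval linear speed; the multiplicative speed noise is
    # slowly varying (voluntary pace drifts below ~0.8 Hz) so that a
    # bradykinetic trace stays regular while dyskinetic irregularity
    # enters through the high-frequency positional perturbation
    if profile.speed_noise_sd > 0:
        slow = _bandlimited_noise(n - 1, rate, 0.0, 0.8, rng)
        mult = np.exp(profile.speed_noise_sd * slow)
    else:
        mult = np.ones(n - 1)

    # arrests: near-zero speed followed by a festinating burst; a
    # hesitating condition always arrests at least once per trial
    factor = np.ones(n - 1)
    n_arrests = rng.poisson(profile.hesitation_rate)
    if profile.hesitation_rate > 0:
        n_arrests = max(1, n_arrests)
    arrest_len = max(1, int(round(profile.hesitation_duration * rate)))
    burst_len = max(1, int(round(0.5 * rate)))
    for start in sorted(rng.integers(0, n - 1, size=n_arrests)):
        stop = min(start + arrest_len, n - 1)
        factor[start:stop] = 0.05
        bstop = min(stop + burst_len, n - 1)
        factor[stop:bstop] = profile.festination_boost

    v = v_nom * profile.speed_scale * mult * factor
    s = np.concatenate([[0.0], np.cumsum(v * dt)])  # arc length
    # r = pitch*phi and ds ~ r dphi give s = pitch*phi^2/2
    phi = np.sqrt(2.0 * s / profile.pitch)
    r = profile.pitch * phi
    if profile.tremor_amp > 0:
        phase = rng.uniform(0, 2 * math.pi)
        r = r + profile.tremor_amp * np.sin(2 * math.pi * profile.tremor_freq * t + phase)

    cx, cy = center
    # lateral asymmetry: the drawing centre drifts rightward in
    # proportion to the radius, skewing the horizontal extents while
    # adding only a slow, low-amplitude velocity component
    x = cx + r * np.cos(phi) + profile.asymmetry_bias * r
    y = cy + r * np.sin(phi)
    if profile.hf_irregularity_amp > 0:
        x = x + profile.hf_irregularity_amp * _bandlimited_noise(n, rate, 2.5, 5.0, rng)
        y = y + profile.hf_irregularity_amp * _bandlimited_noise(n, rate, 2.5, 5.0, rng)
    if profile.jitter_sd > 0:
        x = x + rng.normal(0.0, profile.jitter_sd, n)
        y = y + rng.normal(0.0, profile.jitter_sd, n)

    return SpiralTrial(
        x=x,
        y=y,
        t=t,
        nominal_rate=rate,
        label=profile.label,
        group=metadata.pop("group", "HE" if profile.label == "healthy" else "PD"),
        **metadata,
    )


def simulate_cohort(
    n_per_class: int,
    profiles: dict[str, SimProfile] | None = None,
    base_seed: int = 0,
    trials_per_occasion: int = 3,
    duration: float = 10.0,
    rate: float = 10.0,
    subject_sd_log_speed: float = 0.3,
    subject_sd_log_amp: float = 0.2,
) -> tuple[list[SpiralTrial], pd.DataFrame]:
    """Simulate ``n_per_class`` subjects per condition, 3 trials each.

    Between-subject heterogeneity: each subject draws a multiplicative
    lognormal deviation of ``speed_scale`` (sd of the log 0.3) and of
    the irregularity/tremor amplitudes (sd 0.2), so classes overlap but
    remain separable.  Returns the trials plus a truth table with one
    row per subject.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if profiles is None:
        profiles = PRESETS
    trials: list[SpiralTrial] = []
    truth_rows = []
    for ci, (name, prof) in enumerate(sorted(profiles.items())):
        for si in range(n_per_class):
            ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(ci, si))
            rng = np.random.default_rng(ss)
            subj = replace(
                prof,
                speed_scale=prof.speed_scale
                * float(np.exp(rng.normal(0.0, subject_sd_log_speed))),
                hf_irregularity_amp=prof.hf_irregularity_amp
                * float(np.exp(rng.normal(0.0, subject_sd_log_amp))),
                tremor_amp=prof.tremor_amp
                * float(np.exp(rng.normal(0.0, subject_sd_log_amp))),
            )
            subject_id = f"{name[:4]}{si:03d}"
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "label": name,
                    "speed_scale": subj.speed_scale,
                    "hf_irregularity_amp": subj.hf_irregularity_amp,
                    "tremor_amp": subj.tremor_amp,
                    "hesitation_rate": subj.hesitation_rate,
                    "asymmetry_bias": subj.asymmetry_bias,
                }
            )
            for ti in range(trials_per_occasion):
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trials.append(
                    simulate_trial(
                        subj,
                        duration=duration,
                        rate=rate,
                        seed=trial_seed,
                        subject_id=subject_id,
                        occasion_id=f"{subject_id}-occ1",
                        trial_index=ti + 1,
                    )
                )
    return trials, pd.DataFrame(truth_rows)
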