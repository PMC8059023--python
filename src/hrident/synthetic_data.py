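"""Virtual participants and synthetic 1-Hz treadmill test records.

The study's raw chest-strap data are not publicly deposited, so the
pipeline is exercised on a synthetic cohort with the statistical
structure the analysis assumes: each virtual participant has true
second-order (Phase I + Phase II) heart-rate dynamics drawn from the
reported population dispersion, an affine steady-state HR-speed relation
fixing the operating point, a slow linear Phase III drift, and heart-rate
variability modelled as an AR(1)-filtered Gaussian disturbance plus white
measurement noise.

Population moments for the dynamics (gain 24.70 ± 5.07 bpm/(m/s), time
constants 18.60 ± 7.88 s and 37.95 ± 16.01 s) and age (32.5 ± 12.3 y)
follow the reported cohort; baseline HR and the noise magnitudes are free
synthetic parameters calibrated so the true model's validation RMSE lands
on the ~2 bpm scale of real chest-strap data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .excitation import SpeedProfile
from .identification import TransferFunctionModel, simulate_response

__all__ = [
    "PopulationSpec",
    "ParticipantProfile",
    "TestRecord",
    "draw_participant",
    "compute_hr_ref",
    "determine_operating_speed",
    "simulate_test",
]

#: lower truncation for positive parameters, as a fraction of the mean
_TRUNCATION = 0.1


@dataclass(frozen=True)
class PopulationSpec:
    """Population moments and noise calibration for the virtual cohort."""

    age_mean: float = 32.5
    age_sd: float = 12.3
    k2_mean: float = 24.70
    k2_sd: float = 5.07
    tau21_mean: float = 18.60
    tau21_sd: float = 7.88
    tau22_mean: float = 37.95
    tau22_sd: float = 16.01
    hr_baseline_mean: float = 80.0
    hr_baseline_sd: float = 8.0
    hr_ref_factor: float = 0.765  # moderate/vigorous transition; 0.7 alternate
    drift_rate: float = 0.05 / 60.0  # bpm/s, linear Phase III stand-in
    hrv_sd: float = 2.2  # stationary SD of the AR(1) disturbance, bpm
    hrv_ar_coefficient: float = 0.8  # at 1 Hz
    measurement_noise_sd: float = 1.0  # white, bpm
    true_order: int = 2  # set 1 for null-comparison cohorts

    def __post_init__(self) -> None:
        for name in ("k2_mean", "tau21_mean", "tau22_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("age_sd", "k2_sd", "tau21_sd", "tau22_sd", "hr_baseline_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.hr_ref_factor < 1:
            raise ValueError("hr_ref_factor must be in (0, 1)")
        if not 0 <= self.hrv_ar_coefficient < 1:
            raise ValueError("hrv_ar_coefficient must be in [0, 1)")
        if self.hrv_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.true_order not in (1, 2):
            raise ValueError("true_order must be 1 or 2")


@dataclass(frozen=True)
class ParticipantProfile:
    """A virtual subject's true dynamics and disturbance parameters."""

    id: str
    age: float
    true_model: TransferFunctionModel
    hr_baseline: float
    hr_ref: float
    drift_rate: float
    hrv_sd: float
    hrv_ar_coefficient: float
    measurement_noise_sd: float

    def __post_init__(self) -> None:
        if self.hrv_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.hr_baseline <= self.hr_ref < 220.0:
            raise ValueError("hr_ref must lie between hr_baseline and 220 bpm")

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "age": self.age,
            "true_model": self.true_model.to_dict(),
            "hr_baseline": self.hr_baseline,
            "hr_ref": self.hr_ref,
            "drift_rate": self.drift_rate,
            "hrv_sd": self.hrv_sd,
            "hrv_ar_coefficient": self.hrv_ar_coefficient,
            "measurement_noise_sd": self.measurement_noise_sd,
        }


@dataclass(frozen=True)
class TestRecord:
    """One identification session: 1-Hz heart rate plus the speed profile."""

    participant_id: str
    session: str  # "I" or "II"
    sample_times: np.ndarray
    hr: np.ndarray
    speed_profile: SpeedProfile

    def __post_init__(self) -> None:
        if self.session not in ("I", "II"):
            raise ValueError("session must be 'I' or 'II'")
        t = np.asarray(self.sample_times, dtype=float)
        hr = np.asarray(self.hr, dtype=float)
        if np.any(hr <= 0):
            raise ValueError("heart rate must be strictly positive")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, 1.0):
            raise ValueError("test records are sampled at 1 Hz")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "hr", hr)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.sample_times,
                "speed_mps": self.speed_profile.speeds,
                "hr_bpm": self.hr,
            }
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw resampled until above 0.1x the mean (positivity)."""
    if sd == 0:
        return mean
    lo = _TRUNCATION * mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    raise RuntimeError("truncated normal sampling failed; check mean/sd")


def draw_participant(
    population: PopulationSpec, rng: np.random.Generator, participant_id: str = "P01"
) -> ParticipantProfile:
    """Draw one virtual participant from the population dispersion.

    Parameters are drawn independently (no cross-correlations are
    reported for the cohort) and truncated below at 0.1x the mean to keep
    gains and time constants physiologically positive.
    """
    age = _truncated_normal(rng, population.age_mean, population.age_sd)
    age = float(np.clip(age, 18.0, 75.0))
    k2 = _truncated_normal(rng, population.k2_mean, population.k2_sd)
    tau21 = _truncated_normal(rng, population.tau21_mean, population.tau21_sd)
    tau22 = _truncated_normal(rng, population.tau22_mean, population.tau22_sd)
    hr_baseline = _truncated_normal(
        rng, population.hr_baseline_mean, population.hr_baseline_sd
    )
    if population.true_order == 1:
        # lump the two phases into a mean response time
        model = TransferFunctionModel(order=1, gain=k2, time_constants=(tau21 + tau22,))
    else:
        model = TransferFunctionModel(order=2, gain=k2, time_constants=(tau21, tau22))
    hr_ref = compute_hr_ref(age, population.hr_ref_factor)
    return ParticipantProfile(
        id=participant_id,
        age=age,
        true_model=model,
        hr_baseline=hr_baseline,
        hr_ref=hr_ref,
        drift_rate=population.drift_rate,
        hrv_sd=population.hrv_sd,
        hrv_ar_coefficient=population.hrv_ar_coefficient,
        measurement_noise_sd=population.measurement_noise_sd,
    )


def compute_hr_ref(age: float, factor: float = 0.765) -> float:
    """Target heart rate at the moderate/vigorous intensity transition.

    ``factor * (220 - age)`` bpm; the default factor 0.765 places the
    operating point at the transition, with 0.7 as the conservative
    alternative for participants who would otherwise stay vigorous.
    """
    if not 0 < age < 220:
        raise ValueError("age must lie in (0, 220) years")
    if not 0 < factor < 1:
        raise ValueError("factor must lie in (0, 1)")
    return factor * (220.0 - age)


def determine_operating_speed(
    participant: ParticipantProfile,
    speed_min: float = 0.5,
    speed_max: float = 6.0,
) -> float:
    """Operating-point speed ``v_m`` from the affine steady-state relation.

    The warm-up phase of a real test servo-controls speed until HR settles
    at ``hr_ref``; at steady state that speed satisfies
    ``hr_ref = hr_baseline + k * v_m``, so the closed form is
    ``v_m = (hr_ref - hr_baseline) / k``.
    """
    k = participant.true_model.gain
    if k <= 0:
        raise ValueError("steady-state gain must be positive")
    v_m = (participant.hr_ref - participant.hr_baseline) / k
    if not (v_m == 0.0 or speed_min <= v_m <= speed_max):
        raise ValueError(
            f"operating speed {v_m:.2f} m/s outside treadmill limits "
            f"[{speed_min}, {speed_max}] m/s"
        )
    return float(v_m)


def simulate_test(
    participant: ParticipantProfile,
    profile: SpeedProfile,
    rng: np.random.Generator,
    session: str = "I",
    drift_mode: str = "linear",
) -> TestRecord:
    """Simulate one 1-Hz identification session.

    hr(t) = operating HR
          + second-order LTI response to the speed deviation (zero state)
          + Phase III drift (linear by default; 'creep' gives a slow
            first-order saturating rise of the same asymptotic slope scale)
          + AR(1)-filtered Gaussian HRV
          + white measurement noise.
    """
    T = profile.sample_period
    if T > 1.0 + 1e-9:
        raise ValueError("speed profile must be sampled at 1 Hz or finer")
    t = profile.sample_times
    u_dev = profile.speeds - profile.mean_speed
    y_lti = simulate_response(participant.true_model, u_dev, T)
    hr_op = participant.hr_baseline + participant.true_model.gain * profile.mean_speed

    if drift_mode == "linear":
        drift = participant.drift_rate * t
    elif drift_mode == "creep":
        # slow saturating rise with ~15 min time constant
        tau_d = 900.0
        drift = participant.drift_rate * tau_d * (1.0 - np.exp(-t / tau_d))
    else:
        raise ValueError("drift_mode must be 'linear' or 'creep'")

    a = participant.hrv_ar_coefficient
    hrv = np.zeros(t.size)
    if participant.hrv_sd > 0:
        innov_sd = participant.hrv_sd * np.sqrt(1.0 - a * a)
        e = rng.normal(0.0, innov_sd, size=t.size)
        hrv[0] = rng.normal(0.0, participant.hrv_sd)  # start in stationarity
        if t.size > 1:
            hrv[1:] = signal.lfilter([1.0], [1.0, -a], e[1:], zi=[a * hrv[0]])[0]
    noise = rng.normal(0.0, participant.measurement_noise_sd, size=t.size)

    hr = hr_op + y_lti + drift + hrv + noise
    return TestRecord(
        participant_id=participant.id,
        session=session,
        sample_times=t,
        hr=hr,
        speed_profile=profile,
    )
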