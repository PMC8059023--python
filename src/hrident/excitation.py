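"""PRBS treadmill-speed excitation design.

The formal measurement phase drives treadmill speed as a two-level
pseudo-random binary sequence (PRBS) about an individually determined
operating speed ``v_m``: a maximal-length sequence from a linear-feedback
shift register (LFSR), each bit held for one clock period, mapped to
``v_m ± half_amplitude``.  Model estimation and validation use a
contiguous evaluation window in which the number of high-speed samples
exactly equals the number of low-speed samples, so that the input
deviation is exactly ``±half_amplitude`` after mean removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PRBSSpec",
    "SpeedProfile",
    "EvaluationWindow",
    "generate_prbs_bits",
    "build_speed_profile",
    "select_balanced_window",
    "default_prbs_spec",
]

#: Feedback tap positions giving a maximal-length sequence, by register order.
#: Order 5 uses the standard primitive polynomial x^5 + x^3 + 1.
MAXIMAL_TAPS = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 5),
    7: (7, 6),
}

#: Default LFSR phase.  Chosen so that output bits 3 and 4 (0-based) are
#: high, which makes the canonical 290-2085 s evaluation window balanced
#: at exactly 180 low / 180 high samples (5-s sampling, 60-s bit clock).
DEFAULT_INITIAL_STATE = (1, 1, 0, 0, 0)


@dataclass(frozen=True)
class PRBSSpec:
    """Design parameters of the binary speed excitation.

    Parameters
    ----------
    register_order : int
        Number of LFSR stages; the maximal-length period is
        ``2**register_order - 1`` bits.
    feedback_taps : tuple of int
        1-based register positions XOR-ed to form the feedback bit.
    initial_state : tuple of int
        Nonzero start state ``(s1, ..., s_order)``.
    clock_period : float
        Seconds each bit is held.
    half_amplitude : float
        Speed deviation in m/s; levels are ``mean_speed ± half_amplitude``.
    mean_speed : float
        Operating-point speed ``v_m`` in m/s.
    """

    register_order: int = 5
    feedback_taps: tuple[int, ...] = MAXIMAL_TAPS[5]
    initial_state: tuple[int, ...] = DEFAULT_INITIAL_STATE
    clock_period: float = 60.0
    half_amplitude: float = 0.25
    mean_speed: float = 2.0

    def __post_init__(self) -> None:
        if self.register_order < 2:
            raise ValueError("register_order must be >= 2")
        if len(self.initial_state) != self.register_order:
            raise ValueError("initial_state length must equal register_order")
        if not any(self.initial_state):
            raise ValueError("initial_state must not be all zero")
        if not all(b in (0, 1) for b in self.initial_state):
            raise ValueError("initial_state must be a bit vector")
        if not all(1 <= t <= self.register_order for t in self.feedback_taps):
            raise ValueError("feedback taps must lie in 1..register_order")
        if self.clock_period <= 0:
            raise ValueError("clock_period must be positive")
        if self.half_amplitude <= 0:
            raise ValueError("half_amplitude must be positive")

    @property
    def period_bits(self) -> int:
        return 2**self.register_order - 1


@dataclass(frozen=True)
class SpeedProfile:
    """Uniformly sampled two-level treadmill-speed signal."""

    sample_times: np.ndarray
    speeds: np.ndarray
    mean_speed: float

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times, dtype=float)
        v = np.asarray(self.speeds, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("sample_times and speeds must be 1-d and equal length")
        dt = np.diff(t)
        if t.size > 1 and not np.allclose(dt, dt[0]):
            raise ValueError("sample grid must be uniform")
        object.__setattr__(self, "sample_times", t)
        object.__setattr__(self, "speeds", v)

    @property
    def sample_period(self) -> float:
        return float(self.sample_times[1] - self.sample_times[0])

    @property
    def values(self) -> np.ndarray:
        # alias so generic window extraction works on profiles too
        return self.speeds


@dataclass(frozen=True)
class EvaluationWindow:
    """The N-sample estimation/validation segment (inclusive endpoints)."""

    start_time: float
    end_time: float
    n_samples: int
    sample_period: float

    def __post_init__(self) -> None:
        n = round((self.end_time - self.start_time) / self.sample_period) + 1
        if n != self.n_samples:
            raise ValueError(
                "n_samples inconsistent with (end_time - start_time)/sample_period + 1"
            )

    @property
    def sample_index(self) -> np.ndarray:
        """Discrete time index i = 1..N."""
        return np.arange(1, self.n_samples + 1)


def generate_prbs_bits(spec: PRBSSpec, n_bits: int) -> np.ndarray:
    """Generate the first ``n_bits`` of the maximal-length LFSR sequence.

    The register is a Fibonacci LFSR: the output is the last stage and the
    feedback bit is the XOR of the stages named in ``feedback_taps``.  A tap
    set whose state cycle is shorter than ``2**order - 1`` is rejected.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    order = spec.register_order
    full_period = spec.period_bits

    state = list(spec.initial_state)
    start = tuple(state)
    out = []
    period = None
    for i in range(max(n_bits, full_period + 1)):
        out.append(state[-1])
        fb = 0
        for t in spec.feedback_taps:
            fb ^= state[t - 1]
        state = [fb] + state[:-1]
        if period is None and tuple(state) == start:
            period = i + 1
    if period != full_period:
        raise ValueError(
            f"feedback taps {spec.feedback_taps} are not maximal for order "
            f"{order}: state cycle length {period} < {full_period}"
        )
    bits = np.array(out[:n_bits], dtype=int)
    return bits


def build_speed_profile(
    bits: Sequence[int],
    spec: PRBSSpec,
    sample_period: float,
    duration: float,
) -> SpeedProfile:
    """Expand a bit sequence into a sampled two-level speed signal.

    Each bit is held for ``clock_period`` seconds (zero-order hold); bit 1
    maps to ``mean_speed + half_amplitude`` and bit 0 to
    ``mean_speed - half_amplitude``.  The profile covers samples at
    ``0, sample_period, ..., duration - sample_period``.
    """
    if sample_period <= 0:
        raise ValueError("sample_period must be positive")
    ratio = spec.clock_period / sample_period
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"clock_period {spec.clock_period} s is not an integer multiple of "
            f"sample_period {sample_period} s"
        )
    samples_per_bit = int(round(ratio))
    bits = np.asarray(bits, dtype=int)
    if duration > bits.size * spec.clock_period + 1e-9:
        raise ValueError("duration exceeds the span of the supplied bits")
    n_samples = int(round(duration / sample_period))
    levels = np.where(
        bits == 1,
        spec.mean_speed + spec.half_amplitude,
        spec.mean_speed - spec.half_amplitude,
    )
    speeds = np.repeat(levels, samples_per_bit)[:n_samples]
    times = np.arange(n_samples) * sample_period
    return SpeedProfile(sample_times=times, speeds=speeds, mean_speed=spec.mean_speed)


def select_balanced_window(
    profile: SpeedProfile,
    n_samples: int,
    transient_exclusion: float = 290.0,
) -> EvaluationWindow:
    """Earliest contiguous window with equal high/low sample counts.

    Candidate windows start at or after ``transient_exclusion`` seconds
    (the initial transient of the physiological response is discarded).
    The search is deterministic: the earliest balanced start wins.
    """
    if n_samples < 2 or n_samples % 2:
        raise ValueError("n_samples must be a positive even number")
    T = profile.sample_period
    high = (profile.speeds > profile.mean_speed).astype(int)
    first = int(np.searchsorted(profile.sample_times, transient_exclusion - 1e-9))
    best_imbalance = None
    # cumulative sum makes each candidate O(1)
    csum = np.concatenate([[0], np.cumsum(high)])
    for s in range(first, high.size - n_samples + 1):
        n_high = csum[s + n_samples] - csum[s]
        imbalance = abs(2 * n_high - n_samples)
        if imbalance == 0:
            t0 = float(profile.sample_times[s])
            return EvaluationWindow(
                start_time=t0,
                end_time=t0 + (n_samples - 1) * T,
                n_samples=n_samples,
                sample_period=T,
            )
        if best_imbalance is None or imbalance < best_imbalance:
            best_imbalance = imbalance
    raise ValueError(
        f"no balanced {n_samples}-sample window found after "
        f"{transient_exclusion} s; closest imbalance was {best_imbalance} samples"
    )


def default_prbs_spec(mean_speed: float) -> PRBSSpec:
    """The study's excitation: fifth-order PRBS, ±0.25 m/s, 60-s bit clock."""
    return PRBSSpec(mean_speed=mean_speed)
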