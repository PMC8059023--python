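"""End-to-end study orchestration on a synthetic cohort.

Ties the modules together: draw a cohort, run two PRBS identification
sessions per participant, preprocess to detrended 5-s evaluation
segments, run the counterbalanced cross-validation for both model
orders, and build the statistical report.  One master seed governs every
random draw, so a run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ProcessedSegment, ValidationRecord, cross_validate
from .excitation import (
    EvaluationWindow,
    SpeedProfile,
    build_speed_profile,
    default_prbs_spec,
    generate_prbs_bits,
    select_balanced_window,
)
from .preprocessing import (
    HRSeries,
    detrend_output,
    downsample_hr,
    extract_window,
    remove_mean_input,
)
from .stats_report import ReportBundle, build_report
from .synthetic_data import (
    ParticipantProfile,
    PopulationSpec,
    TestRecord,
    determine_operating_speed,
    draw_participant,
    simulate_test,
)

__all__ = ["StudyConfig", "StudyRun", "simulate_cohort", "preprocess_record", "run_study"]

#: raw 1-Hz record length: the 36-min formal measurement phase
MEASUREMENT_DURATION_S = 2160.0
#: downsampled evaluation window (290-2085 s at 5 s -> 360 samples)
WINDOW_N_SAMPLES = 360
TRANSIENT_EXCLUSION_S = 290.0
DOWNSAMPLE_FACTOR = 5


@dataclass(frozen=True)
class StudyConfig:
    """Study-level knobs; defaults reproduce the reference protocol."""

    n_participants: int = 11
    population: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 1
    duration_s: float = MEASUREMENT_DURATION_S
    window_n_samples: int = WINDOW_N_SAMPLES
    transient_exclusion_s: float = TRANSIENT_EXCLUSION_S
    alpha: float = 0.05


@dataclass
class StudyRun:
    """Everything one pipeline execution produced."""

    config: StudyConfig
    participants: list[ParticipantProfile]
    records: list[TestRecord]
    validation: list[ValidationRecord]
    report: ReportBundle


def participant_speed_profile(
    participant: ParticipantProfile, duration_s: float = MEASUREMENT_DURATION_S
) -> SpeedProfile:
    """The 1-Hz PRBS speed profile about this participant's operating point."""
    v_m = determine_operating_speed(participant)
    spec = default_prbs_spec(mean_speed=v_m)
    n_bits = int(np.ceil(duration_s / spec.clock_period))
    bits = generate_prbs_bits(spec, n_bits)
    return build_speed_profile(bits, spec, sample_period=1.0, duration=duration_s)


def simulate_cohort(config: StudyConfig) -> tuple[list[ParticipantProfile], list[TestRecord]]:
    """Draw the cohort and simulate both identification sessions each."""
    master = np.random.default_rng(config.seed)
    participants: list[ParticipantProfile] = []
    records: list[TestRecord] = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        # inclusion screen: redraw anyone whose operating point falls
        # outside the treadmill's speed range (as recruitment would)
        for _ in range(100):
            participant = draw_participant(config.population, master, pid)
            try:
                determine_operating_speed(participant)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw an eligible participant")
        participants.append(participant)
        profile = participant_speed_profile(participant, config.duration_s)
        for session in ("I", "II"):
            records.append(simulate_test(participant, profile, master, session))
    return participants, records


def preprocess_record(
    record: TestRecord,
    n_samples: int = WINDOW_N_SAMPLES,
    transient_exclusion_s: float = TRANSIENT_EXCLUSION_S,
) -> ProcessedSegment:
    """Raw 1-Hz record -> detrended 5-s evaluation segment.

    Order matters and follows the measurement chain: downsample to 0.2 Hz,
    select the balanced evaluation window on the downsampled grid, cut it
    out, then detrend the output and mean-centre the input.
    """
    hr_1hz = HRSeries(sample_times=record.sample_times, values=record.hr)
    hr_5s = downsample_hr(hr_1hz, DOWNSAMPLE_FACTOR)
    speed_1hz = record.speed_profile
    speed_5s_values = (
        speed_1hz.speeds[: hr_5s.values.size * DOWNSAMPLE_FACTOR]
        .reshape(-1, DOWNSAMPLE_FACTOR)
        .mean(axis=1)
    )
    speed_5s = SpeedProfile(
        sample_times=hr_5s.sample_times,
        speeds=speed_5s_values,
        mean_speed=speed_1hz.mean_speed,
    )
    window: EvaluationWindow = select_balanced_window(
        speed_5s, n_samples, transient_exclusion_s
    )
    y = detrend_output(extract_window(hr_5s, window))
    u = remove_mean_input(extract_window(speed_5s, window))
    return ProcessedSegment(u=u, y=y)


def run_study(config: StudyConfig | None = None) -> StudyRun:
    """Simulate, preprocess, cross-validate and report in one call."""
    config = config or StudyConfig()
    participants, records = simulate_cohort(config)
    cohort: dict[str, dict[str, ProcessedSegment]] = {}
    for rec in records:
        cohort.setdefault(rec.participant_id, {})[rec.session] = preprocess_record(
            rec, config.window_n_samples, config.transient_exclusion_s
        )
    validation = cross_validate(cohort, orders=(1, 2))
    report = build_report(validation, alpha=config.alpha)
    return StudyRun(
        config=config,
        participants=participants,
        records=records,
        validation=validation,
        report=report,
    )
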