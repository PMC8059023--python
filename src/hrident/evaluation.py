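"""Goodness-of-fit metrics and counterbalanced cross-validation.

Validation compares the measured (detrended) heart-rate deviation with
the model's zero-initial-state simulated response on the held-out
session.  Two outcomes are reported per model:

    fit [%] = (1 - ||HR - HR_sim|| / ||HR - mean(HR)||) * 100   (NRMSE)
    RMSE [bpm] = sqrt(mean((HR_sim - HR)^2))

Each participant contributes two session records (I and II); the
counterbalanced scheme estimates on I / validates on II and vice versa,
so a cohort of 11 participants yields 22 model pairs per order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .identification import (
    EstimationResult,
    TransferFunctionModel,
    estimate_model,
    simulate_response,
)
from .preprocessing import DeviationSignal

__all__ = [
    "FitMetrics",
    "ValidationRecord",
    "ProcessedSegment",
    "compute_rmse",
    "compute_fit",
    "cross_validate",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitMetrics:
    """Validation goodness of fit: NRMSE-based fit (%) and RMSE (bpm)."""

    fit: float
    rmse: float

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.fit > 100.0 + 1e-12:
            raise ValueError("fit cannot exceed 100%")


@dataclass(frozen=True)
class ProcessedSegment:
    """A detrended evaluation segment ready for estimation/validation."""

    u: DeviationSignal
    y: DeviationSignal

    def __post_init__(self) -> None:
        if self.u.kind != "input" or self.y.kind != "output":
            raise ValueError("segment needs an input u and an output y")
        if self.u.values.shape != self.y.values.shape:
            raise ValueError("u and y must have equal length")


@dataclass(frozen=True)
class ValidationRecord:
    """One cross-validation outcome (participant x direction x order)."""

    participant_id: str
    estimation_session: str
    validation_session: str
    order: int
    metrics: FitMetrics
    model: TransferFunctionModel

    def __post_init__(self) -> None:
        if self.estimation_session == self.validation_session:
            raise ValueError("estimation and validation sessions must differ")


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, DeviationSignal) else np.asarray(x, dtype=float)


def compute_rmse(hr, hr_sim) -> float:
    """Root-mean-square error between measured and simulated HR (bpm)."""
    a, b = _values(hr), _values(hr_sim)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("signals must be non-empty and of equal length")
    return float(np.sqrt(np.mean((b - a) ** 2)))


def compute_fit(hr, hr_sim) -> float:
    """Normalised RMSE fit in percent: 100 is perfect, 0 matches the mean
    predictor, negative values (worse than the mean) are returned as-is."""
    a, b = _values(hr), _values(hr_sim)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("signals must be non-empty and of equal length")
    denom = np.linalg.norm(a - a.mean())
    if denom == 0:
        raise ValueError("fit undefined for a constant reference signal")
    return float((1.0 - np.linalg.norm(a - b) / denom) * 100.0)


def validate_model(model: TransferFunctionModel, segment: ProcessedSegment) -> FitMetrics:
    """Simulate on the held-out segment (zero initial state) and score."""
    y_sim = simulate_response(model, segment.u)
    return FitMetrics(
        fit=compute_fit(segment.y, y_sim),
        rmse=compute_rmse(segment.y, y_sim),
    )


def cross_validate(
    cohort: dict[str, dict[str, ProcessedSegment]],
    orders: tuple[int, ...] = (1, 2),
) -> list[ValidationRecord]:
    """Counterbalanced cross-validation over sessions I and II.

    ``cohort`` maps participant id -> {"I": segment, "II": segment}.
    Participants missing a session are skipped with a warning.
    """
    records: list[ValidationRecord] = []
    for pid in sorted(cohort):
        sessions = cohort[pid]
        if "I" not in sessions or "II" not in sessions:
            logger.warning("participant %s lacks both sessions; skipped", pid)
            continue
        for order in orders:
            for est, val in (("I", "II"), ("II", "I")):
                seg_est, seg_val = sessions[est], sessions[val]
                result: EstimationResult = estimate_model(order, seg_est.u, seg_est.y)
                records.append(
                    ValidationRecord(
                        participant_id=pid,
                        estimation_session=est,
                        validation_session=val,
                        order=order,
                        metrics=validate_model(result.model, seg_val),
                        model=result.model,
                    )
                )
    return records


def records_to_frame(records: list[ValidationRecord]) -> pd.DataFrame:
    """Tidy table of validation outcomes for the statistics layer."""
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in records],
            "est_session": [r.estimation_session for r in records],
            "val_session": [r.validation_session for r in records],
            "order": [r.order for r in records],
            "fit_pct": [r.metrics.fit for r in records],
            "rmse_bpm": [r.metrics.rmse for r in records],
        }
    )
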