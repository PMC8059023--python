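"""Continuous-time transfer-function models of heart-rate dynamics.

Two small-signal model classes map treadmill-speed deviation u (m/s) to
heart-rate deviation y (bpm) about the operating point:

    P1(s) = k1 / (tau1 s + 1)                       (first order)
    P2(s) = k2 / ((tau21 s + 1)(tau22 s + 1))       (second order)

The first-order model lumps the fast Phase I and slower Phase II
components of the cardiac response into a single mean response time; the
second-order model gives each phase its own time constant.  Simulation
uses exact zero-order-hold (ZOH) discretization, and estimation minimises
the simulation error (output-error least squares) with the gain
concentrated out analytically and time constants searched in log space
from a deterministic grid of starting points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

__all__ = [
    "TransferFunctionModel",
    "EstimationResult",
    "simulate_response",
    "estimate_model",
]


@dataclass(frozen=True)
class TransferFunctionModel:
    """First- or second-order gain/time-constant parameterisation.

    ``gain`` is the steady-state (DC) gain in bpm per m/s; time constants
    are in seconds and, for order 2, stored sorted ascending.
    """

    order: int
    gain: float
    time_constants: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if len(self.time_constants) != self.order:
            raise ValueError("number of time constants must equal the order")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if any(tc <= 0 or not np.isfinite(tc) for tc in self.time_constants):
            raise ValueError("time constants must be positive and finite")
        object.__setattr__(
            self, "time_constants", tuple(sorted(float(t) for t in self.time_constants))
        )

    @property
    def dc_gain(self) -> float:
        return self.gain

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "gain_bpm_per_mps": self.gain,
            "time_constants_s": list(self.time_constants),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunctionModel":
        return cls(
            order=int(d["order"]),
            gain=float(d["gain_bpm_per_mps"]),
            time_constants=tuple(float(t) for t in d["time_constants_s"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class EstimationResult:
    """Outcome of a simulation-error least-squares fit."""

    model: TransferFunctionModel
    residual_sum_of_squares: float
    converged: bool
    n_starts_used: int

    def __post_init__(self) -> None:
        if self.residual_sum_of_squares < 0:
            raise ValueError("residual sum of squares must be >= 0")


def _first_order_zoh(tau: float, u: np.ndarray, T: float) -> np.ndarray:
    """Exact ZOH response of 1/(tau s + 1), zero initial state."""
    a = np.exp(-T / tau)
    return signal.lfilter([0.0, 1.0 - a], [1.0, -a], u)


def _unit_gain_response(
    taus: tuple[float, ...], u: np.ndarray, T: float
) -> np.ndarray:
    """Exact ZOH response of the unit-DC-gain model with the given poles.

    Distinct time constants use the partial-fraction split into two
    first-order recursions; a (near-)repeated pair falls back to the
    matrix-exponential state-space discretization, which is exact for the
    confluent case as well.
    """
    if len(taus) == 1:
        return _first_order_zoh(taus[0], u, T)
    t1, t2 = taus
    if abs(t1 - t2) > 1e-7 * max(t1, t2):
        # 1/((t1 s+1)(t2 s+1)) = A/(t1 s+1) + B/(t2 s+1)
        A = t1 / (t1 - t2)
        B = t2 / (t2 - t1)
        return A * _first_order_zoh(t1, u, T) + B * _first_order_zoh(t2, u, T)
    # cascade state space; exact for t1 == t2
    Ac = np.array([[-1.0 / t1, 0.0], [1.0 / t2, -1.0 / t2]])
    Bc = np.array([[1.0 / t1], [0.0]])
    Cc = np.array([[0.0, 1.0]])
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((Ac, Bc, Cc, [[0.0]]), T, method="zoh")
    num, den = signal.ss2tf(Ad, Bd, Cd, Dd)
    return signal.lfilter(num[0], den, u)


def simulate_response(model: TransferFunctionModel, u, sample_period: float | None = None):
    """Sampled zero-initial-state response to a zero-order-hold input.

    ``u`` may be a plain array or a ``DeviationSignal``; in the latter case
    the signal's own sample period is used and a ``DeviationSignal`` of
    output kind is returned.
    """
    from .preprocessing import DeviationSignal  # local import avoids a cycle

    if isinstance(u, DeviationSignal):
        y = model.gain * _unit_gain_response(
            model.time_constants, u.values, u.sample_period
        )
        return DeviationSignal(sample_times=u.sample_times, values=y, kind="output")
    if sample_period is None or sample_period <= 0:
        raise ValueError("sample_period must be positive for array input")
    u = np.asarray(u, dtype=float)
    return model.gain * _unit_gain_response(model.time_constants, u, sample_period)


# deterministic multi-start grids (seconds)
_STARTS_ORDER1 = [10.0, 30.0, 60.0, 120.0]
_STARTS_ORDER2 = [
    (10.0, 30.0),
    (10.0, 60.0),
    (10.0, 120.0),
    (30.0, 60.0),
    (30.0, 120.0),
    (60.0, 120.0),
    (5.0, 60.0),
    (20.0, 40.0),
]


def estimate_model(
    order: int,
    u,
    y,
    sample_period: float | None = None,
    max_evaluations: int = 2000,
) -> EstimationResult:
    """Simulation-error least-squares fit of a first- or second-order model.

    Minimises sum_i (y_i - y_sim_i)^2 over gain and time constants.  The
    gain enters the simulation linearly, so for fixed time constants the
    optimal gain has a closed form and only the time constants are searched
    numerically (Nelder-Mead in log space, which enforces positivity).
    Eight deterministic starting points for order 2 (four for order 1) make
    the fit reproducible without any random number use.
    """
    from .preprocessing import DeviationSignal

    if isinstance(u, DeviationSignal):
        if sample_period is None:
            sample_period = u.sample_period
        u = u.values
    if isinstance(y, DeviationSignal):
        y = y.values
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if u.shape != y.shape or u.ndim != 1:
        raise ValueError("u and y must be 1-d arrays of equal length")
    n_params = 1 + order
    if u.size < 10 * n_params:
        raise ValueError(f"need at least {10 * n_params} samples to fit order {order}")
    if sample_period is None or sample_period <= 0:
        raise ValueError("sample_period must be positive")
    if np.ptp(u) == 0:
        raise ValueError("input signal is constant: not persistently exciting")

    y_ss = float(np.dot(y, y))
    if y_ss == 0.0:
        warnings.warn("output signal is identically zero; returning zero gain")
        taus = (60.0,) * order
        model = TransferFunctionModel(order=order, gain=0.0, time_constants=taus)
        return EstimationResult(model, 0.0, converged=True, n_starts_used=0)

    def cost(log_taus: np.ndarray) -> float:
        taus = tuple(np.exp(log_taus))
        if any(t < 1e-6 or t > 1e5 for t in taus):
            return y_ss  # off the physiological map; no better than zero gain
        yhat = _unit_gain_response(taus, u, sample_period)
        denom = float(np.dot(yhat, yhat))
        if denom <= 0.0:
            return y_ss
        g = float(np.dot(y, yhat)) / denom
        return y_ss - g * g * denom

    def run_starts(starts):
        best = None
        any_success = False
        for s in starts:
            x0 = np.log(np.atleast_1d(np.asarray(s, dtype=float)))
            res = optimize.minimize(
                cost,
                x0,
                method="Nelder-Mead",
                options={
                    "maxfev": max_evaluations,
                    "xatol": 1e-8,
                    "fatol": 1e-10 * max(y_ss, 1.0),
                },
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        return best, any_success

    if order == 1:
        starts = list(_STARTS_ORDER1)
        best, any_success = run_starts(starts)
    else:
        # the order-2 class contains order-1 behaviour in the limit of a
        # vanishing second time constant; seeding the search from the best
        # first-order fit keeps the nested-class residual ordering intact
        best1, _ = run_starts([[t] for t in _STARTS_ORDER1])
        tau1_hat = float(np.exp(best1.x[0]))
        starts = list(_STARTS_ORDER2) + [(tau1_hat, 1e-2), (tau1_hat, 1e-4)]
        best, any_success = run_starts(starts)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimisation starts failed to converge")

    taus = tuple(np.exp(best.x))
    yhat = _unit_gain_response(taus, u, sample_period)
    g = float(np.dot(y, yhat)) / float(np.dot(yhat, yhat))
    rss = float(np.sum((y - g * yhat) ** 2))
    model = TransferFunctionModel(order=order, gain=g, time_constants=taus)
    return EstimationResult(
        model=model,
        residual_sum_of_squares=rss,
        converged=any_success,
        n_starts_used=len(starts),
    )
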