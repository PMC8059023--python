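"""Paired statistical comparison of model orders and report assembly.

The hypothesis is directional: second-order models validate better than
first-order ones (lower RMSE, higher fit).  Differences are first
screened for normality (Lilliefors-corrected Kolmogorov-Smirnov); if
normality is not rejected for both outcomes, paired one-sided t-tests at
alpha = 0.05 are run and one-sided 95% confidence intervals for the mean
difference reported, matching the test direction.  A Wilcoxon
signed-rank fallback is available for non-normal differences, flagged as
an extension beyond the primary analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .evaluation import ValidationRecord
from .identification import TransferFunctionModel

__all__ = [
    "ComparisonSummary",
    "AverageModel",
    "PowerSpec",
    "lilliefors_normality",
    "paired_one_sided_ttest",
    "one_sided_mean_ci",
    "paired_ttest_power",
    "required_sample_size",
    "average_models",
    "build_report",
    "ReportBundle",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-outcome paired comparison (second order minus first order)."""

    outcome: str  # "rmse" or "fit"
    mean_p1: float
    sd_p1: float
    mean_p2: float
    sd_p2: float
    mean_difference: float
    ci_bound: float
    ci_direction: str  # "less" -> (-inf, bound]; "greater" -> [bound, +inf)
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 pairs")
        if self.ci_direction not in ("less", "greater"):
            raise ValueError("ci_direction must be 'less' or 'greater'")

    def ci_string(self) -> str:
        if self.ci_direction == "less":
            return f"(-inf, {self.ci_bound:.2f})"
        return f"({self.ci_bound:.2f}, +inf)"


@dataclass(frozen=True)
class AverageModel:
    """Cohort-average gain/time constants for one model order."""

    order: int
    gain_mean: float
    gain_sd: float
    gain_ci: tuple[float, float]
    tau_means: tuple[float, ...]
    tau_sds: tuple[float, ...]
    tau_cis: tuple[tuple[float, float], ...]
    n: int

    def model(self) -> TransferFunctionModel:
        return TransferFunctionModel(
            order=self.order, gain=self.gain_mean, time_constants=self.tau_means
        )


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the paired one-sided t-test power computation."""

    effect_size: float  # standardized mean difference of paired outcomes
    n: int
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def lilliefors_normality(differences, alpha: float = ALPHA):
    """Kolmogorov-Smirnov normality test with the Lilliefors correction.

    The null mean and SD are estimated from the sample, which invalidates
    the standard KS null distribution; the Lilliefors correction accounts
    for that.  Returns ``(statistic, p_value, reject)``.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance sample: normality test undefined")
    stat, p = _sm_lilliefors(d, dist="norm")
    return float(stat), float(p), bool(p < alpha)


def paired_one_sided_ttest(x_p2, x_p1, direction: str):
    """Paired one-sided t-test on differences d = x_p2 - x_p1.

    ``direction`` is the alternative for the mean difference: ``"greater"``
    for the fit outcome (second order fits better) and ``"less"`` for RMSE
    (second order errs less).  Returns ``(t, p, mean_difference)``.
    """
    a = np.asarray(x_p2, dtype=float)
    b = np.asarray(x_p1, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired samples with n >= 2")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    d = a - b
    if np.var(d, ddof=1) == 0:
        if np.all(d == 0):
            # symmetric null: t = 0, one-sided p = 1/2
            return 0.0, 0.5, 0.0
        raise ValueError("zero variance of nonzero differences")
    res = stats.ttest_rel(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue), float(d.mean())


def one_sided_mean_ci(differences, level: float = 0.95, direction: str = "greater"):
    """One-sided CI for the mean difference, dual to the one-sided t-test.

    ``direction='greater'`` gives [mean - t*SE, +inf); ``'less'`` gives
    (-inf, mean + t*SE].  The finite bound is returned with the direction.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need n >= 2")
    sd = np.std(d, ddof=1)
    if sd == 0:
        raise ValueError("zero-variance sample")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    se = sd / np.sqrt(d.size)
    tcrit = stats.t.ppf(level, d.size - 1)
    if direction == "greater":
        return float(d.mean() - tcrit * se), direction
    return float(d.mean() + tcrit * se), direction


def paired_ttest_power(spec: PowerSpec) -> float:
    """Power of the one-sided paired t-test via the noncentral t CDF."""
    df = spec.n - 1
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    nc = spec.effect_size * np.sqrt(spec.n)
    return float(stats.nct.sf(tcrit, df, nc))


def required_sample_size(
    effect_size: float, alpha: float = 0.05, target_power: float = 0.8
) -> int:
    """Smallest n achieving the target power for the one-sided paired test."""
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, 10_000):
        if paired_ttest_power(PowerSpec(effect_size, n, alpha, target_power)) >= target_power:
            return n
    raise ValueError("required n exceeds 10000; effect size too small")


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    se = np.std(x, ddof=1) / np.sqrt(x.size)
    h = stats.t.ppf(0.5 + level / 2.0, x.size - 1) * se
    return (float(x.mean() - h), float(x.mean() + h))


def average_models(models: list[TransferFunctionModel]) -> AverageModel:
    """Cohort-average model: arithmetic means/SDs of gains and sorted
    time constants, with two-sided 95% CIs of the means."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    orders = {m.order for m in models}
    if len(orders) != 1:
        raise ValueError("all models must share one order")
    order = orders.pop()
    gains = np.array([m.gain for m in models])
    taus = np.array([m.time_constants for m in models])  # (n, order), sorted rows
    return AverageModel(
        order=order,
        gain_mean=float(gains.mean()),
        gain_sd=float(gains.std(ddof=1)),
        gain_ci=_mean_ci(gains),
        tau_means=tuple(float(v) for v in taus.mean(axis=0)),
        tau_sds=tuple(float(v) for v in taus.std(axis=0, ddof=1)),
        tau_cis=tuple(_mean_ci(taus[:, j]) for j in range(order)),
        n=len(models),
    )


@dataclass
class ReportBundle:
    """Machine-readable analysis report mirroring the headline outputs."""

    summaries: dict[str, ComparisonSummary]
    normality: dict[str, dict]
    normality_ok: bool
    average_models: dict[int, AverageModel]
    paired_samples: pd.DataFrame  # per-record outcomes, wide by order
    wilcoxon: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "summaries": {
                k: {
                    "outcome": s.outcome,
                    "mean_P1": s.mean_p1,
                    "sd_P1": s.sd_p1,
                    "mean_P2": s.mean_p2,
                    "sd_P2": s.sd_p2,
                    "mean_difference": s.mean_difference,
                    "ci_95": s.ci_string(),
                    "ci_bound": s.ci_bound,
                    "p_value": s.p_value,
                    "n": s.n,
                }
                for k, s in self.summaries.items()
            },
            "normality": self.normality,
            "normality_ok": self.normality_ok,
            "average_models": {
                str(order): {
                    "gain_mean": am.gain_mean,
                    "gain_sd": am.gain_sd,
                    "gain_ci95": list(am.gain_ci),
                    "tau_means": list(am.tau_means),
                    "tau_sds": list(am.tau_sds),
                    "tau_cis95": [list(ci) for ci in am.tau_cis],
                    "n": am.n,
                }
                for order, am in self.average_models.items()
            },
            "wilcoxon": self.wilcoxon,
            "notes": self.notes,
        }
        return out

    def to_markdown(self) -> str:
        lines = ["# Model-order comparison report", ""]
        lines.append(
            "| outcome | P1 mean ± SD | P2 mean ± SD | MD (95% CI) | p-value |"
        )
        lines.append("|---|---|---|---|---|")
        for key in ("rmse", "fit"):
            if key not in self.summaries:
                continue
            s = self.summaries[key]
            unit = "bpm" if key == "rmse" else "%"
            lines.append(
                f"| {key}/{unit} | {s.mean_p1:.2f} ± {s.sd_p1:.2f} "
                f"| {s.mean_p2:.2f} ± {s.sd_p2:.2f} "
                f"| {s.mean_difference:.2f} {s.ci_string()} | {s.p_value:.2e} |"
            )
        lines.append("")
        lines.append(f"n = {next(iter(self.summaries.values())).n} model pairs")
        lines.append("")
        for order, am in sorted(self.average_models.items()):
            taus = ", ".join(f"{t:.2f} s" for t in am.tau_means)
            lines.append(
                f"- average order-{order} model: gain {am.gain_mean:.2f} "
                f"bpm/(m/s), time constants {taus} (n = {am.n})"
            )
        lines.append("")
        lines.append(
            "No multiple-testing correction is applied across the two outcomes."
        )
        for note in self.notes:
            lines.append(f"- {note}")
        return "\n".join(lines) + "\n"


_DIRECTIONS = {"rmse": "less", "fit": "greater"}
_COLUMNS = {"rmse": "rmse_bpm", "fit": "fit_pct"}


def build_report(
    records: list[ValidationRecord] | pd.DataFrame,
    models: list[TransferFunctionModel] | None = None,
    alpha: float = ALPHA,
) -> ReportBundle:
    """Assemble the full comparison report from validation records.

    Pairs order-1 and order-2 outcomes by (participant, estimation
    session), screens the differences for normality, then runs the paired
    one-sided t-tests and builds one-sided CIs.  When normality is
    rejected for an outcome the t-test is still reported for reference but
    the bundle flags the violation and adds a Wilcoxon signed-rank result.
    """
    from .evaluation import records_to_frame

    if isinstance(records, pd.DataFrame):
        frame = records.copy()
        if models is None:
            raise ValueError("models must be supplied with a plain DataFrame")
        model_list = models
    else:
        frame = records_to_frame(records)
        model_list = [r.model for r in records]

    if frame["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for the cohort summary")

    wide = frame.pivot_table(
        index=["participant", "est_session"],
        columns="order",
        values=["rmse_bpm", "fit_pct"],
    )
    n = len(wide)

    summaries: dict[str, ComparisonSummary] = {}
    normality: dict[str, dict] = {}
    wilcoxon: dict[str, dict] = {}
    notes: list[str] = []
    normality_ok = True
    for outcome, col in _COLUMNS.items():
        x1 = wide[(col, 1)].to_numpy()
        x2 = wide[(col, 2)].to_numpy()
        d = x2 - x1
        stat, p_norm, reject = lilliefors_normality(d, alpha)
        normality[outcome] = {"statistic": stat, "p_value": p_norm, "reject": reject}
        direction = _DIRECTIONS[outcome]
        t, p, md = paired_one_sided_ttest(x2, x1, direction)
        bound, _ = one_sided_mean_ci(d, 0.95, direction)
        summaries[outcome] = ComparisonSummary(
            outcome=outcome,
            mean_p1=float(x1.mean()),
            sd_p1=float(x1.std(ddof=1)),
            mean_p2=float(x2.mean()),
            sd_p2=float(x2.std(ddof=1)),
            mean_difference=md,
            ci_bound=bound,
            ci_direction=direction,
            p_value=p,
            n=n,
        )
        if reject:
            normality_ok = False
            w = stats.wilcoxon(d, alternative=direction)
            wilcoxon[outcome] = {
                "statistic": float(w.statistic),
                "p_value": float(w.pvalue),
            }
            notes.append(
                f"normality rejected for {outcome} differences (Lilliefors "
                f"p = {p_norm:.3f}); Wilcoxon signed-rank added as a fallback "
                "beyond the primary paired t-test analysis"
            )

    avg: dict[int, AverageModel] = {}
    for order in sorted({m.order for m in model_list}):
        of_order = [m for m in model_list if m.order == order]
        if len(of_order) >= 2:
            avg[order] = average_models(of_order)

    paired = wide.reset_index()
    paired.columns = ["_".join(str(c) for c in col if c != "") for col in paired.columns]
    return ReportBundle(
        summaries=summaries,
        normality=normality,
        normality_ok=normality_ok,
        average_models=avg,
        paired_samples=paired,
        wilcoxon=wilcoxon,
        notes=notes,
    )
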