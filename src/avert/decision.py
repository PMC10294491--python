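"""Sensitivity curves, fragility scans and non-inferiority decision rules.

The counterfactual parameter identifying the AER is external to the trial,
so a sensitivity analysis over its plausible range is essential; fragility
scans probe how many added events would flip a non-inferiority conclusion,
contrasting the stability of the rate-ratio and AER scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .estimands import (
    CounterfactualSpec,
    IntervalEstimate,
    TrialObservation,
    aer_from_incidence,
    rate_ratio,
)
from .uncertainty import (
    BayesSettings,
    aer_ci_bayes,
    aer_ci_delta,
    aer_ci_delta_efficacy,
    exact_conditional_rr_ci,
    wald_log_rr_ci,
)

__all__ = [
    "SensitivityCurve",
    "NoninferiorityVerdict",
    "FragilityScan",
    "sensitivity_curve",
    "default_lambda_p_grid",
    "fragility_scan",
    "noninferiority_rr",
    "noninferiority_aer",
    "effect_preservation_margin",
    "fda_relative_efficacy_criterion",
]

_RR_CI = {"wald": wald_log_rr_ci, "exact": exact_conditional_rr_ci}


@dataclass(frozen=True)
class SensitivityCurve:
    """Pointwise AER estimates and interval bounds over a grid of
    counterfactual parameter values (``lambda_P`` per 100 PYFU, or
    ``theta_CP`` in (0, 1))."""

    parameter_name: str
    grid: tuple[float, ...]
    estimates: tuple[float, ...]
    lowers: tuple[float, ...]
    uppers: tuple[float, ...]
    method: str
    level: float = 0.95

    def __post_init__(self) -> None:
        lens = {len(self.grid), len(self.estimates), len(self.lowers), len(self.uppers)}
        if lens != {len(self.grid)}:
            raise ValueError("grid, estimates, lowers and uppers must have equal length")
        if any(b >= a for a, b in zip(self.grid[1:], self.grid)):
            raise ValueError("grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter_name: self.grid,
                "psi": self.estimates,
                "lower": self.lowers,
                "upper": self.uppers,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Point estimate (black) with confidence limits (grey), matching
        the conventional sensitivity-plot layout.  Requires matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.estimates, color="black", label="point estimate")
        ax.plot(self.grid, self.lowers, color="grey")
        ax.plot(self.grid, self.uppers, color="grey")
        ax.set_xlabel(
            "counterfactual placebo incidence (per 100 PYFU)"
            if self.parameter_name == "lambda_P"
            else "counterfactual control efficacy"
        )
        ax.set_ylabel("averted events ratio")
        return ax


@dataclass(frozen=True)
class NoninferiorityVerdict:
    """Outcome of a non-inferiority rule.

    On the rate-ratio scale the conclusion uses the *upper* confidence
    limit and strict inequality: non-inferior iff upper < margin.  On the
    AER scale it uses the *lower* limit: non-inferior iff lower >=
    threshold (the preserved fraction of the control effect).
    """

    scale: str
    margin_or_threshold: float
    bound_used: float
    conclusion: bool
    narrative: str
    interval: Optional[IntervalEstimate] = None
    estimate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale not in ("rate_ratio", "aer"):
            raise ValueError(f"scale must be 'rate_ratio' or 'aer', got {self.scale!r}")
        expected = (
            self.bound_used < self.margin_or_threshold
            if self.scale == "rate_ratio"
            else self.bound_used >= self.margin_or_threshold
        )
        if self.conclusion is not expected:
            raise ValueError("conclusion inconsistent with bound and margin/threshold")


@dataclass(frozen=True)
class FragilityScan:
    """Event-perturbation scan: row k repeats the analysis with k events
    added to one arm.  ``fragility_index`` is the smallest k that flips
    the k=0 conclusion, or None if no flip occurs within the scan."""

    arm: str
    table: pd.DataFrame
    fragility_index: Optional[int]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def default_lambda_p_grid(trial: TrialObservation, n: int = 50) -> np.ndarray:
    """Default sensitivity grid: ``n`` evenly spaced counterfactual
    incidences between 1.05 x and 4 x the observed control incidence."""
    lam_c = trial.control.incidence
    return np.linspace(1.05 * lam_c, 4.0 * lam_c, n)


def sensitivity_curve(
    trial: TrialObservation,
    parameter_name: str = "lambda_P",
    grid: Optional[Sequence[float]] = None,
    level: float = 0.95,
) -> SensitivityCurve:
    """AER point estimates and delta-method intervals over a grid of the
    counterfactual parameter.

    ``lambda_P`` mode treats the counterfactual placebo incidence as
    known; ``theta_CP`` mode treats the control efficacy as known, with
    the implied lambda_P = lambda_C/(1 - theta_CP) recomputed inside the
    delta expansion (see :func:`avert.uncertainty.aer_ci_delta_efficacy`).
    Every grid value must be admissible (lambda_P above the observed
    control incidence; theta_CP in (0, 1)).
    """
    if parameter_name not in ("lambda_P", "theta_CP"):
        raise ValueError(f"parameter_name must be 'lambda_P' or 'theta_CP', got {parameter_name!r}")
    lam_c = trial.control.incidence
    if grid is None:
        if parameter_name == "lambda_P":
            grid = default_lambda_p_grid(trial)
        else:
            grid = 1.0 - lam_c / default_lambda_p_grid(trial)
    grid = [float(g) for g in grid]
    estimates, lowers, uppers = [], [], []
    for g in grid:
        if parameter_name == "lambda_P":
            if g <= lam_c:
                raise ValueError(
                    f"grid value lambda_P={g:g} inadmissible: must exceed the observed "
                    f"control incidence {lam_c:g} per 100 PYFU"
                )
            est = aer_from_incidence(trial, g).psi
            ci = aer_ci_delta(trial, g, level=level)
        else:
            if not 0 < g < 1:
                raise ValueError(f"grid value theta_CP={g:g} inadmissible: must lie in (0, 1)")
            est = aer_from_incidence(trial, lam_c / (1.0 - g)).psi
            ci = aer_ci_delta_efficacy(trial, g, level=level)
        estimates.append(est)
        lowers.append(ci.lower)
        uppers.append(ci.upper)
    return SensitivityCurve(
        parameter_name=parameter_name,
        grid=tuple(grid),
        estimates=tuple(estimates),
        lowers=tuple(lowers),
        uppers=tuple(uppers),
        method="delta_log",
        level=level,
    )


def fragility_scan(
    trial: TrialObservation,
    arm: str,
    max_added_events: int,
    evaluator: Callable[[TrialObservation], NoninferiorityVerdict],
) -> FragilityScan:
    """Re-run a non-inferiority rule with 0..max_added_events extra events
    in one arm (person-time unchanged).

    ``evaluator`` maps a trial to a :class:`NoninferiorityVerdict` — e.g.
    ``lambda t: noninferiority_rr(t, margin=1.62)`` or an AER rule.  The
    fragility index is the smallest k whose conclusion differs from k=0.
    """
    if max_added_events < 1:
        raise ValueError("max_added_events must be >= 1")
    rows = []
    baseline: Optional[bool] = None
    index: Optional[int] = None
    for k in range(max_added_events + 1):
        verdict = evaluator(trial.with_added_events(arm, k))
        if k == 0:
            baseline = verdict.conclusion
        elif index is None and verdict.conclusion is not baseline:
            index = k
        rows.append(
            {
                "added_events": k,
                "estimate": verdict.estimate,
                "bound": verdict.bound_used,
                "non_inferior": verdict.conclusion,
            }
        )
    return FragilityScan(arm=arm, table=pd.DataFrame(rows), fragility_index=index)


def noninferiority_rr(
    trial: TrialObservation,
    margin: float,
    ci_method: str = "wald",
    level: float = 0.95,
) -> NoninferiorityVerdict:
    """Conventional rate-ratio non-inferiority rule: non-inferior iff the
    upper confidence limit of beta_EC is strictly below ``margin``."""
    if not margin > 1:
        raise ValueError(f"rate-ratio non-inferiority margin must exceed 1, got {margin}")
    ci = _RR_CI[ci_method](trial, level=level)
    beta = rate_ratio(trial)
    ok = ci.upper < margin
    narrative = (
        f"rate ratio {beta:.2f} ({ci.lower:.2f}, {ci.upper:.2f}); upper limit "
        f"{'below' if ok else 'not below'} the non-inferiority margin {margin:g}: "
        f"{'non-inferiority concluded' if ok else 'non-inferiority NOT concluded'}"
    )
    return NoninferiorityVerdict(
        scale="rate_ratio",
        margin_or_threshold=margin,
        bound_used=ci.upper,
        conclusion=ok,
        narrative=narrative,
        interval=ci,
        estimate=beta,
    )


def noninferiority_aer(
    trial: TrialObservation,
    cf: CounterfactualSpec,
    preservation_threshold: float = 0.5,
    interval_method: str = "delta",
    level: float = 0.95,
    bayes_settings: Optional[BayesSettings] = None,
) -> NoninferiorityVerdict:
    """Effect-preservation rule on the AER scale: non-inferior iff the
    lower interval bound of Psi is at least ``preservation_threshold``.

    The narrative states the preserved percentage of the control effect
    implied by the lower bound, reported at the conventional 2-dp
    interval precision.
    """
    if not 0 < preservation_threshold <= 1:
        raise ValueError(
            f"preservation threshold must lie in (0, 1], got {preservation_threshold}"
        )
    lambda_p = cf.implied_lambda_p(trial)
    psi = aer_from_incidence(trial, lambda_p).psi
    if interval_method == "delta":
        if cf.mode == "control_efficacy":
            ci = aer_ci_delta_efficacy(trial, cf.value, level=level)
        else:
            ci = aer_ci_delta(trial, lambda_p, level=level)
    elif interval_method == "bayes":
        if bayes_settings is None:
            raise ValueError("bayes interval_method requires bayes_settings")
        ci = aer_ci_bayes(trial, cf, bayes_settings, level=level).interval
    else:
        raise ValueError(f"interval_method must be 'delta' or 'bayes', got {interval_method!r}")
    ok = ci.lower >= preservation_threshold
    pct = round(round(ci.lower, 2) * 100)
    narrative = (
        f"averted events ratio {psi:.2f} ({ci.lower:.2f}-{ci.upper:.2f}): the experimental "
        f"treatment preserved at least {pct}% of the effect of the control treatment; "
        f"{'non-inferiority concluded' if ok else 'non-inferiority NOT concluded'} "
        f"at preservation threshold {preservation_threshold:g}"
    )
    return NoninferiorityVerdict(
        scale="aer",
        margin_or_threshold=preservation_threshold,
        bound_used=ci.lower,
        conclusion=ok,
        narrative=narrative,
        interval=ci,
        estimate=psi,
    )


def effect_preservation_margin(theta_cp: float, fraction: float) -> float:
    """Rate-ratio non-inferiority margin preserving ``fraction`` of the
    control effect on the log-incidence scale.

    With control efficacy theta_CP, the control-vs-placebo log rate ratio
    is log(1 - theta_CP); requiring the experimental arm to retain a
    fraction f of that effect bounds the experimental-vs-control rate
    ratio by (1/(1 - theta_CP))^(1 - f).
    """
    if not 0 < theta_cp < 1:
        raise ValueError(f"theta_cp must lie strictly in (0, 1), got {theta_cp}")
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    return (1.0 / (1.0 - theta_cp)) ** (1.0 - fraction)


def fda_relative_efficacy_criterion(
    trial: TrialObservation,
    ci_method: str = "wald",
    level: float = 0.95,
    floor: float = -0.10,
) -> NoninferiorityVerdict:
    """Regulatory success criterion on proportionate reduction 1 - beta_EC.

    Maps the rate-ratio interval (L, U) to (1 - U, 1 - L) for the
    proportionate reduction and passes iff its lower bound is strictly
    above ``floor`` (default -10%, the COVID-19 vaccine non-inferiority
    criterion).  Note this uses the head-to-head proportionate reduction,
    not the placebo-anchored efficacy ratio.
    """
    ci = _RR_CI[ci_method](trial, level=level)
    est = 1.0 - rate_ratio(trial)
    lower = 1.0 - ci.upper
    ok = lower > floor
    # Encode as an 'aer'-scale verdict shape (lower bound vs threshold) but
    # with strict inequality, so express via a margin on the rate-ratio scale:
    narrative = (
        f"relative-efficacy (proportionate reduction) estimate {est:+.2f} with lower "
        f"{level:.0%} bound {lower:+.2f}; criterion lower bound > {floor:+.0%}: "
        f"{'PASS' if ok else 'FAIL'}"
    )
    return NoninferiorityVerdict(
        scale="rate_ratio",
        margin_or_threshold=1.0 - floor,
        bound_used=ci.upper,
        conclusion=ci.upper < 1.0 - floor,
        narrative=narrative,
        interval=ci,
        estimate=est,
    )
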