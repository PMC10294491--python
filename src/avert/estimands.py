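"""Domain types and closed-form point estimators for active-control trials.

An active-control randomised trial compares an experimental treatment with
an established effective treatment; there is no placebo arm.  With
event-count/person-time outcomes the conventional estimand is the rate
ratio ``beta_EC = lambda_E / lambda_C``.  When the control treatment is
highly effective this ratio can be clinically misleading, because it
ignores the (large) number of events both arms *averted* relative to no
treatment.

The averted events ratio (AER)

    Psi = (lambda_P - lambda_E) / (lambda_P - lambda_C)

compares the incidence reduction achieved by each arm against a
counterfactual placebo incidence ``lambda_P``.  It is interpretable as the
proportion of the control treatment's preventive effect achieved by the
experimental treatment.  Equivalently, writing ``theta_CP = 1 -
lambda_C/lambda_P`` for the control treatment's efficacy versus no
treatment,

    Psi = (1 - beta_EC * (1 - theta_CP)) / theta_CP = theta_EP / theta_CP.

The AER is not identified by the trial alone: it requires an external
assumption, supplied here as a :class:`CounterfactualSpec` — either a
counterfactual placebo incidence (per 100 person-years) or a control
efficacy in (0, 1), optionally with a prior distribution for Bayesian
unconditional analysis.

Conventions
-----------
* ``person_time`` is in person-years of follow-up (PYFU); every reported
  incidence, including ``lambda_P``, is per 100 PYFU.  The single
  conversion point is :data:`INCIDENCE_SCALE`.
* Orientation is fixed: experimental over control for both ``beta_EC``
  and ``Psi``; there is no auto-detection from arm labels.
* All arithmetic is full double precision; 1-dp averted counts and 2-dp
  ratios are a concern of the reporting layer only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "INCIDENCE_SCALE",
    "ArmObservation",
    "TrialObservation",
    "Prior",
    "CounterfactualSpec",
    "IntervalEstimate",
    "AERResult",
    "DegenerateCounterfactualError",
    "incidence_rate",
    "rate_ratio",
    "expected_placebo_events",
    "averted_events",
    "aer_from_incidence",
    "aer_from_efficacy",
    "relative_efficacy",
    "proportionate_reduction",
]

#: Incidence rates (including the counterfactual placebo incidence) are
#: expressed per this many person-years of follow-up.
INCIDENCE_SCALE = 100.0


class DegenerateCounterfactualError(ValueError):
    """The counterfactual placebo incidence does not exceed the observed
    control incidence, so the AER denominator collapses."""


@dataclass(frozen=True)
class ArmObservation:
    """One trial arm's aggregate outcome: event count and person-time.

    Parameters
    ----------
    label
        Arm name, e.g. ``"TDF/FTC"``.
    events
        Non-negative count of incident endpoints.
    person_time
        Positive person-years of follow-up (PYFU).
    """

    label: str
    events: int
    person_time: float

    def __post_init__(self) -> None:
        if int(self.events) != self.events or self.events < 0:
            raise ValueError(f"events must be a non-negative integer, got {self.events!r}")
        if not (self.person_time > 0 and math.isfinite(self.person_time)):
            raise ValueError(f"person_time must be positive and finite, got {self.person_time!r}")

    @property
    def incidence(self) -> float:
        """Incidence rate per :data:`INCIDENCE_SCALE` PYFU."""
        return INCIDENCE_SCALE * self.events / self.person_time


@dataclass(frozen=True)
class TrialObservation:
    """Paired control/experimental arms from one active-control trial."""

    control: ArmObservation
    experimental: ArmObservation

    def __post_init__(self) -> None:
        if self.control.label == self.experimental.label:
            raise ValueError(f"arm labels must differ, both are {self.control.label!r}")

    def with_added_events(self, arm: str, k: int) -> "TrialObservation":
        """Return a copy with ``k`` events added to ``arm`` (``"control"``
        or ``"experimental"``), person-time unchanged.  Used by fragility
        scans."""
        if arm not in ("control", "experimental"):
            raise ValueError(f"arm must be 'control' or 'experimental', got {arm!r}")
        old = getattr(self, arm)
        new = ArmObservation(old.label, old.events + k, old.person_time)
        if arm == "control":
            return TrialObservation(control=new, experimental=self.experimental)
        return TrialObservation(control=self.control, experimental=new)


@dataclass(frozen=True)
class Prior:
    """A named prior distribution for a counterfactual parameter.

    Supported families: ``gamma`` (shape, rate), ``lognormal`` (mu, sigma
    of log), ``beta`` (a, b) and ``point`` (value,).  Gamma/lognormal are
    natural for a placebo incidence per 100 PYFU; beta for an efficacy.
    """

    family: str
    params: tuple[float, ...]

    _FAMILIES = ("gamma", "lognormal", "beta", "point")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; expected one of {self._FAMILIES}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "gamma":
            shape, rate = self.params
            return rng.gamma(shape, 1.0 / rate, size)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        if self.family == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        return np.full(size, self.params[0])


@dataclass(frozen=True)
class CounterfactualSpec:
    """External assumption required to identify the AER.

    ``mode="placebo_incidence"``: ``value`` is the counterfactual placebo
    incidence lambda_P per 100 PYFU (> 0).
    ``mode="control_efficacy"``: ``value`` is the control treatment's
    efficacy theta_CP versus no treatment, in (0, 1).

    An optional ``prior`` enables unconditional (Bayesian) analysis that
    integrates over the counterfactual parameter.
    """

    mode: str
    value: float
    prior: Optional[Prior] = None

    def __post_init__(self) -> None:
        if self.mode == "placebo_incidence":
            if not self.value > 0:
                raise ValueError(f"placebo incidence must be > 0, got {self.value}")
        elif self.mode == "control_efficacy":
            if not 0 < self.value < 1:
                raise ValueError(f"control efficacy must lie in (0, 1), got {self.value}")
        else:
            raise ValueError(
                f"mode must be 'placebo_incidence' or 'control_efficacy', got {self.mode!r}"
            )

    def implied_lambda_p(self, trial: TrialObservation) -> float:
        """Counterfactual placebo incidence per 100 PYFU implied by this
        spec for ``trial`` (identity in placebo-incidence mode; in
        efficacy mode lambda_P = lambda_C / (1 - theta_CP))."""
        if self.mode == "placebo_incidence":
            return self.value
        return trial.control.incidence / (1.0 - self.value)


@dataclass(frozen=True)
class IntervalEstimate:
    """A (lower, upper) interval for a ratio-scale quantity, with its
    confidence/credibility level and the method that produced it."""

    lower: float
    upper: float
    level: float = 0.95
    method: str = "wald_log"

    _METHODS = ("wald_log", "exact_conditional", "delta_log", "bayes_mc")

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(f"lower ({self.lower}) must not exceed upper ({self.upper})")
        if not 0 < self.level < 1:
            raise ValueError(f"level must lie in (0, 1), got {self.level}")
        if self.method not in self._METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")

    @property
    def width_log(self) -> float:
        """Width on the log scale (inf if the interval touches 0)."""
        if self.lower <= 0:
            return math.inf
        return math.log(self.upper) - math.log(self.lower)


@dataclass(frozen=True)
class AERResult:
    """Result of an averted-events-ratio analysis of one trial.

    ``psi`` is Psi = (lambda_P - lambda_E)/(lambda_P - lambda_C) at full
    precision.  ``predicted_*`` are the expected event counts in each arm
    under no treatment (lambda_P x person_time); ``averted_*`` are
    predicted minus observed and may be negative for a harmful arm (a
    warning is recorded rather than an error — only lambda_P <= lambda_C
    is fatal, because the denominator of Psi collapses).

    Note ``psi`` equals the ratio of averted *counts*
    ``averted_experimental / averted_control`` exactly when the two arms
    have equal person-time, and to a factor ``T_C/T_E`` otherwise.
    """

    psi: float
    predicted_control: float
    predicted_experimental: float
    averted_control: float
    averted_experimental: float
    counterfactual: CounterfactualSpec
    trial: TrialObservation
    interval: Optional[IntervalEstimate] = None
    warnings: tuple[str, ...] = field(default=())


def incidence_rate(arm: ArmObservation, per: float = INCIDENCE_SCALE) -> float:
    """Event incidence of ``arm`` per ``per`` person-years."""
    if not per > 0:
        raise ValueError(f"per must be positive, got {per}")
    return per * arm.events / arm.person_time


def rate_ratio(trial: TrialObservation) -> float:
    """Rate ratio beta_EC = lambda_E / lambda_C, experimental over control."""
    if trial.control.events == 0:
        raise ZeroDivisionError(
            "rate ratio undefined: control arm "
            f"{trial.control.label!r} has zero events"
        )
    return trial.experimental.incidence / trial.control.incidence


def expected_placebo_events(arm: ArmObservation, efficacy: float) -> float:
    """Back-calculate the event count had ``arm`` received no treatment.

    Inverts the action of an efficacy ``theta`` in (0, 1) on a Poisson
    mean: observed = expected x (1 - theta), so expected =
    events / (1 - theta).
    """
    if not 0 < efficacy < 1:
        raise ValueError(f"efficacy must lie strictly in (0, 1), got {efficacy}")
    return arm.events / (1.0 - efficacy)


def averted_events(arm: ArmObservation, lambda_p: float) -> tuple[float, float]:
    """Predicted and averted event counts for one arm under counterfactual
    placebo incidence ``lambda_p`` (per 100 PYFU).

    Returns ``(predicted, averted)`` with ``predicted = lambda_p x
    person_time / 100`` and ``averted = predicted - events``.  A negative
    averted count (treatment harm) is returned, not clamped.
    """
    if not lambda_p > 0:
        raise ValueError(f"lambda_p must be > 0, got {lambda_p}")
    predicted = lambda_p * arm.person_time / INCIDENCE_SCALE
    return predicted, predicted - arm.events


def aer_from_incidence(trial: TrialObservation, lambda_p: float) -> AERResult:
    """Averted events ratio via the counterfactual placebo incidence.

    Psi = (lambda_P - lambda_E)/(lambda_P - lambda_C), with per-arm
    predicted and averted counts populated.  Requires lambda_P strictly
    above the observed control incidence.
    """
    lam_c = trial.control.incidence
    lam_e = trial.experimental.incidence
    if not lambda_p > lam_c:
        raise DegenerateCounterfactualError(
            f"counterfactual placebo incidence lambda_P={lambda_p:g} per 100 PYFU "
            f"must exceed the observed control incidence lambda_C={lam_c:g}"
        )
    pred_c, avert_c = averted_events(trial.control, lambda_p)
    pred_e, avert_e = averted_events(trial.experimental, lambda_p)
    warnings: tuple[str, ...] = ()
    if avert_e < 0:
        warnings = (
            f"experimental arm {trial.experimental.label!r} has negative averted "
            f"events ({avert_e:.3f}): observed incidence exceeds the counterfactual",
        )
    psi = (lambda_p - lam_e) / (lambda_p - lam_c)
    cf = CounterfactualSpec(mode="placebo_incidence", value=lambda_p)
    return AERResult(
        psi=psi,
        predicted_control=pred_c,
        predicted_experimental=pred_e,
        averted_control=avert_c,
        averted_experimental=avert_e,
        counterfactual=cf,
        trial=trial,
        warnings=warnings,
    )


def aer_from_efficacy(beta_ec: float, theta_cp: float) -> float:
    """Averted events ratio via the control treatment's efficacy.

    Psi = (1 - beta_EC (1 - theta_CP)) / theta_CP.  Algebraically
    identical to :func:`aer_from_incidence` with
    lambda_P = lambda_C / (1 - theta_CP).
    """
    if not 0 < theta_cp < 1:
        raise ValueError(f"theta_cp must lie strictly in (0, 1), got {theta_cp}")
    if beta_ec < 0:
        raise ValueError(f"beta_ec must be >= 0, got {beta_ec}")
    return (1.0 - beta_ec * (1.0 - theta_cp)) / theta_cp


def relative_efficacy(theta_ep: float, theta_cp: float) -> float:
    """Ratio of efficacies theta_EP / theta_CP — the efficacy of the
    experimental treatment relative to the efficacy of the control.
    Equals the AER."""
    if theta_cp == 0:
        raise ZeroDivisionError("relative efficacy undefined for theta_cp = 0")
    return theta_ep / theta_cp


def proportionate_reduction(trial: TrialObservation) -> float:
    """(lambda_C - lambda_E)/lambda_C = 1 - beta_EC.

    The proportionate reduction in events using the experimental rather
    than the control treatment, with no reference to a hypothetical
    placebo group.  This is the *alternative* definition of "relative
    efficacy" common in the influenza-vaccine literature; it is
    fundamentally different from the AER and may be negative.
    """
    return 1.0 - rate_ratio(trial)
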