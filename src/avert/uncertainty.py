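"""Interval estimation for the rate ratio and the averted events ratio.

Four methods, each tagged on the returned :class:`~avert.estimands.IntervalEstimate`:

``wald_log``
    Large-sample normal interval for log beta_EC with variance
    1/x_E + 1/x_C (the Poisson log-rate-ratio variance).
``exact_conditional``
    Conditional on the total event count, x_E is binomial with
    p = lambda_E T_E / (lambda_E T_E + lambda_C T_C); the Clopper-Pearson
    interval for p, mapped through the odds transform and the exposure
    ratio T_C/T_E, gives an exact interval for beta_EC.
``delta_log``
    Normal approximation on log Psi treating the counterfactual as known.
    With A_g the averted count in arm g, Var(log Psi) = x_C/A_C^2 +
    x_E/A_E^2 (each observed count contributes its Poisson variance
    through d log Psi / d x_g = -/+ 1/A_g).
``bayes_mc``
    Gamma-Poisson Monte Carlo: per-arm incidence posteriors
    lambda_g ~ Gamma(x_g + c, T_g) (c = 0.5, the Jeffreys shape
    increment, by default), the counterfactual either fixed or drawn
    from its prior, Psi evaluated per draw, equal-tailed credible
    interval reported.  Draws with lambda_P <= lambda_C are discarded
    (Psi is undefined there) and the discarded fraction is reported;
    more than 50% discarded raises, since the counterfactual is then
    inconsistent with the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimands import (
    INCIDENCE_SCALE,
    AERResult,
    CounterfactualSpec,
    IntervalEstimate,
    TrialObservation,
    aer_from_incidence,
    rate_ratio,
)

__all__ = [
    "BayesSettings",
    "BayesAERSummary",
    "MethodInapplicableError",
    "CounterfactualInconsistentError",
    "wald_log_rr_ci",
    "exact_conditional_rr_ci",
    "aer_ci_delta",
    "aer_ci_delta_efficacy",
    "aer_ci_bayes",
]


class MethodInapplicableError(ValueError):
    """The requested interval method cannot be applied to these data."""


class CounterfactualInconsistentError(ValueError):
    """The counterfactual assumption is incompatible with the observed data
    (most posterior draws imply lambda_P <= lambda_C)."""


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    return stats.norm.ppf(0.5 + level / 2.0)


@dataclass(frozen=True)
class BayesSettings:
    """Settings for gamma-Poisson Monte Carlo AER inference.

    prior_shape_increment
        Added to each arm's event count in the gamma posterior shape;
        0.5 is the Jeffreys prior for a Poisson rate.
    draws
        Number of Monte Carlo draws; >= 1000 required for any reported
        interval (200 000 keeps 2-dp quantiles stable to ~0.005).
    seed
        Mandatory RNG seed; identical seeds give identical intervals.
    counterfactual_draws
        If True, sample lambda_P from ``CounterfactualSpec.prior``
        (unconditional analysis); otherwise hold it fixed at its value.
    """

    seed: int
    prior_shape_increment: float = 0.5
    draws: int = 200_000
    counterfactual_draws: bool = False

    def __post_init__(self) -> None:
        if self.prior_shape_increment < 0:
            raise ValueError("prior_shape_increment must be >= 0")
        if self.draws < 1000:
            raise ValueError(f"draws must be >= 1000 for a reported interval, got {self.draws}")


@dataclass(frozen=True)
class BayesAERSummary:
    """Posterior summary of the AER from Monte Carlo draws."""

    interval: IntervalEstimate
    mean: float
    median: float
    discarded_fraction: float
    n_draws: int


def wald_log_rr_ci(trial: TrialObservation, level: float = 0.95) -> IntervalEstimate:
    """Wald interval for the rate ratio on the log scale.

    CI = exp(log beta_EC +/- z sqrt(1/x_E + 1/x_C)).  Requires at least
    one event in each arm; with a zero count the log-scale variance is
    infinite and :func:`exact_conditional_rr_ci` should be used instead.
    """
    x_e, x_c = trial.experimental.events, trial.control.events
    if x_e == 0 or x_c == 0:
        raise MethodInapplicableError(
            "Wald log-scale interval requires >= 1 event per arm "
            f"(got control={x_c}, experimental={x_e}); use exact_conditional_rr_ci"
        )
    beta = rate_ratio(trial)
    half = _z(level) * math.sqrt(1.0 / x_e + 1.0 / x_c)
    return IntervalEstimate(
        lower=beta * math.exp(-half), upper=beta * math.exp(half),
        level=level, method="wald_log",
    )


def exact_conditional_rr_ci(trial: TrialObservation, level: float = 0.95) -> IntervalEstimate:
    """Exact conditional (Clopper-Pearson inversion) interval for the rate
    ratio.

    Conditional on n = x_E + x_C, x_E ~ Binomial(n, p) with
    p = beta_EC T_E / (beta_EC T_E + T_C).  The exact binomial interval
    for p is mapped back through beta_EC = p/(1-p) x T_C/T_E.  The lower
    limit is 0 when x_E = 0 and the upper limit is +inf when x_C = 0.
    """
    x_e, x_c = trial.experimental.events, trial.control.events
    n = x_e + x_c
    if n == 0:
        raise MethodInapplicableError("no events in either arm: rate ratio is unidentified")
    alpha = 1.0 - level
    t_ratio = trial.control.person_time / trial.experimental.person_time
    if x_e == 0:
        lower = 0.0
    else:
        p_lo = stats.beta.ppf(alpha / 2.0, x_e, n - x_e + 1)
        lower = p_lo / (1.0 - p_lo) * t_ratio
    if x_e == n:  # x_c == 0
        upper = math.inf
    else:
        p_hi = stats.beta.ppf(1.0 - alpha / 2.0, x_e + 1, n - x_e)
        upper = p_hi / (1.0 - p_hi) * t_ratio
    return IntervalEstimate(lower=lower, upper=upper, level=level, method="exact_conditional")


def aer_ci_delta(trial: TrialObservation, lambda_p: float, level: float = 0.95) -> IntervalEstimate:
    """Delta-method interval for the AER on the log scale, counterfactual
    placebo incidence treated as known.

    Both averted counts must be positive; otherwise the log-scale
    expansion is meaningless and a Bayesian interval should be used.
    """
    res = aer_from_incidence(trial, lambda_p)
    a_c, a_e = res.averted_control, res.averted_experimental
    if a_c <= 0 or a_e <= 0:
        raise MethodInapplicableError(
            f"delta-method interval requires positive averted counts in both arms "
            f"(control {a_c:.3f}, experimental {a_e:.3f}); consider aer_ci_bayes"
        )
    var = trial.control.events / a_c**2 + trial.experimental.events / a_e**2
    half = _z(level) * math.sqrt(var)
    return IntervalEstimate(
        lower=res.psi * math.exp(-half), upper=res.psi * math.exp(half),
        level=level, method="delta_log",
    )


def aer_ci_delta_efficacy(
    trial: TrialObservation, theta_cp: float, level: float = 0.95
) -> IntervalEstimate:
    """Delta-method AER interval with the control *efficacy* held known.

    With theta_CP fixed, the implied counterfactual incidence
    lambda_P = lambda_C/(1 - theta_CP) moves with the observed control
    incidence, so Psi reduces to (1 - beta_EC (1 - theta_CP))/theta_CP —
    a function of the rate ratio alone.  Propagating the Poisson variance
    of both counts through that function,

        Var(log Psi) = [beta (1-theta) / (1 - beta (1-theta))]^2 (1/x_E + 1/x_C).

    The lambda_C contribution partially cancels between the implied
    lambda_P and the denominator, which is why this variance differs from
    :func:`aer_ci_delta` evaluated at the implied lambda_P.
    """
    if not 0 < theta_cp < 1:
        raise ValueError(f"theta_cp must lie strictly in (0, 1), got {theta_cp}")
    x_e, x_c = trial.experimental.events, trial.control.events
    if x_e == 0 or x_c == 0:
        raise MethodInapplicableError(
            "efficacy-mode delta interval requires >= 1 event per arm"
        )
    beta = rate_ratio(trial)
    shrink = beta * (1.0 - theta_cp)
    if shrink >= 1.0:
        raise MethodInapplicableError(
            f"observed rate ratio {beta:.3f} with theta_CP={theta_cp:g} implies a "
            "non-positive experimental-arm averted count"
        )
    psi = (1.0 - shrink) / theta_cp
    var = (shrink / (1.0 - shrink)) ** 2 * (1.0 / x_e + 1.0 / x_c)
    half = _z(level) * math.sqrt(var)
    return IntervalEstimate(
        lower=psi * math.exp(-half), upper=psi * math.exp(half),
        level=level, method="delta_log",
    )


def posterior_draws(
    trial: TrialObservation, cf: CounterfactualSpec, settings: BayesSettings
) -> tuple[np.ndarray, float]:
    """Monte Carlo draws of Psi under the gamma-Poisson model.

    Returns ``(psi_draws, discarded_fraction)`` after removing draws with
    a non-positive AER denominator.  Exposed so draws can be exported for
    external diagnostics.
    """
    rng = np.random.default_rng(settings.seed)
    n = settings.draws
    inc = settings.prior_shape_increment
    # Gamma(shape=x+c, rate=T/100) so draws are incidences per 100 PYFU.
    lam_c = rng.gamma(trial.control.events + inc, 1.0, n) / (
        trial.control.person_time / INCIDENCE_SCALE
    )
    lam_e = rng.gamma(trial.experimental.events + inc, 1.0, n) / (
        trial.experimental.person_time / INCIDENCE_SCALE
    )
    if settings.counterfactual_draws:
        if cf.prior is None:
            raise ValueError("counterfactual_draws=True requires a prior on the counterfactual")
        par = cf.prior.sample(rng, n)
    else:
        par = np.full(n, cf.value)
    if cf.mode == "placebo_incidence":
        lam_p = par
    else:
        if np.any(par >= 1.0) or np.any(par <= 0.0):
            raise ValueError("control-efficacy draws must lie in (0, 1)")
        lam_p = lam_c / (1.0 - par)
    keep = lam_p > lam_c
    discarded = 1.0 - keep.mean()
    psi = (lam_p[keep] - lam_e[keep]) / (lam_p[keep] - lam_c[keep])
    return psi, float(discarded)


def aer_ci_bayes(
    trial: TrialObservation, cf: CounterfactualSpec, settings: BayesSettings,
    level: float = 0.95,
) -> BayesAERSummary:
    """Equal-tailed Bayesian credible interval for the AER with posterior
    mean and median, by gamma-Poisson Monte Carlo (see module docstring)."""
    psi, discarded = posterior_draws(trial, cf, settings)
    if discarded > 0.5:
        raise CounterfactualInconsistentError(
            f"{discarded:.1%} of draws imply lambda_P <= lambda_C: the counterfactual "
            "assumption is inconsistent with the observed control incidence"
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(psi, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BayesAERSummary(
        interval=IntervalEstimate(lower=float(lo), upper=float(hi), level=level, method="bayes_mc"),
        mean=float(psi.mean()),
        median=float(np.median(psi)),
        discarded_fraction=discarded,
        n_draws=int(psi.size),
    )
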