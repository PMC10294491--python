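"""Synthetic active-control trial generation and estimator calibration.

Generative model: given a counterfactual placebo incidence lambda_P (per
100 PYFU) and per-arm efficacies theta_CP, theta_EP versus no treatment,
the true arm incidences are lambda_C = lambda_P (1 - theta_CP) and
lambda_E = lambda_P (1 - theta_EP); each arm's event count is Poisson with
mean lambda_g x T / 100.  Rates are constant over follow-up — the model
works entirely in count/person-time summaries, with no event times,
dropout or non-adherence.  The true AER is theta_EP / theta_CP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .estimands import INCIDENCE_SCALE, ArmObservation, TrialObservation

__all__ = ["ScenarioSpec", "CalibrationSummary", "simulate_trial", "estimator_calibration"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A simulation scenario for an active-control trial.

    lambda_p : counterfactual placebo incidence per 100 PYFU.
    theta_cp, theta_ep : control/experimental efficacy vs no treatment, in (0, 1).
    person_time : PYFU per arm.
    replicates : number of simulated trials.
    seed : RNG seed; replicate r is identical whether generated alone or
        within a batch (one child seed per replicate).
    """

    lambda_p: float
    theta_cp: float
    theta_ep: float
    person_time: float
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_p > 0:
            raise ValueError("lambda_p must be > 0")
        for name in ("theta_cp", "theta_ep"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not self.person_time > 0:
            raise ValueError("person_time must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def true_psi(self) -> float:
        return self.theta_ep / self.theta_cp

    @property
    def true_lambda_c(self) -> float:
        return self.lambda_p * (1.0 - self.theta_cp)

    @property
    def true_lambda_e(self) -> float:
        return self.lambda_p * (1.0 - self.theta_ep)

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


def _replicate_counts(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (control, experimental) Poisson counts.

    Seed isolation: each replicate r uses the independent child stream
    spawned from (seed, r), so subsetting a scenario to one replicate
    reproduces exactly that replicate.
    """
    mu_c = spec.true_lambda_c * spec.person_time / INCIDENCE_SCALE
    mu_e = spec.true_lambda_e * spec.person_time / INCIDENCE_SCALE
    x_c = np.empty(spec.replicates, dtype=np.int64)
    x_e = np.empty(spec.replicates, dtype=np.int64)
    for r in range(spec.replicates):
        rng = np.random.default_rng([spec.seed, r])
        x_c[r] = rng.poisson(mu_c)
        x_e[r] = rng.poisson(mu_e)
    return x_c, x_e


def simulate_trial(spec: ScenarioSpec, replicate: int = 0) -> TrialObservation:
    """One simulated trial (replicate ``replicate`` of the scenario)."""
    if not 0 <= replicate < spec.replicates:
        raise ValueError(f"replicate must lie in [0, {spec.replicates}), got {replicate}")
    rng = np.random.default_rng([spec.seed, replicate])
    x_c = rng.poisson(spec.true_lambda_c * spec.person_time / INCIDENCE_SCALE)
    x_e = rng.poisson(spec.true_lambda_e * spec.person_time / INCIDENCE_SCALE)
    return TrialObservation(
        control=ArmObservation("control", int(x_c), spec.person_time),
        experimental=ArmObservation("experimental", int(x_e), spec.person_time),
    )


@dataclass(frozen=True)
class CalibrationSummary:
    """Aggregate behaviour of the AER estimator over simulated trials."""

    mean_psi: float
    sd_psi: float
    coverage: float
    n_used: int
    n_degenerate: int
    true_psi: float
    rejection_rate_rr: Optional[float] = None
    rejection_rate_aer: Optional[float] = None


def estimator_calibration(
    spec: ScenarioSpec,
    analysis_lambda_p: float,
    level: float = 0.95,
    rr_margin: Optional[float] = None,
    aer_threshold: Optional[float] = None,
) -> CalibrationSummary:
    """Run the AER point estimator and delta interval on every replicate.

    Replicates where the delta method is inapplicable (observed control
    incidence at or above ``analysis_lambda_p``, or a non-positive
    experimental averted count) are excluded from all summaries and
    counted in ``n_degenerate``; more than 20% degenerate raises, since
    the scenario is then inadmissible for this analysis.  Coverage is the
    fraction of intervals containing the scenario's true Psi.  Optional
    decision rates: ``rr_margin`` counts replicates whose Wald upper
    rate-ratio limit falls below the margin; ``aer_threshold`` counts
    replicates whose lower AER limit reaches the threshold.
    """
    if spec.replicates < 100:
        raise ValueError("calibration requires >= 100 replicates")
    if not analysis_lambda_p > 0:
        raise ValueError("analysis_lambda_p must be > 0")
    x_c, x_e = _replicate_counts(spec)
    t = spec.person_time
    pred = analysis_lambda_p * t / INCIDENCE_SCALE
    a_c = pred - x_c
    a_e = pred - x_e
    ok = (a_c > 0) & (a_e > 0)
    n_degenerate = int((~ok).sum())
    if n_degenerate > 0.2 * spec.replicates:
        raise ValueError(
            f"scenario inadmissible: {n_degenerate}/{spec.replicates} replicates are "
            f"degenerate at analysis lambda_P = {analysis_lambda_p:g}"
        )
    x_c, x_e, a_c, a_e = x_c[ok], x_e[ok], a_c[ok], a_e[ok]
    psi = a_e / a_c  # equal person-time per arm: count ratio == incidence form
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(x_c / a_c**2 + x_e / a_e**2)
    lower, upper = psi * np.exp(-half), psi * np.exp(half)
    true_psi = spec.true_psi
    covered = (lower <= true_psi) & (true_psi <= upper)
    rej_rr = None
    if rr_margin is not None:
        with np.errstate(divide="ignore"):
            both = (x_c > 0) & (x_e > 0)
            beta = np.where(both, x_e / np.maximum(x_c, 1), np.nan)
            up = beta * np.exp(z * np.sqrt(1.0 / np.maximum(x_e, 1) + 1.0 / np.maximum(x_c, 1)))
            rej_rr = float(np.mean(up[both] < rr_margin)) if both.any() else np.nan
    rej_aer = float(np.mean(lower >= aer_threshold)) if aer_threshold is not None else None
    return CalibrationSummary(
        mean_psi=float(psi.mean()),
        sd_psi=float(psi.std(ddof=1)),
        coverage=float(covered.mean()),
        n_used=int(ok.sum()),
        n_degenerate=n_degenerate,
        true_psi=true_psi,
        rejection_rate_rr=rej_rr,
        rejection_rate_aer=rej_aer,
    )
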