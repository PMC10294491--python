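# avert

Averted-events analysis for active-control randomised trials with
event-count / person-time outcomes.

## The problem

Active-control trials compare an experimental treatment against an
established effective treatment because a placebo arm would be unethical.
The conventional estimand, the rate ratio
β<sub>EC</sub> = λ<sub>E</sub>/λ<sub>C</sub>, can be clinically
misleading when the control is highly effective: an experimental vaccine
with 80% efficacy tested against a 95%-efficacious comparator shows a
rate ratio of 4.00 — "markedly inferior" — even though it would avert
80% of the cases a placebo population would suffer.

`avert` implements the **averted events ratio (AER)**

&nbsp;&nbsp;&nbsp;&nbsp;Ψ = (λ<sub>P</sub> − λ<sub>E</sub>) / (λ<sub>P</sub> − λ<sub>C</sub>)

where λ<sub>P</sub> is the *counterfactual placebo incidence* — the event
rate the trial population would have experienced with no treatment. Ψ is
the proportion of the control treatment's preventive effect achieved by
the experimental treatment. Writing θ<sub>CP</sub> = 1 − λ<sub>C</sub>/λ<sub>P</sub>
for the control's efficacy versus no treatment, the identical quantity can
be computed from an assumed control efficacy instead:

&nbsp;&nbsp;&nbsp;&nbsp;Ψ = (1 − β<sub>EC</sub>(1 − θ<sub>CP</sub>)) / θ<sub>CP</sub> = θ<sub>EP</sub>/θ<sub>CP</sub>.

Either counterfactual parameter is an *input* — external knowledge, not
something the trial can estimate — so the package ships sensitivity
analysis over its plausible range, fragility scans of non-inferiority
conclusions under added events, effect-preservation margins, four
interval methods (Wald log-scale and exact conditional for the rate
ratio; log-scale delta method and gamma-Poisson Bayesian Monte Carlo for
the AER), and a Poisson trial simulator for calibration studies.

## Worked example

The DISCOVER HIV pre-exposure prophylaxis trial observed 11 incident HIV
infections over 4386 person-years (PYFU) on TDF-FTC (control) and 6 over
4370 PYFU on TAF-FTC (experimental). With a trial summary CSV

```csv
arm,role,events,person_years
TDF/FTC,control,11,4386
TAF/FTC,experimental,6,4370
```

and the pessimistic counterfactual placebo incidence of 2.06 per 100
PYFU:

```sh
avert estimate --trial discover.csv --counterfactual-incidence 2.06 --ni-threshold 0.5
```

prints

```
Averted events analysis
=======================

Counterfactual placebo incidence: 2.06 per 100 PYFU

Group    PYFU  Observed  Predicted  Averted
TDF/FTC  4386  11        90.4       79.4
TAF/FTC  4370  6         90.0       84.0

Rate ratio (experimental vs control): 0.55 (0.20–1.48 [wald_log])
Averted events ratio: 1.06 (0.96–1.17 [delta_log])

averted events ratio 1.06 (0.96-1.17): the experimental treatment preserved at least 96% of the effect of the control treatment; non-inferiority concluded at preservation threshold 0.5
```

Reading this: had nobody received prophylaxis, ~90 infections were
expected in each arm, so TDF-FTC averted an estimated 79.4 infections and
TAF-FTC 84.0. The AER of 1.06 says TAF-FTC prevented ~6% *more*
infections than the active control, with a plausible range from 4% fewer
to 17% more; non-inferiority follows emphatically from the lower limit.
Contrast the fragile rate-ratio conclusion (margin 1.62):

```sh
avert fragility --trial discover.csv --arm experimental --max-k 3 --margin 1.62
```

```
added_events,estimate,bound,non_inferior
0,0.547451633035157,1.4802903158064544,True
1,0.6386935718743499,1.6475674206935333,False
...
```

a *single* additional event in the TAF-FTC arm pushes the upper
confidence limit from 1.48 to 1.65, overturning the conclusion, whereas
the AER merely moves from 1.06 to 1.05. `avert sensitivity` traces Ψ and
its interval over a grid of counterfactual values, and `avert simulate`
runs calibration scenarios; the same functionality is available from
Python via `avert.estimands`, `avert.uncertainty`, `avert.decision` and
`avert.simulate`.

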