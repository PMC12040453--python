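# radpop

Compartmental modelling of the temporal response of a glioma cell
population to single-dose irradiation.

Time-lapse microscopy of irradiated cell cultures produces density curves
with a characteristic shape: a slow post-exposure rise while DNA
double-strand breaks are repaired, a maximum a day or so later, a decline
as misrepaired cells die or senesce, and — at survivable doses — a late
regrowth of the repaired population.  `radpop` implements a two-phase
cell-fate model of this response, the estimation pipeline that fits it to
replicate density curves, the surviving-fraction and cohort-effect analyses
built on the fitted rates, the nuclei-counting pipeline that turns
fluorescence frames into densities, and a synthetic-data generator so the
whole chain is testable end to end.  It is aimed at radiobiology modellers
and microscopy analysts working in Python.

## The model

During the *repairing phase* (`0 ≤ t ≤ Ta`) the population grows with a
linearly ramping proliferation coefficient,

```
dC/dt = (kd/Ta) · t · C · (1 − C/Cmax),
```

and at `t = Ta` it enters the *regrow-or-die phase*: damaged cells `Cd`
either repair (→ `Cr`, rate λr, normal growth rate k0) or misrepair
(→ `Cu`, rate λu) and then senesce (→ `Cs`, rate λs) or die (→ `CD`,
rate λD), with the structural relations `kd = λu + λr − γ`,
`λD = γ − λs`.  Dead cells detach, so the observed density is
`C = Cd + Cr + Cu + Cs`.  Fits minimize the reduced chi-square
`χ²ν = 1/(n−k) Σ [(Cdata − Cmod)/σ]²` with bounded multi-start
optimization; k0, γ, Cmax and Ta are fixed beforehand by dedicated
estimators (exponential control fits, profile likelihood, peak timing,
derivative maximum), leaving (λs, λu, λr) free per curve.  The asymptotic
surviving fraction is `S = λr/(λu+λr)`, and the ratio `Cr/(Cs+CD)` at the
experiment endpoint quantifies the cohort effect — suppression of regrowth
by co-irradiated dying/senescent neighbours.  See `docs/methods.md` for
the full account.

## Worked example

```python
import numpy as np
import radpop as rp

curves = rp.generate_timecourses(rp.ExperimentDesign(seed=7))
curve = [c for c in curves if c.dose == 15.0][-1]
result = rp.fit(curve, n_starts=200, seed=1)
print(f"chi2_nu = {result.chi2_nu:.3f}")
for name in result.free_names:
    print(f"{name}: {getattr(result.params, name):.5f}")
print(f"S_inf = {rp.surviving_fraction_limit(result.params):.2e}")
```

prints

```
chi2_nu = 0.697
lambda_s: 0.02407
lambda_u: 0.11926
lambda_r: 0.00005
S_inf = 4.52e-04
```

— the fitted senescence and misrepair rates sit within a few percent of the
generating truth (0.025 and 0.12 h⁻¹), the reduced chi-square is of order
one for correctly weighted noise, and the surviving fraction is in the
10⁻⁴ regime expected at 15 Gy (λr, orders of magnitude below λu, is the
one weakly identified rate).  The `examples/` directory has one short
script per capability: simulation, curve fitting, the parameter-fixing
estimators, survival/cohort analyses, nuclei counting, and the end-to-end
pipeline with its reproducibility manifest.

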