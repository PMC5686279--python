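# resistpkpd

Semi-mechanistic PKPD modeling of **acquired resistance to EGFR tyrosine-kinase
inhibitors** (erlotinib, gefitinib) in patient-derived tumor xenografts — for
pharmacometricians and modelers who want to simulate, fit and compare
tumor-growth-inhibition (TGI) models with an emergent drug-resistant cell
population, and to explore dosing regimens in silico.

## The models

**PK.** One-compartment oral kinetics with first-order absorption and
elimination,

    dAd/dt = -ka·Ad,   dAp/dt = ka·Ad - ke·Ap,   Cp = Ap / (V - D·I),

with `Cp` in µg/L, time in days and the weight-normalized dose `D` in mg/kg
(the `I` term captures the dose-dependent shrinkage of gefitinib's apparent
volume; `I = 0` for erlotinib). Multi-dose profiles are superpositions of
closed-form Bateman terms, cross-checked against direct ODE integration.

**Base TGI.** Proliferating cells `S` follow a smooth exponential-to-linear
growth switch and are killed in proportion to plasma exposure, passing through
three transit compartments before leaving the tumor:

    dS/dt  = 2·λ0·λ1·S / (2·λ0·S + λ1) − k2·Cp·S
    dT1/dt = k2·Cp·S − k1·T1,   dT2/dt = k1·(T1−T2),   dT3/dt = k1·(T2−T3)
    TV     = S + T1 + T2 + T3

**Acquired resistance.** Terminally damaged cells convert to a resistant pool
`R` at rate `kSR`; resistant cells grow with the same law scaled by `β`
(λ0R = β·λ0, λ1R = β·λ1), and `TV = S + T1 + T2 + T3 + R`. For simulation
studies only, a threshold drug effect on resistant cells (DER) can be enabled:
resistant cells are killed when `Cp` exceeds a threshold `C_th` (1 µM free
erlotinib ≈ 7153 µg/L total plasma after correcting for 5.5% unbound).

Two secondary quantities recur throughout: the mean transit time
`τ = 3/k1` (≈ 1.97 d at the canonical `k1 = 1.52 /d`) — the average time for a
damaged cell to die or convert — and the resistant fraction `R/TV`.

**Estimation.** Maximum likelihood with a proportional residual error for PK
and a combined (additive + proportional) error for tumor volumes, fit
sequentially (individual PK fixed before the PD fit). Naive-pooled and
two-stage estimators are provided; models are discriminated by AIC
(`2k − 2·logL`, counting structural fixed effects: 5 for the base model, 7 for
the resistance model in the two-compound configuration), with categorical
high-dose covariates testable by likelihood ratio.

**Synthetic studies.** A generator emulates the xenograft study the models
were developed on: 7 arms (vehicle; each drug at 5/25/100 mg/kg) × 8 mice,
14 once-daily doses from day 3, caliper volumes over 30 days with a 5 mm³
detection limit, sparse PK sampling, log-normal inter-individual variability,
and ~7% missingness from sacrifice and below-limit observations — with a
ground-truth sidecar for recovery tests.

**Regimen studies.** Paired virtual-population comparisons (same subject draws
in both arms) of continuous versus pulsed schedules, summarized by minimal
tumor volume, time to progression, and tumor burden (AUCE) with confidence
intervals of the mean, plus a hybrid simulation driving the mouse-estimated
tumor model with human PK for relative regimen comparison.

## Worked example

```python
import numpy as np
import resistpkpd as rp

print(f"transit time tau = {rp.tau(1.52):.2f} d")
cth = rp.threshold_concentration(1.0, 393.4, 0.055)
print(f"resistant-kill threshold C_th = {cth:.0f} ug/L")

# 100 mg/kg erlotinib on days 3-8 and 14-16, canonical high-dose parameters
grid = np.linspace(0, 30, 601)
regimen = rp.DosingRegimen(tuple((float(d), 100.0)
                                 for d in (3, 4, 5, 6, 7, 8, 14, 15, 16)),
                           "erlotinib")
profile = rp.solve_pk(rp.params.ERLOTINIB_PK, regimen, grid)
params = rp.params.resistance_parameters()
traj = rp.simulate(params, profile, grid)
frac = rp.resistant_fraction(traj)
for day in (3, 9, 14, 17, 30):
    i = np.searchsorted(grid, day)
    print(f"day {day:2d}: TV = {traj.TV[i]:7.1f} mm3   "
          f"resistant fraction = {frac[i]:.3f}")
```

prints

```
transit time tau = 1.97 d
resistant-kill threshold C_th = 7153 ug/L
day  3: TV =   173.9 mm3   resistant fraction = 0.000
day  9: TV =    30.4 mm3   resistant fraction = 0.028
day 14: TV =    57.1 mm3   resistant fraction = 0.094
day 17: TV =    52.4 mm3   resistant fraction = 0.289
day 30: TV =   500.6 mm3   resistant fraction = 0.460
```

Reading it: the first treatment cycle collapses the tumor (174 → 30 mm³) while
the resistant pool is still negligible; during the second cycle total volume
barely moves because the kill on sensitive cells is offset by the growing
resistant population (fraction 9% → 29%); after treatment ends the tumor
regrows, now nearly half resistant.

The same pipeline is scriptable from a shell:

```bash
resistpkpd --task generate --seed 1 --out runs/study
resistpkpd --task compare-models --dataset runs/study/observations.csv --out runs/cmp
```

which fits both nested models to the generated study and reports the
AIC-preferred one (`runs/cmp/comparison.txt`), with every run reproducible
from its `manifest.json` (config hash + seed).

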