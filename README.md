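# ogttfit

A delay-differential glucose–insulin model for the 5-point oral glucose
tolerance test (OGTT), with patient-wise parameter identification.

## The problem

A routine 75-g OGTT yields five glycemia and five insulinemia measurements
(0, 30, 60, 90, 120 min).  Threshold-based normality criteria lump
radically different glucose–insulin control behaviors — single-peak,
double-peak, hypoglycemic-dip and near-flat profiles — under one "normal"
label.  `ogttfit` fits a mechanistic model to those ten numbers so that
each patient is characterized by physiological rate constants (gastric
emptying, intestinal absorption and transit, hepatic production, insulin
sensitivity, pancreatic secretion) instead of thresholds.  It is written
for modelers and methods researchers; because clinical OGTT cohorts are
rarely public, the package ships a virtual-patient generator with known
ground truth so every stage is testable end-to-end.

## The model

Five states — stomach *S*, jejunum *J*, ileum *L* (mg), glycemia *G*
(mg/dL), insulinemia *I* (μU/mL):

    dS/dt = −k_js·S                               S(0) = D = 75 g
    dJ/dt = k_js·S − (k_gj + k_jl)·J              J(0) = 0
    dL/dt = k_jl·J(t−τ) − k_gl·L                  L(0) = 0
    dG/dt = −(k_xg + k_xgi·I)·G + G_prod + η·(k_gj·J + k_gl·L)
    dI/dt = k_xi·I_b·[(β^γ+1)/(β^γ·(G_b/G̃)^γ+1) − I/I_b]

with saturable hepatic production
G_prod = k_λ/(k_λ/G_prod0 + (G−G_b)), basal anchor
G_prod0 = (k_xg + k_xgi·I_b)·G_b, and incretin-corrected apparent glycemia
G̃ = G + f_gj·(k_gj·J + k_gl·L).  The ileum sees jejunal glucose delayed by
the transit time τ — a delay differential system whose delayed forcing is
nevertheless exact, because the gastric chain has closed forms.  The basal
anchor leaves exactly 13 free parameters and makes k_xgi the Bergman
insulin-sensitivity index S_I.

Identification minimizes a multi-component functional: range-normalized
MSE on the ten points, a smoothness term against a spline/quadratic
interpolant, an elliptical error-bar term (±3 min, ±5%) that matches
measurements within experimental uncertainty rather than exactly, and a
local regularization toward the patient's profile group — all constrained
by an *information function* that requires the simulated curve to realize
every extremum certified by sign changes in the measured data.  See
`docs/methods.md` for the full account.

## Worked example

```python
from ogttfit import OGTTModel, OGTTRecord

rec = OGTTRecord("patient_007", [0, 30, 60, 90, 120],
                 [88.0, 145.0, 118.0, 104.0, 96.0],   # glycemia, mg/dL
                 [7.0, 48.0, 42.0, 24.0, 13.0])       # insulinemia, uU/mL
res = OGTTModel(rec, explore_budget=5000).fit(seed=1, n_restarts=3)
print(res.summary())
```

```
OGTT delay-differential model fit
==========================================================
patient:          patient_007
basal G, I:       88.0 mg/dL, 7.0 uU/mL
profile group:    1
converged:        True
total cost:       2.1502e-03
  J_exp=1.953e-04  J_spline=3.611e-02  J_error=0.000e+00
information fn:   feasible
insulin sens. S_I: 2.652e-03 1/(min*uU/mL)
----------------------------------------------------------
parameter     estimate     ci 2.5%    ci 97.5%
k_js           0.09202     0.02997     0.09202
k_gj          0.008844    0.008844     0.05085
k_jl           0.04799     0.04799     0.09802
k_gl           0.03095     0.03095     0.08319
tau              2.399       2.399       112.4
k_xg           0.02204     0.02204     0.04046
k_xgi         0.002652   0.0002868    0.002652
eta            0.01934    0.009437     0.01934
k_lambda         43.72       43.72         383
k_xi           0.09867     0.05215     0.09867
beta             8.385        3.79       9.919
gamma            2.145       2.145       3.596
f_gj            0.0995     0.02487      0.1617
==========================================================
```

Reading the output: the fitted curve passes through the measured points
(`J_exp ≈ 2e-4` on a range-normalized scale) and inside every ±3 min / ±5%
error ellipse (`J_error = 0`); the simulated trajectory realizes the
glucose and insulin extrema the data certify (information function
feasible).  The patient's insulin sensitivity is the fitted `k_xgi`,
here S_I ≈ 2.7e-3 (min·μU/mL)⁻¹.  The 95% columns are empirical intervals
across restarts: tight for well-determined parameters, and deliberately
wide where ten data points cannot pin a parameter down (here τ — this
patient's ileal pathway barely contributes, so the transit delay is
unidentifiable and the interval says so).  `res.volcano("k_xgi")` and
`res.plot()` give the sensitivity profile and the fitted curves;
`ogttfit run --config cfg.yaml` chains the full pipeline
(synthesize → explore → cluster → fit → diagnose) from the shell.

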