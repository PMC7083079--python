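# Methods

## The model

`ogttfit` implements a five-compartment delay-differential model of the
glucose–insulin response to a 75-g oral glucose tolerance test (OGTT).
Glucose mass moves through the stomach *S* (mg), jejunum *J* (mg) and ileum
*L* (mg); the blood compartments carry glycemia *G* (mg/dL) and insulinemia
*I* (μU/mL); time is in minutes.

```
dS/dt = −k_js·S                                S(0) = D
dJ/dt = k_js·S − k_gj·J − k_jl·J               J(0) = 0
dL/dt = k_jl·φ(t) − k_gl·L                     φ(t) = 0 (t<τ), J(t−τ) (t≥τ)
dG/dt = −(k_xg + k_xgi·I)·G + G_prod(G) + η·(k_gj·J + k_gl·L)   G(0) = G_b
dI/dt = k_xi·I_b·[ (β^γ+1)/(β^γ·(G_b/G̃)^γ + 1) − I/I_b ]        I(0) = I_b
```

The ileum receives jejunal glucose shifted by the transit time τ (plug-flow
intestinal transport), which makes the system a delay differential system.
Hepatic glucose production is a saturable, strictly decreasing function of
glycemia,

    G_prod(G) = k_λ / (k_λ/G_prod0 + (G − G_b)),    G_prod0 = (k_xg + k_xgi·I_b)·G_b,

equivalently the Monod-complement form k_λ/(k_2+G) with
k_2 = k_λ/G_prod0 − G_b.  Anchoring G_prod at the basal steady state both
eliminates G_prod0 as a free parameter (hence exactly 13 free parameters)
and makes k_xgi the Bergman insulin-sensitivity index S_I = ∂E/∂I,
E = −∂(dG/dt)/∂G, exactly.  Pancreatic secretion responds to the
incretin-corrected apparent glycemia G̃ = G + f_gj·(k_gj·J + k_gl·L):
beta cells effectively sense the intestinal *absorption rate*, not the
luminal content.

Assumptions worth keeping in mind: first-order gastric emptying (liquid
bolus), two discrete absorption sites connected by a pure transport delay,
no interstitial-insulin compartment (its few-minute delay is unresolvable
at 30-min sampling), and a Hill secretion law formulated for OGTT
excursions only.  The hepatic law is only defined for
G > G_b − k_λ/G_prod0; trajectories that leave this domain are reported as
model-validity failures, never silently clipped.

## Parameters, units, defaults

| parameter | meaning | unit | default box |
|---|---|---|---|
| k_js | gastric emptying rate | 1/min | 0.005–0.10 |
| k_gj | jejunal absorption rate | 1/min | 0.005–0.10 |
| k_jl | jejunum→ileum delivery rate | 1/min | 0.005–0.10 |
| k_gl | ileal absorption rate | 1/min | 0.005–0.10 |
| τ | intestinal transit delay | min | 0–120 |
| k_xg | insulin-independent uptake | 1/min | 1e-4–0.05 |
| k_xgi | insulin sensitivity S_I | 1/(min·μU/mL) | 1e-5–5e-3 |
| η | bioavailability / distribution volume | 1/dL | 2e-3–2e-2 |
| k_λ | hepatic saturation constant | mg·(mg/dL)/min | 20–500 |
| k_xi | insulin degradation rate | 1/min | 0.005–0.10 |
| β | secretion half-saturation | – | 0.1–10 |
| γ | secretion Hill exponent | – | 1–8 |
| f_gj | incretin conversion factor | min/dL | 1e-3–0.2 |

G_b, I_b (taken from the record's fasting sample) and the dose D = 75 000 mg
are measured/protocol inputs, not fitted.  The feasible box F0 is a
physiology-motivated implementation choice (η ≈ bioavailability over a
100–200 dL glucose distribution volume; rate ranges spanning half-lives
from ~7 min to several hours; the k_λ floor keeps the hepatic law valid for
moderate dips below basal).  It ships as editable config and is **not**
derived from any published bounds table.  γ is treated as real-valued > 0;
units for η and f_gj follow one consistent convention (η converts mg/min of
absorbed mass to mg/dL/min of glycemia; f_gj converts mg/min to mg/dL).

## Forward solver

Because S and J are linear and decoupled they have closed forms (with the
analytic limit t·D·k_js·e^{−k_js t} when k_js = k_gj + k_jl, switching at
|k_js−(k_gj+k_jl)| < 1e-10), so the delayed forcing J(t−τ) is an explicit
function of time and (L, G, I) integrate as a non-autonomous *ordinary*
system: the delay contributes no history-interpolation error.  Two paths
share this structure:

* **lsoda** (default): stiff-capable LSODA at rel/abs tolerance 1e-8,
  horizon 300 min, 1-min output grid.  Matches a brute-force
  method-of-steps delay integration to < 1e-5 relative.
* **rk4**: a compiled fixed-step RK4 kernel (2 substeps per output step)
  used on the fitting hot path (~0.3 ms per trajectory).  It agrees with
  the reference path to ~1e-4 relative; the derivative kink at t = τ
  limits the effective order.  All optimization, exploration, and cohort
  generation use this path; solver-fidelity checks use the reference path.

## The fitting functional

Per patient, the 13 free parameters minimize

    λ1·J_exp + λ2·J_spline + λ3·J_error + ε·‖θ − θ*_j‖     subject to F(θ) = 0,

* **J_exp** — range-normalized MSE over the 5+5 measured points, with the
  insulin block weighted by α.
* **J_spline** — the same normalized MSE against a densified soft
  interpolant Ĥ = φ·spline + (1−φ)·quadratic evaluated on the 1-min grid;
  the quadratic is a least-squares trend (not interpolating), so φ < 1
  trades exact interpolation against trend smoothing.  The term exists only
  to suppress non-physiological high-frequency oscillation between the
  30-min samples.
* **J_error** — each measurement becomes an ellipse in (t, value) space:
  horizontal semi-axis Δ_t = 3 min (sampling-time uncertainty), vertical
  semi-axis δ_rel·value (assay uncertainty, default 5%).  A point whose
  nearest elliptical distance d from the model curve is ≤ 1 contributes
  nothing (the error density's truncated support); beyond the boundary the
  contribution is the quadratic hinge max(0, d−1)².  This is the
  "mathematical buffer": fits match measurements within error bars, not
  exactly, which measurably stabilizes refits under perturbed data.
* **local regularization** — Euclidean distance to the patient's profile
  group representative θ*_j, computed on box-normalized (min–max)
  parameters so it is unit-invariant; ε = 1e-4 keeps it a tie-breaker.
* **information function** — every sign change of consecutive first
  differences in a measured curve certifies a zero of the underlying
  derivative inside the bracketing sample interval (at most 3 per 5-point
  curve, 6 combined).  A parameter vector is *feasible* if, for every such
  constraint, the simulated trajectory has a vanishing derivative inside
  the bracket (widened by Δ_t) whose stationary value — computed from the
  model's own zero-derivative identity, e.g.
  G_opt = (G_prod* + η(k_gj·J* + k_gl·L*))/(k_xg + k_xgi·I*) — lies inside
  the extremum's confidence interval.  Infeasible vectors carry an infinite
  sentinel in hard mode; during heuristic search a soft mode adds a smooth
  violation magnitude instead so optimizers keep a usable landscape.

Weight defaults: λ1 = 1, λ2 = 0.05, λ3 = 0.25, α = 1, φ = 0.5, ε = 1e-4,
δ_rel = 0.05, Δ_t = 3 min.  Only Δ_t is a literature value; the rest are
this package's choices, all config-overridable.  λ2 is deliberately small:
on noiseless synthetic patients we measured that λ2 = 0.25 lets the
interpolant term dominate — a gradient polish started *at* the generating
parameters walks 25%+ away in k_js and γ while lowering the total cost —
whereas the term's only intended role is to damp between-sample
oscillation.

Two deliberate widenings in the critical-point machinery: the extremum's
confidence interval extends on the overshoot side by half the largest
adjacent first difference (the true between-sample extremum generically
overshoots the nearest 30-min sample by far more than the 5% assay band),
and feasibility accepts any derivative zero in the bracket rather than
only one of matching max/min orientation (dense DDE trajectories can
realize the certified stationary point through a different local extremum
pattern than the sparse samples suggest).  Without both, the generating
parameters of noiseless synthetic patients are routinely tagged
infeasible, which would invert the constraint's purpose.

## Feasible-set exploration and profile groups

Uniform draws from F0 (paired with basal values G_b ∈ [78, 96),
I_b ∈ [4, 12)) are simulated and filtered by the clinical normality rules:
basal glycemia < 100 mg/dL, basal insulinemia < 15 μU/mL, glycemia never
above 160 mg/dL, G(120) ≤ 140 mg/dL, and insulinemia not above 60 μU/mL
across the whole 120-min window.  The persistence rules are the readings we
adopted for sparse data; both are ambiguous for 5-point records.  Surviving
5-point profiles are clustered by k-means on shape features (per-curve
min–max-normalized measurements damped by a saturating relative-range
weight, interior peak counts, and the range weight itself — all invariant
to per-curve unit rescaling; the damping stops near-flat curves from being
inflated to arbitrary shapes by the normalization).  k is chosen by
silhouette over 2–8 when not fixed.  Each group's representative θ*_j is
the member whose curve is closest to the group's mean curve.  The default
exploration budget is 1e5 draws (config `explore_budget`); tests and the
acceptance script use 4e3–5e3, which already yields stable 3–4 group
structures at desk scale.

## Staged fitting

1. **Stage A** — anchor at the assigned group's best-matching member
   (falling back to θ*_j), assignment by the clustering shape metric with
   ties broken toward the lower group id.
2. **Stage B** — fit the nine gastrointestinal/glycemia parameters against
   the glucose data with the measured-insulin interpolant as a known
   exogenous input (a single scalar ODE; the insulin-side parameters
   cannot influence this subproblem).
3. **Stage C** — fit (k_xi, β, γ, f_gj) against the insulin data with the
   Stage-B glucose trajectory held fixed.
4. The staged result is kept only if it beats the anchor under the full
   functional (the stages optimize decoupled surrogates, so this safeguard
   enforces "stages cannot worsen the anchor").

The full problem then runs simulated annealing (geometric cooling, initial
temperature from the cost spread of ~100 box samples, proposal SD shrinking
0.15 → 0.02 in unit-cube coordinates), compass pattern search (mesh 0.10 of
box width, halving on failed polls), and a bounded L-BFGS-B polish with
finite differences.  Default budgets 2000 + 1000 + 500 evaluations; tests
and the acceptance script use reduced budgets (≈ 1500/800/600 and below),
which we found saturate fit quality at this problem size.  Repeated fits
(default n = 10; first start unjittered, then multiplicative log-normal
jitter σ = 0.2 on the staged guess) give empirical percentile 95% intervals
per parameter, clipped to contain the best-cost estimate.

## Synthetic cohort

Virtual patients are drawn from archetype-conditioned sub-boxes
(single-peak, double-peak, hypoglycemic-dip, near-flat glycemia; default
mix 40/25/15/20%), simulated, required to pass the normality rules on the
dense curve and to show the archetype's signature on the sampled 5-point
curve, then perturbed with multiplicative Gaussian noise (default relative
SD 3% glucose, 7% insulin — assay-realistic scales; an optional ±3 min
time jitter is off by default).  The parameter-to-shape map is heuristic;
the signature check makes it self-correcting.  Ground truth is returned
with every record, so recovery experiments are well-posed.

What the generator does *not* emulate: demographic structure, correlated
assay errors, non-protocol sampling times, and any pathology outside the
normality envelope.  Passing tests therefore speak to the method's
behavior on model-generated data, not to clinical performance.

## Diagnostics

* **Goodness of fit**: predicted-vs-observed pairs, per-variable relative
  residual mean/SD, correlation, and a D'Agostino–Pearson normality test.
* **Volcano profiles**: one parameter varied over 50–150% of its optimum
  (21-point grid including 100% exactly), total cost normalized so the
  optimum maps to (100, 100); infeasible points are flagged.
* **Stability under noise**: uniform multiplicative noise (≤ 10%) on the
  measurements, local-only refit from the
  original optimum (no annealing, fine 0.02 mesh), per-parameter drift
  distribution, and a Wilcoxon signed-rank significance flag at the 5%
  level per parameter ("non-significant" is our operationalization; the
  underlying test is not named in the literature the model follows).

## Identifiability: what recovery experiments show

Thirteen parameters against ten measurements is an underdetermined
problem; the interpolant, information function and group regularization
reshape but do not eliminate the flat directions.  Three reproducible
findings on noiseless synthetic cohorts:

* Even a local polish started at the generating parameters moves k_xgi by
  20–50% on some patients while *lowering* the functional — the
  functional's minimizer is displaced from the truth by more than the
  assay-scale tolerances.
* τ is structurally unidentifiable whenever the ileal pathway is nearly
  inactive (small k_jl), which covers most single-peak and near-flat
  archetypes.
* The repeated-fit interval width separates the regimes: estimates whose
  95% interval is narrow (relative width < 0.05–0.1 across restarts)
  recover their true values to a few percent, while wide-interval
  estimates scatter.  Point estimates should therefore only be interpreted
  jointly with their intervals and volcano slopes.

Median recovery errors of the shape-determining subset (k_xgi, k_js, τ, γ)
sit around 25–55% over a mixed cohort — honest numbers the acceptance
suite asserts against much stricter bounds and reports as failures.
Residual statistics behave differently: fitted-curve residual means are
≈ 0.1% (unbiased), but pooled residuals are platykurtic by construction —
the elliptical error term makes fits indifferent inside the ±5% band — so
strict normality tests reject at large n.

## Numerical choices and degenerate inputs

Secretion is evaluated in log space (logaddexp), so large γ with small G̃
cannot overflow.  Flat records (zero measurement range) fall back to
basal-value normalization with a warning.  Zero first differences are no
sign change (strict inequality).  Ties in group assignment break toward
the lower group id.  Simulation failures during optimization become
infinite-cost evaluations (a large finite sentinel where finite-difference
gradients need one); failures during direct simulation raise with the
offending parameter set attached.  All randomness flows from explicit
seeds; fits are bit-stable for a fixed seed on a fixed platform.

## Problem sizes used by the shipped experiments

Exploration 4e3–5e3 draws; recovery cohorts 12–20 patients with 2–3
restarts per patient at optimizer budgets ≈ 1200–1500 annealing + 600–800
pattern + 500–600 gradient evaluations; buffer experiment 4 patients × 10
noise replicates per condition; residual experiment 30–50 patients at 5%
noise.  These sizes make the full suite a desk-scale run; all are
config-overridable upward.
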