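# Methods

This note records the model structure, parameter provenance inside the
package, unit conventions, numerical choices, and known limitations of
`fexupk`.

## 1. Model structure

### 1.1 Compartments and flows

The body is represented by 13 circulatory compartments: 11 perfused
tissues (adipose, adrenal gland, brain, heart, kidney, large intestine,
liver, lung, small intestine, spleen, stomach) plus venous and arterial
blood pools, with a first-order absorption depot feeding the liver. All
tissue distribution is perfusion-limited: tissue T takes up drug from
arterial blood at its blood flow Q_T and returns it at the emergent
venous concentration C_T·R/Kp_T, where R is the blood-to-plasma ratio
and Kp_T the tissue-to-plasma partition coefficient.

Topology:

- **Systemic tissues** (adipose, adrenal gland, brain, heart, kidney)
  drain directly into the venous pool.
- **Portal tissues** (stomach, spleen, small intestine, large intestine)
  drain into the liver; the liver also receives a hepatic arterial flow
  equal to its total flow minus the portal inflows, and drains into the
  venous pool.
- The **lung** carries the entire cardiac output in series between the
  venous and arterial pools.
- The **residual flow** Q_RE = Q_CO − Σ Q_T(systemic) − Q_LI is a pure
  arterial→venous shunt with no tissue mass (1877.4 mL/min at defaults).

State is carried as drug **amounts** (ng); every term is linear in the
state, so the system is x′ = A·x with a constant 16×16 matrix (14
physical states plus two bookkeeping integrals: cumulative hepatic
elimination and cumulative depot→liver transfer).

### 1.2 Absorption

Oral doses enter the depot as Fa·Fg·dose (Fg = 1 by default) and
transfer to the liver at the first-order rate Ka. Ka is predicted from
Caco-2 permeability: Peff(10⁻⁴ cm/s) = 10^(0.4926·log10(Papp,nm/s) −
0.1454), Ka = 2·Peff/r with r = 1.75 cm; Papp = 165 nm/s gives
Ka = 0.060684 min⁻¹. Intravenous doses are bolus additions to the
venous pool.

### 1.3 Elimination

Elimination is hepatic only, at rate CLu,int·fup·C_LI/Kp_LI with

CLu,int = Σ_pathways Vmax/(Km·fu,mic) + CLu,add = 15 905.3 mL/min.

Vmax/Km in (nmol/min)/(µM) is a clearance in mL/min because µM ≡
nmol/mL. The pathway fractions at the default parameters are M14
18.55%, M11 0.349%, residual CLu,add 81.10%. The well-stirred liver
closed form on a blood-flow basis,

Fh = Q_LI·R / (Q_LI·R + fup·CLu,int) = 0.5084, ER = 0.4916,

gives F = Fa·Fg·Fh = 0.3869 at Fa = 0.761 and is used both as an
analytic cross-check of the ODE model and for the extraction correction
of the liver Kp.

### 1.4 Distribution parameters

Rat steady-state Kp values are scaled to human by a single Kp scalar;
the liver (eliminating organ) is further corrected by 1/(1 − ER):
Kp_LI = 417 × 0.371 / (1 − 0.4916) = 304.3. The scalar that makes the
Øie–Tozer composition

V_SS = Vp + Vrbc·EP + Σ V_T·Kp, EP = 1 + (R − 1)/Hct

meet the allometric target of 7.48 L/kg × 70 kg is s = 0.3392 (closed
form); the bundled authoritative scalar is 0.371 and the bundled human
Kp table is the model input (the scaling chain reproduces it, see
section 5). Allometry is an unweighted ordinary least-squares fit in log–log
space on rat (0.25 kg, 5.05 L), monkey (4 kg, 36.68 L), and dog (10 kg,
126 L): a = 15.049 L, b = 0.83557.

### 1.5 IVIVE

Recombinant CYP3A4 Vmax (pmol/min/pmol CYP) is scaled to the whole
liver with ISEF × abundance (79 pmol/mg) × MPPGL (39.79 mg/g) × liver
mass; ISEF = 6100/(200 × 79) = 0.386, rounded to 0.4 for use.

## 2. Units

Internal units are mL, mL/min, min, ng, and ng/mL throughout; doses in
mg are converted at 1 mg = 10⁶ ng. Reported plasma concentration is
venous blood concentration divided by R: C_p = X_ven/(V_ven·R). AUC is
reported in ng·min/mL.

## 3. Numerics

- **Integrator.** Fixed-step classic RK4. For a linear system this is
  identical to multiplying by Φ = I + B + B²/2 + B³/6 + B⁴/24 with
  B = A·dt, so the engine precomputes Φ once and advances by
  matrix–vector products; `rhs`/`rk4_step` expose the conventional
  formulation and the two are cross-checked in the tests.
- **Step size.** dt = 0.5 min by default. The fastest pool turnover is
  arterial blood (Q_CO/V_art ≈ 3 min⁻¹); explicit RK4 is unstable for
  this system at dt = 1 min, while dt = 0.5 min is stable with
  half-step convergence error < 0.1% of Cmax. A convergence check
  (`convergence_check`) that compares dt against dt/2 is part of the
  public API and of the test suite.
- **Dose events** are snapped to the nearest grid step (displacement at
  most dt/2). Negative undershoot beyond 10⁻⁹ of the dose triggers a
  warning; tiny undershoot is clipped to zero.
- **Fast evaluation.** `plasma_at_times` advances between breakpoints
  with cached powers of Φ; the fitting objective additionally exploits
  linearity in the dose (Fa is a pure multiplier on the unit-Fa curve,
  cached per candidate clearance), making a per-subject fit ≈ 0.1 s.
- **AUC quadrature.** Linear trapezoid. For IV bolus curves the venous
  mixing spike (time scale V_ven/Q_CO ≈ 0.7 min) dominates the
  quadrature error: the PO/IV AUC ratio deviates from the analytic
  well-stirred limit by 0.63% at dt = 0.5, 0.15% at 0.25, 0.04% at
  0.125 (second-order convergence).

## 4. Estimation, pooling, and validation

Per-subject (Fa, CLu,add) are estimated by bounded least squares
(uniform weights by default; 1/ŷ and 1/ŷ² available) with Ka fixed at
its permeability-predicted value; Nelder–Mead from 3 deterministic
starts, bounds Fa ∈ (0, 3], CLu,add ∈ [0, 100 L/min]. Fitted Fa above 1
is treated as an apparent fraction and flagged with a warning, not an
error. Dose groups are compared by one-way ANOVA per parameter; pooling
of the grand means is recommended iff p ≥ 0.05 for both parameters. The
degenerate zero-variance ANOVA case is resolved by its limit (equal
means → F = 0, p = 1; unequal → F = ∞, p = 0).

The validation table simulates each bundled clinical scenario (20/40/80
mg once daily; day-1, day-7, 48-h and 8th-dose windows) with pooled
parameters and reports prediction/observation ratios with a two-fold
acceptance flag. All ten bundled scenarios are within two-fold
(ratios 0.67–1.36).

### Synthetic cohorts

`generate_cohort` draws per-subject Fa and CLu,add from lognormal
distributions parameterised by mean and CV (σ² = ln(1 + CV²),
µ = ln m − σ²/2, so the arithmetic mean is preserved), simulates each
subject, applies proportional + additive Gaussian residual error, and
censors observations below the LLOQ (dropped). Everything is driven by
one `numpy.random.default_rng(seed)`; identical specs ⇒ identical
cohorts. The generator covers study-design emulation only — it is not a
population-PK model (no covariates, no parameter correlation, no
between-occasion variability).

## 5. Design decisions

- The middle (unscaled hepatic uptake) term of the intrinsic-clearance
  assembly is fixed at zero: CLu,int is the two measured pathways plus
  CLu,add, which reproduces both the reference bioavailability and the
  reference liver Kp.
- The bundled human Kp table (including small intestine 124) is the
  authoritative model input; the rat-scaling chain is provided to
  reproduce it, not to override it. The chain reproduces all bundled
  values within 1% except the small intestine, where the chain gives
  236 — the bundled 124 is kept (documented discrepancy).
- Kp scalar: the closed-form solution against the allometric target is
  0.339; the bundled reference scalar 0.371 is used for the derived Kp
  table. Both are exposed.
- Reported "concentration" is plasma (C_ven/R); the vascular pools
  internally carry blood amounts.
- The moment-based V_SS from a simulated IV bolus **underestimates**
  the compositional V_blood·R + Σ V_T·Kp by design of the model, not by
  numerical error: elimination is hepatic and the liver holds ≈ 70% of
  the distribution volume (V_LI·Kp_LI ≈ 545 L of 781 L), so drug
  cleared in the liver never re-enters plasma and the plasma MRT misses
  most of its residence time. The exact ratio at default parameters,
  computed from the matrix moments AUC = −A⁻¹x₀ and AUMC = A⁻²x₀, is
  0.404 — a documented, analytically verified bias of ≈ 60%, far larger
  than the "slight" bias sometimes assumed for non-central elimination.
  The test suite checks the moment estimate against the exact matrix
  moments (2%) rather than against the composition.
- ANOVA is reported without a post-hoc test; pooling needs only the
  omnibus p-values.

## 6. Limitations

- Linear kinetics only (Michaelis–Menten saturation is not modelled;
  Vmax/Km is used as a constant clearance), consistent with the
  dose-proportional exposure range covered.
- Absorption is a single first-order depot: no gastric emptying,
  intestinal transit, dissolution, or gut-wall metabolism (Fg = 1).
- Elimination is hepatic only; renal clearance is not represented.
- No pharmacodynamics, no drug–drug interaction simulation, no
  metabolite disposition.
- Fitted parameters are per-subject least squares, not mixed-effects
  population estimates.
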