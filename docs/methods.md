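# Methods

## Scope and state

The simulator advances a mono- or bi-specific even-aged stand one year at a
time.  The whole state per species is (N, Dg, SI): stem count per hectare
(kept continuous — expected values, rounded only in reports), over-bark mean
quadratic diameter in cm, and the site index.  Basal area is always derived
as N·π·Dg²/40000 and never stored separately, so the N/Dg/BA triplet cannot
drift apart.  Spatial structure, age structure beyond even-agedness, and
disturbance mortality (storm, drought, insects) are outside the model: the
only mortality is competition at the self-thinning boundary.

## Growth

The five-year under-bark basal-area increment of species *i* is
SIᵢ·f₂,ᵢ(DI)·f₃,ᵢ(Dgᵢ), in m²·ha⁻¹ per 5 years.

* **Site index.** SIᵢ = a₀ + Σ aₘXₘ over a species-specific set of
  environmental variables (30-year monthly temperatures and water-budget
  terms in °C/mm, soil water holding capacity in mm, bio-indicated pH and
  C/N, 0/1 soil and ecological-region indicators, 0–10 stoniness scores,
  slope in %).  The vocabulary of variable names is documented in
  `src/salem/data/growth_site_terms.csv`; squared terms (pH², C/N²) are
  derived from the base variable at evaluation time.  Users who know their
  site index (the usual case in scenario work) supply it directly.  A
  non-positive SI is clamped to zero growth with a warning rather than
  allowed to shrink the stand.
* **Density response.** f₂ = DIᵇ for ten species; for fir and Douglas fir a
  hyperbolic form (1+b)·DI/(b+DI).  Both pass through 0 at DI = 0 and 1 at
  DI = 1.  DI is Reineke-type: N/N_max with log N_max = p + q·log Dg, and in
  mixture the total DI is the sum of the species' partial indices.  DI is
  computed from over-bark quantities, matching the inventory data the
  boundary was fitted on.
* **Stage response.** f₃ = (e^{c₁Dg} + c₂)/(1+c₂), equal to 1 at Dg = 0 and
  tending to c₂/(1+c₂).
* **Mixture.** Species *i* mixed with *j* receives
  BAIᵢ(DI_total, Dgᵢ)·xᵢ·(1+uᵢⱼ) where xᵢ = DIᵢ/DI_total (density terms, not
  basal-area terms) and uᵢⱼ = s₀·(1−xᵢ) or (s₀+s₁·SIᵢ)·(1−xᵢ) when a
  site-productivity interaction was fitted.  Relations are directional; 26
  directed relations over 19 species pairs ship in `mixture.csv`, all other
  combinations are neutral (u = 0).  Every fitted s₁ is negative: mixture
  benefits shrink on richer sites.  The product is clamped at zero so an
  adverse mixture effect cannot produce negative growth.

**Time step.**  The fitted increment is a five-year quantity (its residual
standard deviation is reported in m²/ha/5yrs); the annual loop adds one fifth
of it per year, re-evaluating the responses yearly.  This is exposed as
`increment_period_years` (default 5) in the configuration.

**Bark.**  Growth operates on under-bark basal area; the state is over-bark.
Each step converts with the species' bark-proportion model evaluated at the
cohort's current Dg (the stand-level diameter summary; the model is per-tree
but the simulator never holds individual trees between years).  The
back-conversion reuses the pre-growth bark proportion, avoiding a circular
Dg↔BA dependency; at annual steps the error is second order.  Predictions
are clamped to the 10 cm–max-dbh calibration range, which also keeps the
proportion inside (0, 1) for every positive diameter.  The two *Quercus*
models and the undifferentiated oak data behind them serve all three oaks;
Aleppo pine borrows the Scots pine model (no bark data of its own, very
similar bark proportion).

## Mortality and thinning

Both removals act from below: the removed trees' squared mean diameter is
Kg·Dg² with Kg < 1, so survivors' Dg rises as
√((N·Dg² − r·Kg·Dg²)/(N − r)).  The removed basal area equals the standing
loss exactly, which is what makes the basal-area conservation check close to
float precision.

* **Mortality** fires at DI ≥ 1 with Kg = 0.68.  The total stems to kill are
  allocated to species by their stem-number proportion before mortality (the
  simplest reading of proportional allocation; basal-area shares would be the
  alternative) and the total is solved by dichotomy so the post-mortality DI
  is 1 within 1e-6.
* **Thinning** follows a prescription: prescribed DI rising linearly from an
  initial to a final value over the simulation horizon (read as linear; only
  a gradual increase is specified), symmetric trigger bounds (fire above
  prescribed+bounds, cut back to prescribed−bounds), a minimum number of
  years between thinnings, a removal Kg (default 0.95) and a target share of
  the first species.  In a two-species stand the per-species removals are
  solved so the post-thinning DI split matches the target share; when that
  would require adding trees to a species, that species is left untouched
  and the whole removal falls on the other one (logged as a warning).
  An optional target Dg ends the simulation once any species reaches it.
* **Solver.**  Both dichotomies solve over the number of stems removed,
  bracketing from zero by geometric expansion.  The DI response to removal
  is non-monotone in the extreme: for self-thinning slopes steeper than
  |q| = 2 the Dg inflation dominates as the removal fraction approaches 1
  and DI turns back upward.  The bracket expansion therefore stops at the
  first crossing, returning the smallest removal that achieves the target —
  the only silviculturally meaningful root.  Tolerance is 1e-6 on DI.

Within a year the order is growth → mortality → thinning.

## Downscaling

Deterministic, no sampling: per species, stems are spread over diameter
classes (default width 1 cm) under a normal density with mean
Dm = √(Dg² − σ²) and standard deviation σ = α(1−e^{−γDg})^β.  The window
spans Dm ± 4σ clipped at positive diameters and is *not* renormalised, so
class counts fall short of N by the (< 10⁻³) mass outside the window — the
mass-conservation tests budget for exactly that truncation.  Each class
centre gets a height h = 1.3 + (α + g₁(Dg) + g₂(SI))(1−e^{−β·c130^γ}) with
the species' fitted g₁/g₂ forms and c130 = π·dbh, then a commercial volume
v = β₁h/dbh + (β₂+β₃·dbh)·π·dbh²·h/40 in dm³ (β₂ the form factor, β₁ ≤ 0 the
non-commercial-top correction, dropped coefficients zero).  Classes below
the 7.5 cm commercial limit are extrapolated (with a warning when called
directly) and floored at zero volume in stand totals.  Downscaled diameters
are over-bark, the inventory measurement convention.

Harvested and killed volume is obtained the same way: each removal batch is
downscaled as a pseudo-stand of (n_removed, Dg_removed = √Kg·Dg), with the
pre-removal stand Dg (recovered exactly as Dg_removed/√Kg) as the stage
proxy for heights.  How the reference implementation aggregates harvested
volume is not documented; this choice keeps harvested and standing volume on
an identical footing.

## Scenarios and the demonstration

A scenario supplies per-species SI and Dg plus either explicit per-species
basal areas or a stand total and first-species share (in basal-area or
density-index terms), a horizon, and optionally a thinning block.  The
bundled demonstration is a spruce–beech stand, 2000–2090: spruce SI 65.4 /
beech SI 26.8, total over-bark BA 32 m²·ha⁻¹, Dg 17.5 / 12.2 cm, corridor
0.6 → 0.8 with bounds 0.05, ≥ 5 years between thinnings, Kg 0.95, target
spruce share 0.6.  The published description does not print the initial
species proportion explicitly; the target share of 0.6 is used for the
initial basal-area split as the natural reading.  The matched pure-stand
variants reuse the same site indices, initial dendrometric values (total BA
32) and thinning parameters.  A 90-year run takes well under a second on one
CPU, so all tests and the acceptance script run the scenarios in full.

## Parameter data

Every fitted estimate lives in a CSV under `src/salem/data/`, keyed by
species abbreviation, with the functional form recorded alongside; no
numeric estimate is embedded in code.  Two quirks are worth knowing: the
published mixture table prints the black pine / Scots pine relation as two
s₀ rows (1.419 and −0.017); the second is read as the site-index interaction
s₁ (a typesetting slip — every other interaction row is labelled s₁ and the
magnitude matches the fitted s₁ of comparable pairs).  And downy oak uses
the undistinguished *Quercus sp.* volume model, mirroring its treatment in
the volume dataset.

## What the tests do and do not show

The suite checks: every shipped value against a second, independently typed
transcription; the worked single-point examples of each model; structural
identities (f₂(1)=1, f₃(0)=1, u(x=1)=0, σ(0)=0, Dm(σ=0)=Dg); solver targets
on hundreds of randomised stands, with the mortality dichotomy cross-checked
against a brute-force grid search; exact basal-area bookkeeping along full
trajectories; and the end-to-end demonstration outcome (final beech
diameters pure vs mixed, and the production ordering pure spruce > mixture >
pure beech).  Random stands are drawn inside the species' inventory
calibration envelopes.  None of this validates the fitted models against
field data — predictions inherit the phenomenological models' validity
domain (French inventory conditions, past climate) and degrade outside it.

## Known limitations

* Two species at most; no uneven-aged structure.
* Growth is deterministic: the fitted residual variance models are shipped
  nowhere and no stochastic increment is simulated.
* Site-index helpers stop at the linear predictor: quantile positioning
  against inventory distributions requires inventory data and is out of
  scope.
* The climate drivers are static; climate-fluctuation responses are not
  modelled.
* Volume is the single commercial-bole equation — no assortments, no taper.
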