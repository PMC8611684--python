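# Methods

## Model

The package implements a two-parameter survival model for clonogenic assays.
Cell kill is treated as the superposition of first-order (rate γ·Ḋ·N) and
second-order (rate δ·Ḋ·N²) activation kinetics of death pathways; because the
dose rate multiplies both terms it cancels, leaving a logistic ordinary
differential equation in absorbed dose,

    dS/dD = −γS − κS²,  S(0) = 1,  κ = δN₀ = γ(1−n)/n,

with closed form S(D) = n/(e^{γD} − 1 + n) and n = γ/(γ + κ). The two
parameters are assumed dose-independent. Key consequences used throughout:

- initial slope −d lnS/dD|₀ = γ/n > 0 (no zero-slope defect at D = 0);
- exact exponential tail S ≈ n·e^{−γD} for γD ≫ 1 (relative deviation
  (n−1)e^{−γD}), the multi-target-model asymptote with γ = 1/D₀;
- RS(D) = γ/(1 + (n−1)e^{−γD}) increases with dose for n > 1 (shoulder),
  decreases for 0 < n < 1 (inverted shoulder);
- GRS = 1/∫₀^∞ S dD = γ(n−1)/(n ln n), continuously γ at n = 1.

The sign space of (γ, n) decomposes into six qualitative regimes
(`classify_regime`): second-order-dominated death (n < 0), second-order-only
(n = 0, where S = 1/(κD + 1)), inverted shoulder (0 < n < 1), pure
exponential (n = 1), shouldered death (n > 1, γ > 0) and net growth (n ≥ 1,
γ < 0, the only regimes with S > 1). All clinical-layer functions accept only
γ > 0, n > 0; the core survival function covers the full space and reports
the singular dose ln(1−n)/γ when a requested dose crosses the denominator's
sign change (possible only outside the clinical branch).

## Fractionated courses and clinical quantities

With complete sublethal-damage repair between fractions, an m × D Gy course
kills to S(D)^m. The derived quantities are exact algebra on that statement:
BED is the single dose with the same end-of-course survival; EQD2 the total
dose of the iso-effective 2 Gy course; TCP/NTCP the Poisson probability
exp(−N₀·S^m) that no clonogen (or tissue-forming unit) survives; D50 solves
TCP = 1/2, giving S(D50)^m = ln2/N₀ and D50 = ln(1 + n[(N₀/ln2)^{1/m} − 1])/γ;
BED50 = BED(m, D50); and the response steepness per unit total dose at the
midpoint is Γ50 = (ln2/2)·RS(D50) — the coefficient is kept as the exact
ln2/2 = 0.34657, since it follows from differentiating the Poisson form.
TD(80% tumour) and TD(20% normal tissue) are the standard linearisations
TD50 ± 0.3/Γ50. Iso-survival refractionation to i fractions uses
D_i = (1/γ)·ln(1 + n[S(D)^{−m/i} − 1]).

Each of these is covered by a defining-property test that does not reuse the
implementation's algebra: survival(BED) must equal the course survival,
TCP(D50) must be 1/2, Γ50 must match a central-difference slope of the TCP
curve, and refractionation must preserve course survival (all at 1e-6–1e-10
relative tolerance).

## Parameter estimation

The fit uses the parameterised logit transform: for data generated exactly by
the model with n > 1, y = ln[S/(A−S)] is affine in D precisely at
A = n/(n−1), with slope −γ and intercept γ₀ = ln(n−1), so n = A·e^{γ₀}.
`UMACurve` searches A by a 50-point log-spaced scan of the R² of the
transformed straight-line fit over A ∈ (max S, 100], refined by a bounded
scalar (golden-type) search between the best scan point's neighbours
(xatol 1e-10). Three branches are always evaluated and the best R² wins:

- positive ceiling (n > 1), transform ln[S/(A−S)], points with S ≥ A
  (possible only for S > 1 measurement noise) excluded and flagged;
- negative ceiling (0 < n < 1), transform ln[S/(S−A)], n = −A·e^{γ₀};
- the n = 1 boundary (plain regression of ln S on D), preferred whenever its
  R² is within `tie_tolerance` (default 1e-6) of the best interior fit —
  parsimony at a removable boundary.

**Weighting.** Survival errors are multiplicative, so the natural noise model
is homoscedastic on ln S; the transform then has per-point variance
amplification (dy/d ln S)² = (A/(A−S))², largest at low doses. The default
regression therefore uses the delta-method GLS weights w = ((A−S)/A)²
(`weighting="delta"`). Unweighted least squares (`"ols"`) and per-point
1/sd² weights propagated the same way (`"sd"`) are available; all three
coincide on noiseless data. R² is reported on the transformed (logit) scale
as 1 − SSres/SStot with the active weights.

**Outliers.** Points are flagged when their whitened logit residual
(r·√w) exceeds `outlier_threshold` (default 2.5) times the robust scale
1.4826·MAD. The MAD scale is used because a single gross outlier inflates
the RMS enough to mask itself. Flagging is suppressed when the RMS residual
is below 1e-6 on the logit scale — such fits are numerically exact and their
residual pattern is optimisation round-off, far below any experimental
error. Both the contaminated fit and the refit without flagged points are
always reported; nothing is silently dropped.

`LQCurve` provides the linear-quadratic contrast fit −lnS = αD + βD² with
zero intercept by linear least squares. On shoulder-type model data over
0–8 Gy it reaches R² ≥ 0.99 yet overshoots −lnS by well over 10% at 14 Gy —
the bending-curve discrepancy that motivates the straight-tailed model for
hypofractionation.

## Synthetic data

No public data tables exist for the underlying assays (the published curves
are redrawn from textbook figures), so the test surface is (a) the published
parameter sets — the five-line lung panel (γ from 0.33 to 0.90, n from 3.2
to 12) and the skin panel (three fibroblast strains with n = 2 and γ = 0.67,
1.08, 2.27; adipose-derived stem cells with γ = 0.90, n = 1.20) — and (b)
synthetic assays S_i = S(D_i)·e^{ε_i} with ε ~ N(0, σ²), σ = 0.05 by default
on the default 0–12 Gy unit-spaced grid; replicates are averaged on the log
scale and their spread fills the sd column. The generator reproduces exactly
under a fixed seed. It emulates multiplicative assay noise only: no
Poisson colony-counting statistics, no plating-efficiency drift, no
dose-delivery error, and no correlation between doses — parameter-recovery
results on it therefore bound estimator behaviour under idealised noise, not
under every failure mode of a real assay.

Recovery under these conditions (200 assays, σ = 0.05, 8 doses, generator
γ = 0.45, n = 4): median |Δγ|/γ ≈ 1.9%, median |Δn|/n ≈ 8%; errors shrink
monotonically as σ → 0 and noiseless data are recovered to ≤1e-4 in both
parameters with R² ≥ 1 − 1e-10.

## Numerical choices

- All expressions containing e^{γD} are evaluated in log space
  (`logaddexp`/`log1p`), so survival, BED, EQD2 and refractionation remain
  finite and accurate for γD of several hundred; e^{γD} is never
  materialised when it would overflow.
- n = 1 is an exact branch everywhere (S = e^{−γD}, GRS = γ, BED = mD), not
  an ε-perturbation of the removable singularities in n−1 and ln n.
- The ODE oracle integrates in log-survival (du/dD = −γ − κe^u) with DOP853
  at rtol 1e-12, which keeps *relative* accuracy where S underflows toward
  1e-20; it agrees with the closed form to better than 1e-8 across
  γ ∈ [0.1, 2.3], n ∈ [0.2, 60], D ∈ [0, 20] (the reported fitted range).
- The 50%-response formulas are implemented from their defining property
  TCP(D50) = 1/2 (the N₀/ln2 form), verified to 1e-10; BED50 additionally
  matches an independent bisection on survival(B) = ln2/N₀.
- Probabilities are carried as fractions internally; the table renderer
  rounds to one-decimal percentages and two-decimal doses for display while
  JSON output always retains full precision.
- Problem sizes in the test suite (grids of ≤ 41 doses, ≤ 200 synthetic
  assays, ≤ 100 random parameter draws) were chosen so every property is
  exercised across the full fitted parameter range while the whole suite
  runs in a few seconds.

## Known limitations

- Published summary-table values that cannot be derived from the printed
  (γ, n) via the model's own equations (part of the BED row and the whole
  BED50 block of the lung panel; EQD2 beyond ~0.2%) are *not* emulated: the
  package follows the equations and their defining properties, and the
  discrepancy is pinned down by tests that assert the recomputed values.
- Uniform-population TCP only: no inter-patient heterogeneity in N₀ or γ, no
  dose–volume effects, no organ-specific NTCP models (LKB etc.).
- No time-domain kinetics: dose-rate effects, incomplete interfraction
  repair, repopulation and assay-time selection are outside the model.
- Confidence intervals for fitted parameters (profile likelihood, bootstrap)
  are not provided; the fit reports residual diagnostics instead.
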