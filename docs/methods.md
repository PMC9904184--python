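# Methods

## Gas-production kinetics

**Pressure reconstruction.** Readings are gauge pressure (psi) above
ambient. Cumulative gas at reading *k* equals the volume of the current
gauge pressure plus the volumes of all releases recorded strictly before
*t*ₖ; the instrument is modelled as *read-then-vent*, so a release
stamped at *t*ₖ contributes only from the next reading on. A vent resets
the gauge to zero. Under this convention the reconstructed curve is
bit-identical whatever the venting schedule (threshold 0.75 psi, 0.4
psi, or never), which the tests verify to 10⁻⁹ mL/g DM. A decrease in
the reconstructed cumulative pressure larger than 0.1 psi without a
recorded vent is rejected as an inconsistent trace; smaller dips are
tolerated as sensor noise.

**Unit chain.** psi → kPa (× 6.894757) → moles (ideal gas law,
R = 8.314472 L·kPa·K⁻¹·mol⁻¹) → mL (× 22 400 mL/mol). Defaults:
headspace 0.150 L (250 mL bottle − 66 mL buffer − 34 mL inoculum,
substrate volume neglected) and 312.15 K (39 °C incubation); both are
configurable because neither is a property of the method, only of the
hardware.

**Blank correction.** Blank (inoculum-only) curves stay in mL per
bottle; their pointwise mean is subtracted from a substrate curve before
DM normalization semantics (i.e. divided by that bottle's g DM when the
curve is already normalized). Negative corrected values are kept and
flagged, never clamped — clamping would bias the asymptote low.
Correction is optional: reported gas may or may not have been
blank-corrected in any given lab's workflow, so both modes exist.

**Model fit.** The monophasic model G(t) = A/(1 + (B/t)^C) is defined as
0 at t = 0 by continuity. Fitting is bounded nonlinear least squares
(scipy `least_squares`, trust-region reflective) with starting values
A₀ = 1.1·max(G), B₀ = the interpolated time at which the curve crosses
A₀/2, C₀ = 1.5, and bounds A ∈ (0, 5·max(G)], B ∈ (0, 96] h,
C ∈ [0.1, 10]. Convergence tolerances are 10⁻¹² on parameters, cost and
gradient — tight enough that noiseless curves on the 10-minute/48 h grid
are recovered to better than 10⁻⁶ relative, which the acceptance tests
hold across the parameter range observed for grass substrates
(A ∈ [100, 200] mL/g DM, B ∈ [6, 13] h, C ∈ [1.2, 2.0]). Only the
monophasic (single-pool) case is implemented; multiphasic model
selection is out of scope.

**t_RM.** B(C−1)^(1/C) is reported only for C > 1; for C ≤ 1 the rate is
maximal at the origin and the quantity is undefined (None). Note the
geometry: t_RM < B for 1 < C < 2, t_RM = B at C = 2, and t_RM > B for
C > 2 — the property tests encode all three regimes. When t_RM is
evaluated on *mean* parameters (as printed summary tables do) it differs
slightly from the mean of per-replicate t_RM values because the formula
is nonlinear; a tolerance of ±0.05 h covers this in the worked-example
checks.

## Mobile-bag analysis

**Design.** The default plan is 2 grasses × 2 harvests × 2 pore sizes
(15/36 µm) × (40 intubated + 4 wash) replicates = 352 bags, intubated
bags assigned to 4 horses × 4 periods through a seeded random Latin
square over the four grass × harvest feeds (20 bags per horse per
period, pore sizes split evenly within a cell). 0.5 g of feed over the
24 cm² working face (one 2 × 12 cm side) gives the target
feed-to-surface-area of 20.8 ≈ 21 mg/cm².

**Transit time.** A bag found at the check at hour *k* is assigned the
midpoint *k* − 0.5 h of the preceding hour; transit time is the
recovered-fraction-weighted mean of these midpoints, hence invariant to
duplicating records and always inside the midpoint range.

**Exclusions.** Fecal bags count toward total recovery only; they enter
neither transit time, nor pooling, nor the regression — disappearance
past the caecum confounds the precaecal signal. Washing loss is reported
alongside, never subtracted from, in vivo disappearance, since the
soluble fraction genuinely leaves the bag in the stomach as well.

**Pooling and disappearance.** Residues pool by grass × harvest × pore ×
interval (1–3, 4–6, 7–10 h): masses add, compositions combine
residue-mass-weighted. For bags sharing a feed composition, pooled
nutrient disappearance equals the feed-amount-weighted mean of per-bag
disappearances (verified against that oracle in the tests). All masses
are on a DM basis including ash.

**Common-slope regression.** dDM is regressed on residence time with one
shared slope and a separate intercept per grass × harvest group
(dummy-coded ANCOVA, no interaction), solved by ordinary least squares
on the explicit design matrix. Per-bag midpoints are used when per-bag
dDM exists; pooled data fall back to interval midpoints (2, 5, 8.5 h).
Rank-deficient designs (a single distinct time) raise rather than
returning an arbitrary pseudo-inverse solution.

## Synthetic-data generators

All generators are pure functions of (scenario, seed); one
`numpy.random.default_rng` per call.

**Incubation.** Per-substrate truth defaults to twelve (A, B, C)
triples spanning six cool-season grasses at two harvests
(A 112–186 mL/g DM, B 7.6–12.1 h, C 1.24–1.95). Replicate variation is
independent mean-preserving lognormal noise (σ = 0.05 per parameter);
sensor noise is Gaussian on the pressure readings (σ = 0.01 psi — noise
lives on what the instrument measures, not on derived volumes). The
grid is 10-minute over 48 h (289 readings); venting follows the
read-then-vent protocol at the constant's threshold. Blanks carry a
small inoculum-only curve (8 mL/bottle asymptote).

**Bag study.** Each intubated bag is captured in the caecum with
probability 0.78, found in feces with probability 0.19, lost with 0.03.
Capture failure is modelled as an independent Bernoulli per bag rather
than as slow transit: a lognormal with mean 4.7 h and sd 1.7 h puts
~99% of its mass below 10 h, so censoring alone cannot produce a 78%
caecal rate — missed magnet captures can. Caecal transit is that
lognormal truncated at 10 h and discretized to the hourly check
(ceiling). Per-bag dDM = group intercept + 0.608 %/h × midpoint +
Gaussian noise (sd 2 points, truncated to [0, 100]); per-nutrient
disappearance = soluble fraction + rate × midpoint, capped at 99.9%
(residues always retain a trace). Soluble/rate defaults: sugars 92–95% /
≤0.7 %/h (washing-dominated), fructan 70% / 3.5 %/h (large wash loss
plus fast precaecal degradation), CP 55% / 2.5 %/h, fiber 2% / 0.7 %/h.
Wash controls lose exactly the soluble fractions. Residue compositions
are back-computed so the analysis recovers these targets.

**Feeds.** Grass × harvest means encode the qualitative maturation
structure (CP falls, fiber rises, PR richest in WSC, fructan share
rising late in SB/PR/TF/TI); Gaussian block noise (sd 8 g/kg DM) applies
to totals, and component sugars are rescaled to sum exactly to the drawn
WSC.

**What the generators do not emulate:** microbial community or pH
dynamics, diurnal/horse-level transit heterogeneity, correlated
replicate parameters (independence assumed; the joint distribution is
unknown), gastric acid-hydrolysis mechanisms, or assay error structure
in the enzymatic sugar measurements. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
structure, not robustness to every feature of real data.

## Problem sizes and determinism

Monte-Carlo checks use sizes chosen to keep sampling error well inside
the asserted tolerances: 100 seeds for noisy kinetic refits (median
|ΔA|/A < 2%), 200 seeds for noisy slope recovery (mean slope within
±0.1), and 20–25 replicate 352-bag studies for the transit/recovery
targets (standard error ≈ 0.08 h and 0.5 points). Seeds are fixed in
the tests; the CLI funnels all randomness through `--seed`.

## Known limitations

* The monophasic fit can sit at a bound (C → 0.1 or 10) on pathological
  curves; `converged` plus the residual sum of squares must be checked
  rather than trusting parameters blindly.
* Blank correction assumes blanks share the recording grid up to linear
  interpolation; strongly nonlinear blank kinetics between readings
  would alias.
* The disappearance bookkeeping treats compositions as exact; assay
  uncertainty is not propagated into the reported percentages.
* The Latin-square randomization is one admissible square per seed, not
  a uniform draw over all 4 × 4 squares.
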