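# fermkin

Forage fermentation kinetics and equine precaecal digestion analysis.

`fermkin` is for animal-nutrition researchers who evaluate grass forages
with two complementary techniques:

* the **in vitro gas-production technique (IVGPT)** — a substrate is
  fermented in sealed bottles with hindgut inoculum, a sensor records
  headspace gauge pressure every 10 minutes for 48 h, and the bottle is
  vented automatically whenever the pressure exceeds a threshold
  (0.75 psi by default);
* the **mobile bag technique (MBT)** — porous feed-filled bags transit
  the gastrointestinal tract, are captured at a caecal cannula by hourly
  magnet checks for 10 h (or later in feces), and their residues
  quantify precaecal nutrient disappearance.

The package turns the raw outputs of both techniques into the standard
kinetic and digestibility summaries, and ships seeded synthetic-data
generators that emulate the full experiment, so every analysis stage is
testable by parameter recovery without animal data.

## The model

Vented pressure traces are rebuilt into cumulative gas: each release is
added back to the running total, pressure is converted to moles with the
ideal gas law *n* = *pV*/(*RT*) and to volume with the standard molar
volume (22 400 mL/mol), and the curve is normalized to mL per g of
substrate dry matter. The curve is then fitted with the monophasic
sigmoidal model

    G(t) = A / (1 + (B / t)^C)

where *A* is the asymptotic (maximum) gas production (mL/g DM), *B* the
time at which half of *A* is reached (h), and *C* a dimensionless shape
constant. The time of maximum digestion rate is

    t_RM = B (C − 1)^(1/C),      defined for C > 1.

For the bag experiment the package computes the transit time
Σ *t*ᵢ*M*ᵢ (midpoint of the *i*-th hourly check weighted by the fraction
of recovered bags found there), caecal and total recovery rates,
per-nutrient disappearance 100·(feed-in − residue)/feed-in on a DM
basis, washing loss from never-intubated control bags, residue pooling
by grass × harvest × pore size × recovery interval (1–3, 4–6, 7–10 h),
and the common-slope ANCOVA dDM = *a*_group + *b*·*t* — one shared slope
with a separate intercept per grass × harvest group.

## Worked example

```python
import fermkin as fk

# --- gas kinetics: simulate one bottle and recover its parameters
scenario = fk.GasScenario(substrates={"PR_early": (181.8, 8.3, 1.62)},
                          n_replicates=1, n_blanks=0,
                          replicate_cv=(0, 0, 0), noise_sd_psi=0.01, seed=1)
traces, truth = fk.simulate_incubation(scenario)
curve = fk.cumulative_gas(traces[0])
fit = fk.fit_monophasic(curve)
print(fit.A, fit.B, fit.C, fit.t_rm)
# 181.8  8.30  1.620  6.18   (23 automatic vents on the way)

# --- mobile bags: a full 352-bag study with known ground truth
records, _ = fk.simulate_bag_study(fk.BagScenario(seed=1))
print(fk.transit_time(records), fk.recovery_rate(records))
# 4.57 h, (76.9 % caecal, 96.2 % total)

points = [((r.grass, r.harvest), r.recovery_hour - 0.5,
           100 * (r.feed_in - r.residue_mass) / r.feed_in)
          for r in records if r.recovery_site == "caecum"]
fit = fk.common_slope_fit(points)
print(fit.slope, fit.intercepts)
# slope 0.609 %/h; intercepts PR-early 38.38, PR-late 32.62,
#                             CF-early 35.37, CF-late 21.32  (r² = 0.90)
```

The recovered slope and intercepts sit on top of the generator's truth
(0.608 and 38.01/32.51/35.29/21.37): the intercept is the instantly
soluble fraction of the feed, the slope the additional DM lost per hour
of precaecal residence.

The same pipeline runs from the shell:

```sh
fermkin --seed 1 simulate-bags --out-dir sim
fermkin --seed 1 analyze-bags --bags sim/bags.csv --feeds sim/feeds.csv \
        --residues sim/residue_composition.csv --out-dir results
```

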