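# Methods

## Disproportionality model

A cohort is a set of spontaneous adverse-event reports, every one anchored
on oxaliplatin.  A **case** is a report whose reaction list contains any of
the peripheral-neuropathy preferred terms (matching is exact per term after
whitespace collapsing and case folding — no substring or MedDRA-hierarchy
matching).  An **exposure** is a report listing any member drug of the
definition in a counted role; the default counts both SUSPECT and
CONCOMITANT roles, since spontaneous reports use the roles inconsistently
and "use" of a co-medication is role-agnostic.  Class rows ("any PPI")
count a report once regardless of how many member drugs it lists.  The
default PPI class contains omeprazole, pantoprazole and rabeprazole plus
the other marketed PPIs (lansoprazole, esomeprazole, dexlansoprazole) as
configurable extras.

Each panel row contrasts exposed reports against **all other reports of the
cohort** (not against PPI-free reports); this "with vs without" design is
the standard disproportionality contrast and is configurable by editing the
exposure definitions.  No multiple-testing adjustment is applied across
panel rows; readers should treat the panel as descriptive signal detection,
not confirmatory inference.

Statistics on the 2×2 table (n11 exposed cases, n12 exposed non-cases, n21
unexposed cases, n22 unexposed non-cases):

- `ROR = (n11·n22)/(n12·n21)`, computed at full floating precision.
- Wald CI `exp(ln ROR ± z·√Σ 1/cell)` with `z = 1.96` **exactly** at the
  95% level, matching the conventional printed constant rather than the
  exact quantile 1.959964 (invisible at two decimals, but it makes printed
  arithmetic bit-reproducible); other levels use the exact normal quantile.
- Pearson chi-square with 1 df, delegated to `scipy.stats.chi2_contingency`;
  the Yates continuity correction triggers automatically when any
  **observed** cell is `< 5` (the literal small-count rule), with an option
  to trigger on expected counts, always, or never.  The test suite verifies
  both variants against the closed-form 2×2 expressions.
- Zero cells raise a degenerate-table error by default; an opt-in
  Haldane–Anscombe correction adds 0.5 to every cell and is flagged in the
  result.

## Marginal reconstruction

Published summaries often print only the cohort total, the case total and
the two group rates at two decimals.  `reconstruct_from_marginals` searches
every exposed-group size `Ne ∈ [1, N−1]` and every feasible `n11`, scoring
candidates by the squared difference between the table's rates — rounded
half away from zero at two decimals, the print convention — and the printed
rates.  All minimal-score tables are returned.  The printed rates are
interval-censored (3.06 means [3.055, 3.065)), so the tie set is an
interval of consistent tables; the default primary pick is its **central**
member (ordered by `Ne`), the least extreme consistent table, with
`tie_break="smallest"` available.  For the published omeprazole marginals
17 tables reproduce both rates exactly (Ne 1273–1374); the central pick is
(41, 1297, 3112, 44902), whose ROR and CI round to the published values,
while the extreme members shift the upper CI bound by one unit in the
second decimal.  Infeasible inputs (both rates on the same side of the
overall rate) raise an error.

## Synthetic cohort generator

The generator emulates a database extract of oxaliplatin reports with a
known ground truth:

- per-drug exposures are independent Bernoulli draws at their prevalence
  (co-prescription correlation is deliberately not modelled);
- the event is drawn with probability `mb/(1−b+mb)` where `b` is the
  baseline event probability and `m` the product of odds multipliers of the
  drugs present — under this model the population ROR of a planted drug
  equals its multiplier, which is what makes the multiplier a recovery
  target;
- the planted event is reported under one of the three neuropathy preferred
  terms, chosen uniformly;
- 0–3 filler reactions and 0–3 filler co-medications per report are drawn
  uniformly from configurable vocabularies (disjoint from the planted
  terms/exposures by validation) to make term matching non-trivial; fillers
  carry multiplier 1;
- each co-medication is labelled CONCOMITANT with probability 0.8 (SUSPECT
  otherwise) so both roles occur; the anchor drug is always SUSPECT;
- one `numpy` Generator seeded from `config.seed` drives everything — no
  global RNG state; identical configs reproduce identical cohorts.

`expected_table` gives the exact expected 2×2 cells in closed form by
marginalizing over the other planted drugs (an explicit convolution of the
multiplier-product distribution), and serves as the independent oracle for
generator tests.

What the generator does **not** emulate: FAERS duplicate reports and case
versions, demographics, indications, dates, dose, report-quality artifacts,
and correlated co-prescription.  Passing recovery tests therefore shows the
statistics are correct and calibrated under the stated sampling model, not
that real-database biases are handled.

Default study-scale conditions used in the end-to-end tests: planted-effect
recovery uses 50,000-report cohorts with baseline event probability 0.0648,
omeprazole prevalence 0.0265 and multiplier 0.456 (the scale of the
published cohort); null-calibration uses 200 replicate cohorts of 20,000
reports — large enough that expected exposed-case counts (~34) put the Wald
interval in its asymptotic regime while keeping the 200-replicate sweep
fast.

## Preclinical formulas

- **Tumor volume**: `V = (π/6)·thickness·length·width` (mm³), the ellipsoid
  approximation for caliper measurements; symmetric in the three
  dimensions; zero if any dimension is zero.
- **Sample size**: `n = 2σ²/δ²·(z₁₋α/₂+z₁₋β)²`, rounded **up** (the pilot
  inputs σ=5.5/δ=8.0 g and σ=145/δ=210 mm³ give raw values 7.42 and 7.48,
  both reported as 8, confirming the ceiling), defaults α=0.05, β=0.20,
  minimum 2 per group.  The ceiling is taken with a 1e−9 tolerance so
  mathematically integer raw values do not round up spuriously.
- **Group comparison**: one-way ANOVA (`scipy.stats.f_oneway`) followed by
  Tukey–Kramer all-pairs tests (`scipy.stats.tukey_hsd`, which honours
  unequal group sizes).  Zero-total-variance input returns F=0 and all
  p-values 1.

## Up–down threshold estimation

The procedure follows the standard rodent convention: stimulation starts
mid-ladder on the default filament set 0.41–15.14 g (mean log10 spacing
δ ≈ 0.224); a withdrawal steps down, no withdrawal steps up, clamped at the
ladder ends.  The counted window is six responses starting one trial before
the first change in response; trials recorded after the window are ignored
with a warning.  The 50% threshold is `10^(x_f + k·δ)` grams, with `x_f`
the log10 of the final counted force and `k` looked up by the window's
response pattern; the estimate is clamped to the ladder range.  A series
that never changes response is censored at the corresponding ladder bound
and flagged.

The bundled k-table (`data/updown_k.json`, 32 patterns) is derived by
bounded maximum likelihood: the up–down rule fixes the relative filament
positions a pattern visits, and `k` is the ML location of a probit response
curve with scale equal to one ladder step, minus the final position
(patterns with perfect response separation have flat likelihood tails, so
the optimum is constrained to the visited range ± 2 steps).  The table is a
plain data file and can be replaced by any other pattern → k mapping;
`build_k_table()` regenerates it, and a test compares the bundled file
against regeneration.  Limitation: `k` is keyed on the response pattern
alone, so a counted window that runs into a ladder end (where the rule
clamps) uses the nominal unclamped positions.

## Fiber morphometry

Boundaries are closed planar polygons (shoelace area, Euclidean perimeter,
via shapely; self-intersecting or degenerate polygons are rejected) or raw
(area, perimeter) measurements.  Diameters are equivalent-area-circle
diameters `d = 2√(A/π)`; thus `g = √(A_axon/A_fiber)` and myelin thickness
`(d_fiber−d_axon)/2`, which satisfy `thickness = (d_fiber/2)(1−g)`
identically.  Circularity is `4πA/P²`.  Image segmentation is out of scope:
inputs are boundaries or areas, e.g. exported from a mask-labelling step.
The synthetic generator plants per-fiber g on concentric ellipses (outer
semi-axis 2–6 µm, mild eccentricity) with optional multiplicative radial
vertex jitter; with zero jitter the planted g is recovered exactly because
scaling a polygon by g scales its area by g².

## Numerical conventions

- Rates and printed statistics round half away from zero (2 decimals for
  rates, 4 for statistics), matching print conventions rather than
  banker's rounding.
- Chi-square closed forms clamp `|n11·n22−n12·n21| − N/2` at zero under the
  Yates correction.
- All seeds are plain integers feeding `numpy.random.default_rng`; derived
  seeds stay below 2³¹.

## Known limitations

- The reconstruction is exact only up to the information destroyed by
  printing; the tie set, not the primary pick, is the honest answer, and
  both are returned.
- The Wald interval is asymptotic; at small exposed-case counts its
  coverage drifts from the nominal level, which bounds how small the
  simulated cohorts in the calibration tests can be.
- Disproportionality on spontaneous reports measures reporting, not risk:
  no causal reading is implied anywhere in the package.
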