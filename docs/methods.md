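# Methods

This note documents the models, rules and numerical choices the package
implements, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem left genuine latitude.

## Nutrient-profile score (FSAm-NPS / FSAm-HCSP)

Foods and beverages are scored per 100 g (100 mL for beverages) with the
2017 rules in force when the Nutri-Score became the official French
front-of-pack label. Unfavourable points A sum four 0–10 components:

| component | band lower edges (strict `>`) |
|---|---|
| energy (kJ) | 335, 670, …, 3350 |
| sugars (g) | 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45 |
| saturated fat (g) | 1, 2, …, 10 |
| sodium (mg) | 90, 180, …, 900 |

Favourable components: fibre (edges 0.9, 1.9, 2.8, 3.7, 4.7; 0–5),
protein (1.6, 3.2, …, 8.0; 0–5) and fruit/vegetables/legumes/nuts
(>40 % → 1, >60 % → 2, >80 % → 5; beverages 2/4/10). Beverages use their
own energy bands (multiples of 30 kJ, 0 only at ≤ 0) and 1.5-g sugar
bands; added fats replace the saturated-fat table with the
saturated-fat-to-total-fat percentage table (`≥` on its lower edges 10,
16, …, 64 — the one table whose published convention is inclusive).

Final score = A − C with the protein cap: when A ≥ 11, protein points are
withheld unless the item is a cheese or its fruit-and-vegetable points sit
at the category maximum (5 for foods, 10 for beverages). Letters: foods
A ≤ −1, B 0–2, C 3–10, D 11–18, E ≥ 19; beverages B ≤ 1, C 2–5, D 6–9,
E ≥ 10, with letter A reserved for water via an explicit flag — never
inferred from composition, so even a 100 %-fruit juice grades B at best.

Unit conversions are fixed at 1 kcal = 4.184 kJ and salt g = sodium mg ×
2.5/1000; a composition may omit one member of each pair and the other is
derived. Fibre is taken as AOAC fibre with no conversion. The
fruit/vegetable percentage of mixed dishes is accepted as an input column;
the package does not attempt to infer it from recipes.

Scoring is deterministic integer arithmetic, so the test suite checks it
against an independently written brute-force band scanner on 10⁵ random
compositions, plus monotonicity (raising any A-nutrient never lowers the
score; raising fibre or fruit content never raises it) and kJ/kcal and
salt/sodium entry-point equivalence at band edges.

## Meal assembly

A receipt is all lines sharing (badge, site, date). Lines name either an
item of the same-day offer or one of the till's undetailed composite
tokens. Composites resolve to the unweighted arithmetic mean of the
members on offer that day at that site — unweighted because no
within-composite sales data exist in this design. Composite portions are
standard containers (cheese fixed at 30 g; yogurt 125 g, beverage 250 mL,
salad bar 150 g, dessert bar 100 g, side dish 150 g by default,
overridable). The fixed-price menu token is never resolved: its contents
vary too much for a day-average to be meaningful, so the meal is only
flagged and later excluded.

Per-meal totals are Σ (per-100 g value × portion / 100); a line's
quantity multiplies its portion, not the product count. The meal score is
the energy-weighted mean of item scores, Σ sᵢeᵢ / Σ eᵢ with eᵢ the item's
portion energy; the weighting is invariant to the energy unit since the
conversion factor cancels. The score is therefore always bounded by the
minimum and maximum item score of the meal (convexity), which is asserted
on every simulated trial. Main courses are identified by the offer's slot
column, not by name matching.

## Exclusion cascade and ledger

Order: (1) badges observed at both sites are dropped wholesale (they
cannot be one diner's trajectory); (2) receipt rules — menu receipts,
then > 10 products, then > 1 main course, each meal counted once under
the first matching rule, boundaries inclusive (exactly 10 products or 1
main is kept); (3) meals strictly below the 1st or strictly above the
99th percentile of the pooled post-receipt-rules energy distribution.

Percentiles use the empirical definition with averaging at integer ranks
(with n observations, p·n integral → mean of order statistics p·n and
p·n+1, otherwise order statistic ⌈p·n⌉). This is the default definition
of the statistical software the motivating trial used, and on a sample of
100 distinct energies it trims exactly the minimum and maximum; the
inclusive nearest-rank alternative would trim nothing at the bottom of
such a sample, which contradicts the intended ~1 % per tail. Pools under
100 meals trigger a warning but still compute. Every run maintains a
flow-chart ledger with the identity
input = kept + menu + >10 + >1-main + trimmed, validated on every call.

## Inference

**Difference-in-differences.** Outcomes are first averaged per participant
× period, restricted to participants with at least one meal in both
periods; a Gaussian identity-link model `y ~ site × period` is then fit to
the aggregates. On this saturated 2×2 design the interaction equals the
arithmetic difference of differences exactly (asserted to 10 significant
digits), and aggregation keeps heavy attenders from dominating.

**Trajectory mixed model.** Per-meal observations, participant random
intercept, fixed effects site, time (days since study start, absorbing the
seasonal drift of the menu cycle), site × time (differential drift),
intervention period (the immediate label effect: 1 only at the labelled
site after the switch) and intervention × time (post-switch change of
trend), optionally plus the day-offer mean score (absorbing day-to-day
changes in what the kitchen proposed). Estimation is REML via statsmodels
MixedLM; the default BFGS optimiser is followed by L-BFGS, Nelder–Mead
and Powell fallbacks, accepting the first converged fit and raising a
diagnostic-carrying error if none converge. A collapsed random-intercept
variance triggers a flagged fixed-intercept OLS fallback. Intervals and
p-values are Wald z — appropriate at the thousands-of-meals scale the
design produces, and verified to give 93–97 % empirical coverage under a
null generator. Fixed effects are cross-checked against R's lme4 on the
same data in the test suite. Time is measured in days; rescaling to weeks
multiplies the three time-slope terms by exactly 7 and leaves the rest
unchanged (asserted).

**Sensitivity variants** re-fit without the offer covariate and on the
subset with ≥ 5 meals and at least one per period.

**Power.** `required_n` uses the two-group normal approximation with the
small-sample correction applied at the total level,
N = ⌈4(z₁₋α/₂+z₁₋β)²/d² + z²₁₋α/₂/2⌉. Among the common correction
conventions (which differ by 1–3 subjects), this is the one that
reproduces the motivating trial's published 1053 at d = 0.20, power 0.90,
α = 0.05 exactly; the alternatives are not otherwise distinguishable from
the published text. The formula is monotone in d and rejects d = 0. No
evenness constraint is imposed on N (the published value is odd).

## Synthetic trial generator

The generator emulates the study conditions of the motivating trial: two
sites with identical daily menus (standardised recipes), 1268 + 795
participants, a Mon–Fri calendar from mid-December capped at 62 service
days, the label switched on at day 49 (start of week 8), ten starters /
eight mains / seven desserts a day plus cheese, yogurt, beverage, salad
bar, dessert bar and side-dish composites, monthly rotation of item
pools, and ~11 % fixed-price-menu receipts plus small fractions of
>10-product and dual-main receipts to exercise the filters. Per-slot
uniform nutrient ranges are chosen so each day's offer spans at least
four letter bands and assembled meals average ≈ 800 kcal, matching the
descriptive magnitudes of real cafeteria data; attendance probabilities
are uniform on (0.06, 0.50) per participant, which yields ≈ 36,000 meals
over the study.

Choice behaviour is a softmax over item utilities −aᵢ·s with
participant-specific score aversion aᵢ ~ N(0.20, 0.15²). After the
switch, intervention-site utilities gain `immediate_shift × score`
(default −0.5: toward lower-score items) drifting linearly by
`trend_per_day` (default +0.01: the effect fades), which reproduces the
immediate-improvement-then-decay pattern through the full receipt
pipeline. Because the receipt format carries no per-line portion (portions
live in the composition table and quantities are integers), the
post-switch time trend is carried entirely by item choice rather than
portion drift; the direct panel simulator below is the tool for exact
linear trends.

What the generator does **not** emulate: nutrient correlations within
items (nutrients are drawn independently and clipped to validity), menu
semantics, prices, weekday or holiday effects, plate waste, and any
participant covariates. Passing tests therefore demonstrate that the
pipeline's arithmetic, filters and estimators behave correctly under the
assumed data-generating structure — not that the behavioural model
predicts real cafeteria behaviour.

`simulate_panel_from_model` bypasses behaviour entirely: outcomes are
drawn from the random-intercept linear model on the trial's design matrix
(calendar-day time over Mon–Fri service days). It backs the
simulate-then-refit validation: panels generated from the published
coefficient blocks (1000 participants per site, 62 days; random-intercept/
residual SDs 1/2 score points, 50/150 kcal, 0.5/1 g for the score, calorie
and salt outcomes respectively) are refit and the targeted coefficients
must land inside the published 95 % intervals. Multi-replicate recovery
and interval-coverage checks in the test suite run at reduced panel sizes
(e.g. 200 participants/site over 62 days × 50 replicates; 60/site × 100
replicates) with noise levels chosen so the Monte-Carlo error of the
check is small relative to its tolerance.

## Numerical and degenerate-input conventions

- Band comparisons: strict `>` on lower edges everywhere except the
  added-fat ratio table (`≥`), per the published tables; a food at
  exactly 4.5 g sugars scores 0 sugar points.
- A meal with zero total energy has no defined energy weighting and is an
  error, as is an added fat with zero total fat.
- Descriptive cells with one participant report a missing SD, and empty
  cells are reported missing, never zero; an empty site × period cell
  makes the DiD contrast inestimable (error).
- All randomness flows from a single integer seed per run; identical
  seeds give bit-identical offers, receipts, manifests and fits.

## Known limitations

- The behavioural choice model is a minimal stand-in whose job is to
  carry injectable effects; its utility scale is not calibrated to any
  observed elasticity, so generator effect sizes are not comparable in
  magnitude to published trial coefficients.
- Wald intervals ignore the finite number of participants; at a few dozen
  groups they will undercover slightly.
- The day-offer covariate is the unweighted mean score of everything on
  offer; it does not weight by popularity.
- Composite day-averages blur within-token heterogeneity (a
  classification bias inherent to undetailed receipts, affecting both
  sites alike).
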