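# Methods

This note documents the models, rules and numerical choices behind
`olfmap`, and what the synthetic data can and cannot show.

## Clinical scoring

BMI is weight/height² (kg/m²); 25 ≤ BMI < 30 is overweight, BMI ≥ 30
obesity. BMI < 25 is an out-of-cohort signal for a weight-excess study
population: `compute_bmi` returns class `None` and the pipeline excludes
such records (with a log note) before classification and mapping.

The metabolic component flags follow the IDF-style definition for
European adults. Comparison directions are deliberate and tested:

* waist circumference is elevated when it **strictly exceeds** the
  sex-specific cut-off (80 cm women, 94 cm men);
* fasting glucose (≥ 100 mg/dL), triglycerides (≥ 150 mg/dL) and blood
  pressure (≥ 130 systolic, ≥ 85 diastolic) are **inclusive**;
* HDL is reduced when **strictly below** 50 mg/dL (women) / 40 mg/dL (men);
* specific treatment (diabetes, dyslipidemia, hypertension) raises the
  corresponding flag regardless of the measured value.

The blood-pressure flag defaults to the either-or reading (systolic **or**
diastolic over its cut-off); a conjunctive variant is available via
`bp_both_required` because the definition is sometimes quoted both ways.
Metabolic syndrome is elevated waist **plus at least two** of the four
remaining flags — an exhaustive 2⁵ truth-table test pins the rule.

The Mediterranean Diet Score sums 11 food-group components, each 0–5
(Mediterranean-typical foods scored increasingly, non-typical decreasingly;
inputs arrive pre-binned — the package defines no food-frequency bin
edges). The alcohol component maps daily volume to 5/4/3/2 for consumption
below 300/400/500/600 mL/day; the published band list leaves 600–700
unstated, and the scorer fills that gap minimally by letting score 1 cover
600–700 mL/day inclusive, with 0 for zero consumption or > 700. The
adherence reference of 30 points is a sample-derived convention, kept as a
configurable default rather than a validated threshold.

## Sniffin' Sticks scoring

Dilution steps are indexed 1–16 with 16 the most dilute pen, so higher
threshold scores mean better sensitivity. The staircase starts at the most
dilute pen and presents triplets in increasing concentration (step index
decreasing). Two correct responses in a row at one step (evaluated within
the level) reverse the run toward weaker concentrations; from then on a
single miss reverses downward-in-concentration runs and two-in-a-row
successes reverse upward ones. After seven reversals the threshold score
is the mean of the last four reversal levels.

Boundary handling: the staircase clips at steps 1 and 16. A toward-dilute
run clipped at 16 records a reversal there — the subject detects the
weakest stimulus, so the score saturates at 16, the conventional perfect
score. The ascending clip at step 1 records nothing: a subject missing
even the strongest stimulus has no measurable threshold, and the run ends
as a non-completion at the presentation cap (default 100).

Discrimination and identification are 16-trial forced-choice counts.
Normosmia/hyposmia cut-offs are configurable; the shipped TDI default
(30.75) follows common clinical usage and the subtest defaults are package
choices. The fixture cohort carries explicit stored classes so nothing
downstream depends on the default numbers. Scores at or below TDI 16 fall
in the conventional anosmia range; the two-class output still reports
hyposmic, with a warning.

The simulated respondent answers threshold triplets correctly with
probability `1/3 + (2/3)·Φ((rank − θ)/σ)` where rank = 17 − step is the
concentration rank, θ the latent threshold and σ the psychometric slope
(σ = 0 degenerates to a step function); discrimination and identification
responses are Bernoulli with floors at the 1/3 and 1/4 chance rates.

## Statistics

Pearson correlation uses the two-sided t transform on n − 2 df and is
refused below n = 3 or at zero variance. The 2×2 chi-square is the
uncorrected Pearson statistic — the variant consistent with the reference
sex-by-olfactory-status comparison — with the Fisher exact p reported
alongside; Fisher is two-sided by the probability-mass method (all tables
with fixed margins whose probability does not exceed the observed one),
which the tests verify against an independent hypergeometric enumeration
for small tables. Significance is α = 0.05 with no multiple-testing
correction: the mapping stage is explicitly exploratory, and the bivariate
results are reported as observed.

## Synthetic cohorts

The generator's defaults are the study conditions: 51 women and 17 men per
cohort, per-sex means and dispersions fixed to the reference descriptives,
with SD reconstructed from printed standard errors as SE·√n (n = 51 or
17). The female age dispersion (20.8) is treated as an SD — as a standard
error it would imply an impossible spread — and is exposed as a parameter.

Each subject carries one standard-normal latent metabolic factor z; every
loaded variable is drawn as `mean + SD·(λz + √(1−λ²)·ε)`, which preserves
the marginal calibration exactly while planting pairwise correlations
λ_i·λ_j. Default loadings: +0.6 on systolic BP, fasting glucose and
triglycerides, +0.5 on weight and waist, +0.4 on diastolic BP, −0.6 on the
three olfactory subtests, −0.5 on the diet score, 0 on HDL (no association
was observed there). These are the simplest values that reproduce the
reference sign structure with comfortable margin: empirically r(TDI, SBP)
averages ≈ −0.47 and is negative in 100 of 100 seeds at n = 68. The
`sex_effect_olfaction` shift defaults to 0 because the per-sex means
already encode the female advantage. Values are clipped to physiologic
ranges, olfactory counts rounded to integers, threshold scores to quarter
steps (the staircase granularity), and the MDS total is scattered over 11
components capped at 5. Clipping and rounding bias the mean female TDI by
about −0.13 points against the 26.96 calibration target — an order of
magnitude inside the two-standard-error acceptance band.

What the generator does **not** emulate: real joint distributions beyond
one latent factor, measurement error structure, treatment assignment
correlated with disease, or any real patient's data. Passing tests on
synthetic cohorts therefore demonstrate that the pipeline recovers
structure that is present, not that the published effect sizes would be
recovered from clinical data.

The deterministic fixture cohort reproduces every reference per-sex count
margin exactly. Tables give only margins, so records are built by a greedy
first-k assignment per sex with no claim about joint cells (stated in the
cohort's provenance note). The metabolic-syndrome margin is made exact
structurally: all waists are elevated, the first k records per sex receive
≥ 2 component flags (stacking third and fourth flags where the margins
demand it) and every other record at most one, so the syndrome count
emerges from the classification rule rather than a stored label. The four
olfactory margins are mutually independent in the reference tables, so the
composite TDI class is stored as given data; the subtest raw scores are
consistent with the shipped cut-offs, but re-deriving the TDI class from
t + d + i can disagree with the stored class for some records —
fixture-mode analyses use the stored classes. Smoking and age are
unconstrained by any reference table and use fixed filler values so the
encoding can emit all 28 map nodes.

## Auto-Contractive Map

Training is exactly the contractive scheme in the README, with these
numerical choices:

* **C = 1.0**, initial weights 0.01·C, `max_epochs` 1000 — all
  configurable and recorded in the run manifest.
* **Learning rate 0.01** with per-epoch batch accumulation: deltas are
  averaged over records (fixed input order) and applied once per epoch.
  Averaging rather than summing keeps the rate independent of cohort size;
  at rate 0.01 the update factors provably keep every weight strictly
  below C (the `(1 − w/C)` contraction shrinks the gap geometrically and
  both deltas are non-negative, so weights grow monotonically in [0, C)).
* **Stopping**: training stops when the mean output magnitude |m^t| falls
  below `tol` (1e−6) — the fully contracted state — or when the applied
  updates themselves drop below `tol` (stationary weights). Under these
  dynamics the weight matrix typically freezes long before the output
  fades (the input-layer contraction v grows on a much slower timescale),
  so the stationarity criterion is the one that usually fires; on the
  28-variable cohort encoding neither fires within 1000 epochs and the
  model reports `converged=False` with fully stationary strengths — the
  determinism, boundedness and ordering properties hold regardless.

Strengths are the symmetrized weights `(w + wᵀ)/(2C)` with zero diagonal;
distances `1 − s`. Variables that co-activate often accumulate weight
fastest, so strengths order by co-occurrence (verified on two-variable
sweeps) and a variable's strongest connection is to its exact duplicate.
On cohort-sized inputs most tree-edge strengths land above 0.9, matching
the qualitative behaviour expected of the method. The encoding uses
complementary dummy pairs (both poles of each attribute appear as nodes,
summing to 1 per record); age is dichotomized at a configurable cut-off,
default 55 years, near the cohort mean.

## Semantic map

The map is the MST of the distance matrix (Kruskal via networkx).
Determinism under ties: candidate edges are inserted in lexicographic
label order and the stable sort preserves it, so equal distances resolve
lexicographically. Exhaustive Prüfer-sequence enumeration (n ≤ 8) serves
as the optimality oracle in tests.

Hubs are all nodes of maximal degree. The central node is found by
recursively deleting all current leaves; even-diameter trees leave two
survivors and the tie goes to the larger incident-strength sum, then the
lexicographically smaller label (the pruning survivor set equals the
classical eccentricity center, which the tests cross-check against
networkx). Tree energy is reported as both the sum of edge strengths and
the complementary total distance the MST minimizes.

Exports: edge-list TSV (strength at 4 d.p., distance at full precision,
hub/central annotations in comment lines; lossless round-trip at that
precision), GraphML and DOT with strength/distance edge attributes and
hub/central node flags. Layout and styling are left to graph viewers.

## Problem sizes and determinism

Shipped analyses use desk-scale sizes chosen to exercise every code path:
68-record cohorts, 200 generator replicates for calibration checks, 100
seeds for sign-recovery rates, 20 end-to-end runs for the planted
obesity–hyposmia adjacency property, 50 random matrices (n ≤ 6) against
the MST oracle. Every stochastic step flows from an explicit integer seed;
pipeline report bundles from identical configs are byte-identical apart
from the manifest timestamp.

## Known limitations

* The reference analysis's exact published map strengths depend on
  unavailable patient-level data and unpublished trainer settings; this
  package reproduces the method's contracts (determinism, bounded
  strengths, co-occurrence ordering, map topology properties), not those
  numbers.
* The Auto-CM stopping tolerance on the output magnitude is effectively
  decorative at the default C; the stationarity criterion governs.
* Whether the two-part healthy/unhealthy partition sometimes drawn on such
  maps is algorithmic or editorial is undefined here: the package exports
  the tree and leaves partition annotation to the user.
* The fixture's joint cell counts are a construction, not data; only its
  margins are meaningful.
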