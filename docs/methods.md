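# Methods

This note documents the models and procedures implemented in `sanmf`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Time-series graphs

Raw input is a long-format table of measurements (patient, variable, time
offset in hours from ICU admission, value in natural units) for 34 candidate
physiological variables. Records outside a per-variable measurable range
(plausibility bounds shipped in `sanmf.registry`) are removed as measurement
artifacts before any aggregation.

Windows are half-open `[w·Δt, (w+1)·Δt)`, 0-based, over a 72-hour horizon;
a record at exactly t = 72 h is discarded. Δt is 6 h (12 windows) or 24 h
(3 windows). Multiple records in one window are averaged before
interpolation — the merge rule is otherwise unconstrained and the mean is
the least structured choice. Empty interior windows are linearly
interpolated between the nearest populated windows; empty leading/trailing
windows copy the nearest populated value, since plain linear interpolation
leaves edges undefined. A patient-variable pair with no records yields no
chain at all (rather than an empty one).

Z-statistics are computed **cohort-wide per variable** over all interpolated
values (all patients, all windows, n−1 denominator); per-patient
standardization would destroy cross-patient comparability of levels. A
switch (`stats_on="raw"`) computes them from raw records instead, since
either reading of "standardized per variable" is defensible. Z-scores are
rounded half-away-from-zero and clipped to ±4 (configurable): ±4 SD spans
the plausible physiological range and bounds the level vocabulary.
Variables with zero variance are dropped with a warning.

The cohort-window filter (suspected infection onset within ±24 h of ICU
admission) treats the boundary as closed and excludes patients with missing
timestamps with a warning, not an error.

## Frequent subgraph mining

Chains are linear, so subgraph mining reduces exactly to contiguous
subsequence mining. `mine_corpus` is an Apriori-style level-wise miner:
length-m windows are counted only when their (m−1)-prefix is frequent
(anti-monotone pruning); sizes run 2–6 by default. Two counting conventions
coexist deliberately:

- **support** = number of distinct chains containing the pattern (document
  frequency), used against `min_support`;
- **feature values** = per-patient occurrence counts, overlapping
  occurrences all counted.

Since each patient contributes at most one chain per corpus, chain support
equals patient support. The test suite checks the miner against an
independent brute-force enumerator, exactly.

Subsumption removal works per patient: with P the set of patterns having
nonzero count for that patient *before* removal, every pattern in P that is
a contiguous sub-pattern (same variable) of a larger member of P is zeroed.
Judging maximality against the original P, not the progressively zeroed
set, removes any cascade ambiguity and makes the operation idempotent.
Patterns are never compared across variables. Columns whose totals reach
zero are dropped, with `mined − dropped = retained` bookkeeping preserved
in the matrix object and run manifest.

## NMF, consensus, and rank selection

The count matrix is factorized with Frobenius-loss NMF via Lee–Seung
multiplicative updates on raw counts (no TF-IDF or scaling — the method
operates on the plain count matrix). Multiplicative updates guarantee a
monotone non-increasing objective; the per-iteration trajectory is recorded
and asserted in tests. The objective is computed without forming `W·H`
(`‖X‖² − 2⟨XHᵀ, W⟩ + ⟨WᵀW, HHᵀ⟩`), keeping sparse inputs sparse.
Initialization is uniform random scaled by `sqrt(mean(X)/k)`, fully seeded.
Convergence: relative objective decrease below `tol` (default 1e-5) or
`max_iter` (default 300).

Multiplicative updates occasionally settle in a clearly worse local optimum
(on probe cohorts, ~10–20% of random inits, with a visibly higher
objective). The consensus ensemble doubles as a restart set: the
lowest-objective run provides the final `W`, `H`, and memberships.
Membership is the row-argmax of `W`, ties broken toward the lowest
component; all-zero rows are reported as unassigned rather than forced into
a component.

Consensus stability follows the Brunet convention: `n_runs` seeded fits
(default 30, enough for a stable estimate at a few hundred patients), a
connectivity matrix per run (1 iff two patients share an argmax component),
their mean as the consensus, and the Pearson correlation between
`1 − consensus` distances and the cophenetic distances of their
average-linkage dendrogram. A degenerate all-equal distance vector (single
consensus cluster) is reported as ρ = 0. Note a known property of this
statistic: at ranks *below* the true structure, the consensus can be
perfectly stable (every restart merges the same groups), so ρ saturates at
1.0 and does not strictly decrease away from the true rank on cleanly
separated data. This is why rank selection uses ρ as the primary score
**with a distinctiveness tie-break**: 1 − mean pairwise Jaccard overlap of
the components' top-100 coefficient sets. Hyperparameter search re-mines
the training matrix per (interval, support) grid cell on the training split
only; the 80:20 split is stratified by mortality with largest-remainder
apportionment (train size exactly `round(0.8·n)`, per-stratum rates equal
to within one patient). Refit validation refits the chosen configuration on
the held-out split and reports the ρ difference plus a Spearman correlation
of shared subgraphs' H weights, with components aligned greedily by cosine
similarity.

## Representatives and outcome models

A trend group's representatives are the union of its top-100 subgraphs by H
coefficient (rank ties at the boundary all included, making selection
deterministic) and all subgraphs with coefficient strictly greater than 1,
on raw H coefficients. Exclusivity counts representatives appearing in
exactly one component's set.

Outcome models are scikit-learn gradient boosting classifiers (300 trees,
depth 3, learning rate 0.1 — conventional defaults, configurable, fully
seeded). Membership classification is multiclass over the combined
representative sets; per-class AUC is one-vs-rest. Mortality models are
binary with a 0.5 decision threshold and are fit on a refreshed stratified
split, independent of the NMF split; the three feature sets
(representative-subgraph counts; mean of observed daily SOFA totals over
days 1–7; Elixhauser index as a van Walraven-weighted flag sum) share one
split so their test AUCs are comparable. Reported AUC is standard ROC-AUC.

## Profiling

Demographics tables report mean ± SD (n−1) for continuous variables and
within-subgroup percentages for categorical ones; BMI strata use
underweight < 18.5 ≤ healthy < 25 ≤ overweight < 30 ≤ obese. SOFA
trajectories average daily totals and the six organ subscores over patients
observed on each day (deceased patients drop out; a carry-forward switch
propagates the last observed day instead). Day-1 SOFA is the day-1 maximum
daily total taken as input. The comorbidity table retains categories whose
**maximum** subgroup incidence reaches 10% — the filter reads "minimal
subgroup incidence of 10%" as "at least one subgroup reaches 10%", which is
the only reading consistent with incidence tables that include categories
below 10% in some subgroups — and sorts by whole-cohort incidence with
registry order breaking ties.

Hypothesis tests are an unassuming standard battery: Welch one-way ANOVA
(via pingouin) plus pairwise Welch t-tests for continuous variables,
chi-square contingency tests for proportions, α = 0.05, no multiplicity
correction by default (a Holm option exists). Zero-variance groups with
equal means report p = 1 rather than erroring.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure the analysis assumes:

- **Latent groups.** Each patient draws a group from the cohort proportions;
  each (group, variable) has a trend archetype — a z-scale function of the
  window index. Observation times are a Poisson process (default rate 24
  measurements per variable per 72 h, roughly 3-hourly charting); measured
  values are `mean + sd·(archetype(w) + N(0, noise_sd))` with Table-style
  per-variable means/SDs; a patient-variable series is entirely absent with
  probability 0.05 (charting gaps).
- **Outcomes.** 30-day mortality is logistic per group; in-hospital death is
  a 0.75-probability subset of 30-day death. SOFA day-d totals are normal
  around `day1_mean + slope·(d−1)` (SD 2, clipped to 0–24, integer), split
  across the six subscores by fixed per-group weights with largest-remainder
  rounding capped at 4; days after an (uniformly drawn) death day are
  missing. Comorbidity flags are independent Bernoulli per category given
  group; demographics come from per-group normal/categorical distributions.

The study-default spec (`make_paperlike_spec`) plants three groups at
proportions 21/35/44% with mortality ≈ 17/28/10%, SOFA day-1 means
6.5/8.7/6.5 with slopes −0.35/−0.05/−0.70 (slow / little / fast
improvement), group-weighted subscore profiles (renal+cardiovascular,
+hepatic, +neurologic respectively), and comorbidity prevalences on the
scale of the study's incidence table. Trajectory shapes come from a fixed
bank (flat/rising/falling/peaked at amplitudes within ±2 z). For each
variable, one designated pair of groups shares its shape and the third
differs; the designated pair rotates across variables with subset sizes
(8/16/10) chosen so that, weighted by harmonic pair sizes, no two
phenotypes are systematically easier to collapse than any other — the
planted structure is genuinely three comparably distinct groups.

What the generator does **not** model: physiological coupling between
variables (variables are independent given group), within-group
heterogeneity beyond iid noise, time-varying mortality hazard,
within-patient comorbidity correlation, and measurement batch effects.
Passing recovery tests therefore demonstrate that the pipeline's machinery
is correct and that it recovers planted structure of realistic scale and
noise; they do not certify performance on real EHR data, where
between-patient variability is richer and group boundaries are fuzzier.

## Problem sizes and numerical choices

Recovery experiments run at 300 patients (34 variables, ~230k records,
count matrices of roughly 300 × 8–10k after subsumption removal) with 30
consensus runs; prognostic-signal experiments at 400 patients with 10
consensus runs; the demonstration pipeline at 100. These sizes give stable
statistics while keeping a full multi-seed experiment in the minutes range
on one core. Known numerical conventions: argmax ties break to the lowest
component; consensus matrices are symmetrized and their diagonal forced to
1; Pearson/cophenetic degeneracies report ρ = 0; divisions inside
multiplicative updates are guarded by ε = 1e-12.

## Known limitations

- Rank selection by argmax cophenetic ρ is unreliable when candidate ranks
  below the true rank are perfectly stable (see above); the distinctiveness
  tie-break mitigates but does not eliminate this.
- The miner's per-patient counts count overlapping occurrences; a
  non-overlapping convention would change counts for self-similar patterns.
- Subsumption removal is per-patient and exact, but the corpus-level
  vocabulary is not closed/maximal-mined; very low supports on large
  cohorts can produce wide matrices.
- The GBM hyperparameters are fixed defaults; no tuning or calibration is
  performed.
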