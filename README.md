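# sanmf — subgraph-augmented NMF phenotyping of ICU time series

`sanmf` derives discrete patient phenotypes from irregular multivariate ICU
physiological time series, for researchers studying heterogeneity in sepsis
and other critical-illness syndromes. Sepsis is a heterogeneous syndrome:
patients with the same diagnosis follow very different physiological
trajectories and outcomes. Rather than clustering on single time-point
snapshots, this package clusters on *temporal trends* — short, recurring
runs of discretized physiology — and validates the resulting subgroups
against mortality, organ-failure trajectories and comorbidity burden.

Because the clinical source data for this kind of study (ICU EHR extracts)
is access-restricted, the package ships a first-class synthetic cohort
generator that plants latent trend groups with group-linked outcomes, so the
whole pipeline can be exercised and its recovery properties tested end to
end against a known ground truth.

## Method

1. **Discretization.** Each patient-variable series from the first 72 h of
   the ICU stay is binned into uniform windows (Δt = 6 h ⇒ 12 windows),
   linearly interpolated across empty interior windows, z-scored cohort-wide
   per variable, and rounded to integer levels clipped to ±4 SD. The result
   is a chain graph per patient and variable; 34 candidate physiological
   variables give 34 corpora of chains.
2. **Frequent subgraph mining.** Within each corpus, every contiguous run of
   2–6 levels occurring in at least `min_support` chains is a frequent
   subgraph (a temporal trend). Per-patient occurrence counts form a sparse
   patients × subgraphs matrix; per patient, any pattern that is a
   contiguous sub-pattern of a larger pattern also present for that patient
   is zeroed (subsumption removal), and all-zero columns are dropped.
3. **NMF phenotyping.** The count matrix `X` is factorized as `X ≈ W·H` with
   `W, H ≥ 0` (Frobenius loss, multiplicative updates). Rows of `H` are
   *trend groups* — weighted composites of subgraphs; each patient's
   phenotype is the argmax of their `W` row. Stability across seeded
   restarts is scored by the cophenetic correlation of the consensus matrix;
   rank and preprocessing hyperparameters are selected by that score, with a
   distinctiveness tie-break (1 − mean pairwise Jaccard overlap of the
   components' top-100 subgraph sets).
4. **Representatives and validation.** Each trend group is summarized by the
   subgraphs ranked in its top 100 or with coefficient > 1. Gradient
   boosting machines validate that (a) these representatives predict
   phenotype membership and (b) the phenotypes carry prognostic information
   on 30-day mortality, benchmarked against mean 7-day SOFA scores and the
   Elixhauser comorbidity index (van Walraven weights).
5. **Profiling.** Demographics and outcome tables, 7-day SOFA trajectories
   with organ subscores, comorbidity incidence tables (retaining categories
   with ≥ 10% incidence in some subgroup), and between-subgroup Welch
   ANOVA / Welch t / chi-square tests at α = 0.05.

## Worked example

Run the full pipeline on a 100-patient synthetic cohort:

```sh
sanmf run --n 100 --seed 1 --out-dir demo
```

which prints a per-stage summary:

```json
{
  "simulate": {"patients": 100, "records": 77272},
  "prep": {"variables": 34, "chains": 3241},
  "mine": {"mined": 5334, "dropped": 1330, "retained": 4004},
  "factorize": {"objective": 137.88, "cophenetic_rho": 1.0,
                "unassigned": 0, "subgroup_sizes": {"1": 47, "2": 31, "3": 22}},
  "represent": {"n_unique": 296, "n_exclusive": 252},
  "validate": {"membership_test_accuracy": 1.0,
               "benchmark_order": ["representative_subgraphs",
                                   "elixhauser_index", "mean_sofa_7d"]},
  "profile": {"n_tests": 57, "n_rejected": 13}
}
```

Reading this: 77k irregular measurements became 3,241 level chains; mining
at support 5 found 5,334 frequent trends, of which 1,330 were subsumed by
larger patterns, leaving a 100 × 4,004 count matrix. The rank-3 consensus was
perfectly stable (cophenetic ρ = 1.0) and split the cohort 47/31/22. 296
unique representative trends summarize the three trend groups (252 exclusive
to one group); a GBM on those representatives reproduces the phenotype
labels perfectly on held-out patients, and the subgraph-based mortality
model ranks above both benchmarks. Every artifact (cohort CSVs, corpora,
MatrixMarket count matrix, W/H, representative sets, metric tables,
profile tables, run manifest with hashes) is written under `demo/`.

The stages are also available individually (`sanmf simulate | prep | mine |
tune | factorize | represent | validate | profile`), reading and writing the
same plain-text artifacts, and as library functions under `sanmf.*`.

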