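# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `netfa`, in the spirit of the methods
documentation of packages like statsmodels or msprime: what is computed,
under which assumptions, and what the tests do and do not establish.

## Graphs and position metrics

A cohort's friendship survey defines a directed, unweighted, simple graph:
`ego → alter` means ego nominated alter. Self-nominations are rejected
with a warning, duplicates collapsed, and surveyed subjects without ties
retained as isolates. Five position characteristics are computed per
subject:

- **Out-/in-degree**: counts of outgoing/incoming nominations.
- **Eigenvector centrality**: only incoming ties confer prestige, so
  scores solve `x ∝ Aᵀx` for the leading eigenvector. We use shifted
  power iteration on `Aᵀ + I` (same eigenvectors, no periodicity issues),
  uniform positive start, tolerance 1e−10, at most 10,000 iterations,
  normalized to max 1. Acyclic (nilpotent) graphs have leading eigenvalue
  0 and no meaningful centrality: detected exactly (DAG test) and mapped
  to all-zero scores with a warning rather than an error. Edgeless graphs
  raise. Tests verify the eigen-residual against a dense
  eigendecomposition to 1e−8.
- **Betweenness**: computed on the symmetrized graph (any tie in either
  direction), unnormalized Freeman/Brandes counting with multiplicity
  splitting, via igraph. The overall scale is irrelevant because metrics
  are z-scored before modeling. An exhaustive BFS path-count enumeration
  is the independent test oracle.
- **Burt constraint**: on the symmetrized graph,
  `Constraint_i = Σ_{j∈N(i)} (P_ij + Σ_q P_iq P_qj)²` with
  `P_ij = 1/deg(i)` and q over mutual contacts. The outer sum runs over
  direct contacts only (Burt's definition; the pendant-node value 1.0
  requires it). Isolates have undefined constraint: they yield NaN and
  are dropped only from constraint-based analyses. Brokerage is the exact
  negation of constraint.

**Transform.** Raw metrics are positively skewed. The modeling transform
is a sign-preserving square root of the raw metric (for brokerage this
equals minus the square root of raw constraint) followed by a
within-cohort z-score; transformed values therefore have mean 0 and unit
(population) variance per cohort. Applying the z-score first and the
square root second is ill-defined for negative z-scores; that literal
order is still available as `order="z_then_signed_sqrt"` (signed square
root after z-scoring) for comparison, but it is not the default and does
not return unit-variance values.

**Conventions.** All standardization in the package — the transform, the
fold-wise predictor scaler, internal z-scores — uses the population (1/n)
variance, matching the behavior of the usual machine-learning scalers, so
that worked examples like `zscore([0,1,2]) = [−1.2247, 0, 1.2247]` are
unambiguous.

## The predictive model

For one brain network (P tracts) and one transformed outcome:

1. Ten outer folds (seeded uniform shuffle, no stratification — outcomes
   are continuous). Setting `outer_folds = n` gives leave-one-subject-out.
2. Within each outer training fold, ten inner folds grid-search the ridge
   penalty λ over 100 log-spaced values in [1e−5, 10]. The inner selection
   criterion is mean validation MSE (out-of-sample correlation is
   available as an option); ties resolve to the smallest λ.
3. Predictors are standardized using training-fold statistics only; the
   model refit on the full outer-training fold predicts the held-out
   subjects. Every subject receives exactly one out-of-sample prediction.
4. Performance is the Pearson r between predictions and actual values;
   inference is a one-sided permutation test: the entire pipeline is
   re-run on outcome vectors shuffled across subjects and
   `p = (1 + #{r_null ≥ r_obs}) / (1 + B)` (add-one convention; the plain
   exceedance proportion is available as an option). One-sided because
   only positive prediction–outcome associations are interpretable here.
5. Across the five outcomes of a network, p-values are Benjamini–Hochberg
   adjusted. The adjustment family is "within network" by default; a
   pooled adjustment across all network × outcome tests is available,
   since the correct grouping is a genuine analytic choice.

**Covariates.** Age, gender, handedness, cohort and extraversion can be
controlled two ways. The default, `residualize_outcome`, fits an OLS of
the outcome on the covariates (indicator coding for categorical ones,
encoding fit on training rows) within each outer training fold and models
the residuals, applying the same projection to the held-out subjects —
the common choice in connectome-based predictive modeling, keeping P
interpretable. `unpenalized_covariates` instead adds the covariates to
the design without penalty (implemented by Frisch–Waugh residualization
of predictors and outcome, which is algebraically identical). The
covariate model is fit once per outer fold; inner folds inherit the
outer-training residualization. Missing FA entries surviving QC are
imputed with the training-fold column mean at model time, never globally.

**Implementation.** Permutation inference re-runs the identical pipeline
hundreds of times while only the outcome vector changes. The engine
therefore factorizes each design once per fold (scaler statistics and an
SVD of the standardized training design, from which the ridge solution
for the whole λ grid is a diagonal rescaling) and evaluates all outcome
columns — observed plus permutations — in a single batched product per
fold. For a single outcome this is value-for-value identical to a naive
per-fold scaler + ridge pipeline, which the test suite asserts against an
independent sklearn reimplementation at 1e−8. Because the factorization
depends only on the predictors and fold structure, training artifacts
cannot depend on held-out outcomes; a leakage probe (corrupting test-fold
outcomes and comparing the trained artifacts) verifies this directly.

## Necessity and sufficiency

**Necessity** (per tract t of a predictive model): the same pipeline is
run on the P−1 remaining tracts, giving `Δr = r_full − r_loo`. For each
of B outcome shuffles, both models are re-evaluated and the difference
collected; `p = (1 + #{Δ_null ≥ Δ_obs})/(1 + B)`. One seeded permutation
schedule is shared by the full model and every ablation within a run, so
the difference null isolates the effect of removing the tract rather than
permutation noise. The full-model r is recomputed inside the analysis
with the same configuration (never read from a previous run), and each
ablated model re-optimizes λ, mirroring the primary pipeline.

**Sufficiency** (per tract × outcome): cross-validated simple OLS on the
single standardized predictor, using the same seeded outer folds and the
same covariate handling as the multivariate models; there is no
hyperparameter, so the inner search is trivial. With a one-point λ grid
at λ → 0 the ridge pipeline reproduces these results (asserted at 1e−6).
P-values come from the same one-sided permutation scheme; they are
FDR-adjusted strictly across all executed tests (865 at the full design:
173 tracts × 5 outcomes; constant tracts are skipped with a warning and
excluded from the family size, which is recorded) and, as a relaxed
comparison, within each outcome's family.

## The synthetic-data generator

The generator emulates the study design so that every stage can be tested
against known ground truth; its defaults are the study's conditions.

**Survey arm.** Three cohorts of 275/279/285 subjects. Each unordered
pair seeds a nomination with probability proportional to the geometric
mean of gamma-distributed sociability propensities (shape 4, mean 1),
giving right-skewed degree distributions; a seeded edge is reciprocated
with probability `ψ = ρ/(2 − ρ)`, which makes the expected edge-level
reciprocity equal the target ρ. Pair probabilities are calibrated
analytically (including the gamma correction factor) to the printed
per-cohort mean total degrees 91/78/55 and reciprocities 0.53/0.49/0.48;
realized values land within a few percent at these cohort sizes. This is
the simplest mechanism hitting density and reciprocity jointly, not a
model of friendship formation.

**Imaging arm.** An imaged subsample of 46/32/34 subjects per cohort
(n = 112) is drawn without replacement. For subject i and tract t,

    FA[i,t] = 0.45 + offset_t + b_t·y_i + γ_t'z_i + ε[i,t],  clipped to [0.1, 0.9]

where y is the standardized transformed effect metric (default:
eigenvector centrality, signal placed in the mirroring network's tracts),
`offset_t ~ N(0, 0.05)` are tract-level baselines, and z are standardized
age, gender and extraversion. Signal weights b_t are nonzero for a random
subset of the effect network's tracts (default sparsity 0.5) with random
signs and common magnitude `b = σ·sqrt(r²/((1−r²)k))`, which makes the
planted linear combination explain `effect_r2` (default 0.2) of the
outcome variance in expectation; a Monte-Carlo test confirms the realized
R² stays in [0.1, 0.3] across replicate seeds at n = 112.

The tract noise ε is **not** independent across tracts: it is the sum of
a subject-level shared factor and an idiosyncratic part, with total
per-tract sd 0.03 and between-tract noise correlation 0.5. Real FA values
are strongly correlated across tracts within a subject (global
white-matter integrity, motion, scanner effects; empirical inter-tract FA
correlations commonly fall in the 0.3–0.6 range), and this shared
variance is precisely what lets distributed multi-tract models outperform
any single tract — the central phenomenon the package exists to test.

**Confounding.** Extraversion is generated as
`c·y + sqrt(1−c²)·noise` (default c = 0.3), and covariates load weakly
into FA (per-tract loadings scaled by c), so outcome–covariate and
FA–covariate correlations are nonzero exactly when c ≠ 0.
`SyntheticSpec.null()` gives the no-signal, no-confounding configuration
used for calibration runs. Gender and handedness are binary, age is an
integer in 24–35, matching the sample description.

**Reproducibility.** One global seed fans out to named substreams
(crc32-keyed `SeedSequence` children) for the survey arm, the imaging
arm, fold assignment and permutations, so components can be regenerated
independently and identical spec + seed reproduces every artifact
byte for byte. The survey arm can be generated once and reused across
imaging replicates, exactly as one survey wave serves every downstream
analysis of a real study.

**What the generator does not emulate:** voxel-level diffusion data,
tractography geometry, non-Gaussian FA noise, missingness (unless
injected), longitudinal change, or any mechanism of friendship formation.
Passing tests therefore demonstrate that the statistical machinery is
correct and well calibrated under a realistic covariance structure — not
that real brains predict real social networks.

## Problem sizes in the test and acceptance runs

Simulation-based checks run at the study's scale (n = 112, P up to 49;
the full 173 × 5 sufficiency screen) but with reduced replicate and
permutation counts chosen as the package's own defaults for routine
verification: 200 permutations per test, 200 null datasets for
calibration, 50 replicates for power and necessity detection, 30 for the
diffuse-necessity pattern, and 5 replicate datasets for the sufficiency
null screen. A full study analysis would use 1,000 permutations (the
`RidgeCVConfig` default).

## Known limitations

- Permutation p-values with B = 200 have resolution 1/201; strict BH
  across 865 tests cannot reject at that resolution (a full analysis
  should use B ≥ 1000).
- The out-of-sample r of nested CV is overdispersed relative to the
  1/√n normal heuristic (sd ≈ 0.13 at n = 112); the permutation null
  accounts for this automatically, but analytic p-values based on r would
  not.
- `unpenalized_covariates` reports r against the raw outcome, so its r
  mixes covariate and FA contributions; use `residualize_outcome` to
  isolate the FA contribution.
- With heavy regularization and weak signal, fold-wise predictions can be
  nearly constant; degenerate correlation columns are scored 0 inside
  permutation loops rather than raising.
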