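# Methods

## Data model

The unit of prediction is one target–indication pair. Evidence is stored as
a sparse three-mode binary tensor (targets × indications × evidence
sources); the clinical-outcome matrix (1 = at least one drug succeeded,
0 = all drugs failed Phase I–III) is appended as one extra slice. Three
states are distinguished per cell: observed positive (1), observed negative
(0), and *unknown* (absent from the file). An explicit 0 row is therefore an
observed negative, never a default. Duplicate evidence rows for the same
(target, indication, source) key are aggregated by maximum after
binarization: the upstream resources report positive associations, so a
conflicting duplicate 0 is treated as noise dominated by the positive call.

Evidence scores are binarized as positive → 1, zero → 0, missing → missing;
negative scores are rejected. Target-only categorical attributes are one-hot
encoded per source with non-overlapping categories; a target with no label
under a source gets an all-zero block, which matches "unclassified"
semantics without inventing a category.

All files are TSV with header rows and string ids; integer indices are
0-based and in-memory only.

## The factorization model

Observed cells are modelled as Gaussian around their CP score,
`x_ijk ~ N(Σ_d u_di v_dj e_dk, α⁻¹)`, with conjugate per-mode priors

- `u_i ~ N(μ_t + Bᵀ g_i, Λ_t⁻¹)` — targets, with side information,
- `v_j ~ N(μ_d, Λ_d⁻¹)` — indications,
- `e_k ~ N(μ_e, Λ_e⁻¹)` — evidence slices plus the outcome slice,

and a Normal–Wishart hyperprior on each mode's `(μ, Λ)`. Each mode carries
its **own** hyperparameters. (The source description of this model class
reuses one precision symbol across the three priors; we read that as a
typesetting slip — per-mode hyperparameters are the symmetric and standard
choice for this model family.)

Unstated constants are set to weakly-informative matrix-factorization
defaults: `μ₀ = 0`, `β₀ = 2`, `ν₀ = D`, `W₀ = I`. The link matrix has
i.i.d. `N(0, 1/λ_B)` entries with `λ_B = 1` by default — the simplest proper
prior that keeps the update conjugate.

Inference is Gibbs sampling with exact full conditionals:

- **Factor vectors.** For entity `a` with observed cells `c` and companion
  products `q_c` (elementwise product of the other two modes' vectors), the
  conditional is Gaussian with precision `Λ + α Σ q qᵀ` and mean
  `P⁻¹(Λ m + α Σ x q)`, where `m` is the (attribute-shifted, for targets)
  prior mean. Entities with no observed cells are drawn from their prior —
  this is exactly how cold-start predictions arise.
- **Hyperparameters.** Standard Normal–Wishart update on the factor vectors;
  for targets the conditioning vectors are the residuals `u_i − Bᵀ g_i`, so
  `μ_t` models what the attributes do not explain.
- **Link matrix.** With `Λ_t = Q diag(s) Qᵀ`, rotating the latent axes by
  `Q` decouples the rows of `Bᵀ` into independent ridge regressions of the
  rotated residuals on the attribute matrix; the i.i.d. prior is rotation
  invariant, so rotating the draw back is exact.

Sweep order is fixed (hyperparameters, B, U, V, E) for reproducibility; the
order does not affect the stationary distribution. No convergence
diagnostics gate the run — chain length is a configuration knob, defaulting
to 500 burn-in + 300 retained sweeps as in the reference analysis.
Predictions are the arithmetic mean of the per-sweep CP scores of the query
cells over the retained sweeps. No variational or MAP shortcut is provided.

**Observation precision.** The production default is α = 1, the reference
analysis's setting. For the desk-scale synthetic studies in
`trialtensor.experiments` we use a calibrated α = 10: those worlds are
binarized low-rank tensors whose best CP approximation leaves residuals of
roughly 0.3 sd, so 1/0.3² ≈ 10 is the noise level the likelihood should
assert. Asserting sd-1 noise on 0/1 values instead makes the posterior —
correctly, under that assumption — shrink nearly all signal at a few
thousand observed cells, which is a statement about the assumed noise, not
about the data. At the original study's scale (hundreds of cells per
entity) the distinction is immaterial.

**Rank selection.** The latent dimension D is chosen by maximizing mean
inner-fold AUPRC over a candidate grid (ties break to the smallest D). The
original analysis used an unpublished heuristic; the inner-CV grid is our
substitute and is not claimed equivalent.

## Synthetic worlds

`make_world` draws true factors `U*, V*, E*` at a known rank, computes
continuous CP scores plus `N(0, noise_sd²)` observation noise, binarizes by
a quantile threshold chosen to hit the requested positive rate, and keeps
exactly `⌈density · cells⌉` cells per slice set. Targets and indications are
assigned to contiguous-block groups; group means of the factors are placed
at least `link_strength` apart (scaled coordinate axes), and entities
scatter `within_group_sd = 1` around them. Target attributes one-hot encode
the target's group (padded with inert random binary columns up to G), and
the true link matrix maps that indicator to the group's latent mean — so
`u*_i = B*ᵀ g_i + scatter`, exactly the structure the model's prior assumes.
This makes parameter-recovery and transfer tests well-posed by design.

Default study conditions (chosen once, as a desk-scale analogue of the real
875 × 574 × 17 analysis slice): M=60 targets, N=40 indications, K=5 evidence
sources, true rank 3, G=12 attribute columns, 10% evidence density, 30%
outcome density, noise sd 0.1, positive rate 0.3, link strength 3, 6 target
classes and 4 indication clusters. The cold-start transfer study uses link
strength 6 — attribute-driven transfer is only well-posed when the
attributes genuinely determine the factors.

What the generator deliberately does **not** emulate: the real marginal
distributions of the 17 evidence sources, their mutual redundancy, phase
structure, or any real biology. Passing tests show the machinery is correct
and that the claimed qualitative behaviours (out-of-group robustness,
cold-start transfer) follow from the model's structure when the data has
it; they do not show the model would reach any particular performance on
real clinical data. One visible consequence: because the synthetic evidence
is CP-consistent with the outcomes by construction, the tensor model also
leads matrix completion under *random* CV here, whereas on the real data
matrix completion was narrowly ahead in that setting.

## Baselines

- **soft-impute** (implemented in-repo): iterative SVD soft-thresholding
  from Z = 0, `Z ← S_λ(P_Ω(R) + P_Ω⊥(Z))`, stopping at relative Frobenius
  change < 1e-5 or 500 iterations; the objective
  `½‖P_Ω(R−Z)‖² + λ‖Z‖*` is non-increasing by construction and asserted in
  tests. λ is tuned by inner-fold AUPRC, ties towards more shrinkage. A
  target or indication with no training outcomes carries no signal for pure
  completion; such pairs are scored at the observed global success rate
  (the collapse of completion under group CV is expected behaviour, not an
  error).
- **Tabular learners** (scikit-learn / xgboost behind the module surface):
  each pair is a row with two binary columns per evidence source — 1 →
  (1,0), 0 → (0,1), unknown → (0,0), i.e. "unknown" is the reference level
  so an all-missing pair sits at the intercept — plus the target's
  attribute block duplicated across its indications. Plain logistic
  regression uses a very large C (no practically relevant penalty); L1
  logistic regression tunes C on inner stratified folds by average
  precision; random forest tunes `max_features` by out-of-bag score;
  gradient boosting (xgboost) tunes learning rate, depth, feature
  subsample and iteration count on inner folds. Exact grids are
  configuration-exposed; the contract is the tuned scorer, not the
  learner internals.

## Benchmarking

Outer folds come in three schemes: random stratified (positives and
negatives shuffled separately and dealt round-robin, so per-fold positive
counts differ from proportionality by at most one), leave-one-target-class-
out and leave-one-indication-cluster-out (one fold per pre-defined group;
groups without outcome cells are dropped with a warning). Test outcome
cells are masked from the tensor before any fitting or tuning; evidence
cells of test pairs stay visible, mirroring a setting where association
evidence exists before a trial reads out. A poisoning test (flipping
held-out labels) asserts that fold scores cannot depend on test labels.

Metrics: AUROC (Mann–Whitney with ties at ½) and AUPRC (average precision,
step integration — the conservative standard, no interpolation), both
delegated to scikit-learn and verified against brute-force oracles in the
tests; precision@k and recall@k (k = 30, stable-order tie-breaking);
F-score at the 0.5 score threshold (the operating point is otherwise
unspecified). Folds where a metric is undefined (single class) are excluded
from aggregates with a warning, never imputed. Aggregates are mean ± sd
across outer folds. Bootstrap 95% CIs are percentile intervals over 1000
pair resamples; single-class resamples are redrawn up to a retry cap.

## Downstream analyses

The promotion threshold is the smallest score whose precision on pooled
outer-fold CV predictions reaches the target (default 0.8); pooling gives a
single well-defined threshold where per-fold averaging would not. Ranked
hypotheses exclude — by a hard error, not a filter — any pair with an
observed outcome. Phase-score comparisons use two-sided rank-sum tests,
enumerated exactly when both groups have ≤ 10 scores and the tie-corrected
normal approximation otherwise (the branches agree to < 0.02 absolute
p-value at the boundary). Latent embeddings are exported as posterior-mean
factor vectors per entity for external 2-D embedding; dimensionality
reduction itself is out of scope.

## Numerical and reproducibility notes

Cholesky factorizations back all Gaussian draws; conditional precisions are
symmetric positive-definite by construction and a failure is reported as a
numerical error rather than patched. Wishart scale matrices are
re-symmetrized before sampling to suppress round-off drift. A single global
seed fans out to per-stage seeds by hashing stage names, so adding a stage
never perturbs another stage's stream; every experiment is a pure function
of its seed.

Problem sizes in the canonical studies (60×40×6 worlds, 150–200 burn-in and
retained sweeps, 5 outer folds) are the package's chosen desk-scale
conditions; the experiments complete in a few minutes on one CPU.

## Known limitations

- The Gaussian likelihood on binary cells is a deliberate simplification
  (as in the reference analysis); no probit/logit link is provided.
- All clinical failures are treated equally; the data model does not
  distinguish definitive failures from under-explored hypotheses.
- `select_rank` substitutes inner-CV AUPRC for the original unpublished
  rank heuristic.
- No connectors to live evidence/outcome resources; inputs are flat TSVs.
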