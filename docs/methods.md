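# Methods

This note documents the statistical machinery in `psychonectome`: what each
stage assumes, which knobs matter, and where the design was genuinely open.

## The model

The object of interest is a *psychonectome*: an undirected network over k
psychological subscale scores (default k = 25, spanning mindfulness,
compassion, well-being, distress and emotional/cognitive control
instruments) in which an edge is the partial correlation between two
subscales given all others — a Gaussian graphical model (GGM). A zero edge
means conditional independence; regularization (LASSO) drives small edges to
exactly zero so the surviving structure is interpretable. The pipeline
estimates one network layer per measurement occasion (pre/post an
intervention) and quantifies how the layers differ.

## Synthetic cohorts (module `synthgen`)

Real questionnaire data of this kind are rarely shareable, so the package
validates itself on cohorts drawn from a *planted network*:

- A target partial-correlation matrix is assembled from chains (paths of
  construct-to-construct dependence), blocks (communities) and individual
  signed edges. The precision matrix K has unit diagonal and
  `K_ij = -pcor_ij`. If K is not positive definite, the smallest ridge
  `delta·I` (binary search to 1e-8) bringing the minimum eigenvalue to 1e-6
  is added and the matrix rescaled to unit diagonal; this shrinks every
  weight uniformly by `1/(1+delta)` and keeps planted zeros at exactly zero.
  The *realized* matrix is the declared truth for all recovery tests, so no
  test ever chases an unattainable target.
- Where chains and blocks overlap on a pair, the chain weight wins (blocks
  fill only unset pairs); conflicting duplicates within the same spec kind
  are errors. This lets a strong path run through a weak community, which
  the demo scenario needs.
- Subjects are Gaussian copula draws: latent multivariate normals with the
  implied correlation matrix, discretized per margin by L-1 equal-probability
  normal thresholds (L = 5 by default, matching the dominant 5-point response
  format; L = 0 keeps continuous margins). Balanced margins are the neutral
  default; skewed margins can be passed as an explicit threshold vector.
- Paired occasions share a subject-level latent component:
  `z_occ = L_occ(sqrt(rho)·u + sqrt(1-rho)·e_occ)`, which preserves each
  occasion's own correlation structure exactly and gives per-node pre/post
  latent correlation `rho` when the two structures coincide. No empirical
  anchor exists for `rho` in this design, so the default 0.4 encodes
  moderate trait stability; it only affects paired-test power, not either
  layer's marginal structure.
- Missingness is MCAR: entries masked independently at rate 0.108 by
  default (the conventional overall missingness level for pre/post
  questionnaire batteries of this size).
- `random_sparse_network` draws random planted structures at a requested
  density with per-node absolute-weight budgets below 1. The budget keeps
  the precision matrix diagonally dominant, hence positive definite with a
  healthy margin, so requested weights are realized exactly. Without the
  budget, a random graph at 15% density with weights up to 0.45 is
  essentially always indefinite and the ridge repair would crush it into a
  near-singular structure.

What the generator does *not* emulate: item-level response processes
(subscales are the atoms), skewed or bimodal margins by default, MNAR
mechanisms, practice effects, or measurement non-invariance across
occasions. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under a faithful dependence structure — not robustness
to every pathology of real questionnaire data.

## Preprocessing (module `preprocess`)

- **EM imputation.** Scores are transformed per column to rank-based normal
  scores (Blom offset, mid-ranks for ties), a multivariate-normal EM runs to
  convergence (relative log-likelihood change < 1e-6, at most 100
  iterations, grouped by missingness pattern), and completed scores map back
  to the ordinal grid through each margin's cumulative-proportion
  thresholds. The default back-fill draws from the fitted conditional normal
  (stochastic regression imputation) with a fixed seed: deterministic
  conditional means are available via `method="mean"`, but mean-filling
  adds no residual noise to imputed entries and measurably inflates
  correlations among strongly related nodes (≈ +0.05 on r ≈ 0.3–0.5 pairs at
  10.8% missingness), which would bias every downstream network quantity.
  Conditional means remain the better choice when per-entry accuracy is the
  goal; the draw default optimizes correlation-structure fidelity, which is
  what the network estimator consumes.
- **Spearman matrix.** Pairwise-complete mid-rank Spearman correlations;
  non-PSD results are projected by eigenvalue clipping and re-standardized,
  and the repair is flagged (smallest auditable intervention; no shrinkage).
- **Polychoric matrix.** Two-step estimator: thresholds from marginal
  cumulative proportions, then pairwise latent correlation by maximizing the
  bivariate-normal cell likelihood with a bounded scalar search on
  (-0.999, 0.999), tolerance 1e-6. Rectangle probabilities use an Owen's-T
  decomposition of the bivariate normal CDF (exact-zero limits are nudged by
  1e-13 to avoid the removable singularity). Two-step rather than joint ML:
  standard, fast, and adequate at n ≈ 200.
- **Cronbach's alpha.** Standardized form `k·r̄/(1+(k-1)·r̄)` from the mean
  inter-item correlation of a (typically polychoric) matrix, computed per
  occasion.

## Network estimation (module `ggm`)

The estimator regresses each node's normal scores on all others:

1. Plain LASSO, penalty from a 50-point log grid spanning
   `[1e-4·λ_max, λ_max]`, chosen by K-fold (default 10) cross-validation
   with the **one-standard-error rule**. CV-minimum selection keeps
   noise-level predictors often enough that null edges survive the AND rule
   ~35% of the time; the 1-SE rule restores the sparsity that regularized
   psychometric networks are used for (null-edge inclusion < 10%, empty
   networks on fully independent nodes at n = 182).
2. Adaptive LASSO on the stage-1 support with penalty factors `1/|β₁ᵢ|`,
   penalty chosen by CV at the **minimum** (re-estimation on a cleaned
   support should not be shrunk further; this keeps recovered weights within
   ±0.07 of planted values at n = 2000).
3. AND-rule symmetrization: edge `w_ij = sign·sqrt(β_{j←i}·β_{i←j})` only
   when both directed coefficients are nonzero with a common sign — the
   standard identity linking nodewise coefficients to partial correlations
   (an OR rule is available behind a flag).

Regressing on normal scores (whose Pearson correlation tracks the Spearman
correlation of the raw ordinal data to ~0.01) is the subject-level
equivalent of feeding a Spearman matrix to the GGM, while giving CV and the
bootstrap actual rows to resample. With the penalty forced to zero the
estimator collapses to OLS and reproduces the matrix-inversion partial
correlations (`-K_ij/sqrt(K_ii K_jj)`), which is both a debug mode and a
standing oracle test.

All LASSO paths run through one JIT-compiled covariance-update coordinate
descent kernel (warm starts across the grid, coordinate-change tolerance
1e-10), verified against `sklearn.linear_model.lasso_path` to ~1e-11. The
seed fixes CV fold assignment, making every estimate deterministic. Edges
below 1e-8 in absolute value count as absent everywhere — LASSO produces
exact zeros, so the threshold only guards float noise.

## Topology (module `topology`)

- Expected influence is the one-step signed sum of a node's weights;
  strength is the absolute sum. Degree counts present edges; hubs are nodes
  at or above the 90th degree percentile (ties included; percentile
  configurable, since "highest degree" admits many cutoffs).
- Clustering is the Onnela geometric-mean form on absolute weights
  normalized by the network maximum (a Barrat variant is available behind a
  flagged argument in the output metadata sense: the variant used is always
  recorded). Efficiency uses edge lengths `1/|w|`; disconnected pairs
  contribute zero. Signs are dropped for distance purposes — an edge's
  magnitude, not its direction, carries the coupling strength.
- Path extraction keeps edges with `|w| ≥ 0.15` (just below the smallest
  path weight the planted scenarios use, 0.18), enumerates all maximal
  simple paths, ranks by total absolute weight and greedily picks up to five
  node-disjoint paths of ≥ 2 edges, with lexicographic tie-breaks. Dense
  thresholded graphs have exponentially many simple paths; past 500k
  extension steps the extractor falls back to a deterministic greedy
  strongest-edge procedure and warns. The selection rule as a whole is a
  reconstruction — visual path-tracing on published network figures follows
  no published algorithm — so it is documented here as this package's
  convention.
- The Fruchterman-Reingold layout (networkx, attraction ∝ |w|, seeded,
  rescaled to the unit square) is exported as coordinates only; no figure
  rendering.

## Communities (module `community`)

Signed spinglass detection minimizes the Reichardt-Bornholdt Potts
Hamiltonian with separate configuration-model null expectations per sign
layer (`p±_ij = s±_i s±_j / 2m±`), equal positive/negative importance, and
resolution γ. Because both layers enter linearly, the Hamiltonian reduces to
`H = -Σ_{i<j} J_ij δ(σ_i,σ_j)` with a precomputed coupling matrix J, which
makes single-node Metropolis updates O(1) per proposal via an incremental
node-by-community sum matrix. Annealing defaults: start temperature 1, stop
0.01, cooling 0.99, at most 25 spin states, k single-node sweeps per
temperature, followed by a zero-temperature greedy polish; all seeded. The
pipeline uses 10 restarts (best Hamiltonian wins); unit tests use 1. On
planted two-block instances with k ≤ 8 the annealer attains the exhaustive
minimum over all set partitions in ≥ 95% of seeds.

## Robustness (module `robustness`)

- **Predictability**: per-node adjusted R² (floored at 0) of OLS on all
  other nodes' normal scores — an absolute interconnectedness measure. All
  nodes are treated as Gaussian on the normal-score scale; the metadata
  records this choice.
- **Edge accuracy**: nonparametric bootstrap (subjects resampled with
  replacement, full re-estimation per replicate, 2.5/97.5 percentile
  interval widened to include the point estimate). Replicate b draws from
  substream (seed, b), so results are bit-identical for any worker count.
  Replicates that draw a constant column are redrawn (at most 10 times).
- **Case-dropping stability**: for each drop proportion, B subsamples
  without replacement are fully re-estimated and each centrality vector is
  correlated with the full-sample vector. The CS-coefficient is the largest
  proportion whose correlation stays ≥ 0.7 in ≥ 95% of subsamples — the
  established convention; both constants are arguments. A zero drop
  proportion reuses the full-sample fit, making its correlation exactly 1.
- Defaults B = 1000 (edges) and 500 (case-drop) follow common practice; the
  packaged demo and the test suite run B = 100/20 so that full pipelines
  stay desk-scale. The methods are B-agnostic; only interval smoothness
  changes.

## Pre/post comparison (module `compare`)

Paired Student t-tests run on raw subscale scores (matching how such tables
are reported; the network stages use transformed scores but mean change is a
raw-scale quantity), two-sided, df = n-1, with zero-variance differences
flagged rather than forced. No multiple-testing correction by default —
per-node raw p-values are the reporting convention here — with Holm
step-down behind a flag. Network reorganization is quantified by per-node
centrality deltas (top-5 movers per index), Pearson correlations of
vectorized upper-triangle edge weights and of each centrality index across
layers, and ARI/NMI between the layers' spinglass partitions.

## Pipeline (module `cli`)

`psychonectome all --demo` (or `--config run.yaml`) runs simulate/load →
impute → correlate → estimate both layers → topology → communities →
robustness → compare, writing every artifact (CSV/TSV/JSON/GraphML) plus a
manifest with package versions, seeds and a hash of the semantically
meaningful config. Runs are bit-reproducible: one config seed derives every
stage's stream. The demo scenario plants the two construct chains (weights
0.45–0.18) across five communities at the pre occasion — the chain node sets
cohere through weak (0.12) within-block edges so the chains remain the only
strong multi-edge structures, while the three non-chain communities are
dense enough (0.17–0.35) to be recovered reliably at n = 182 — and five
differently composed communities at post; n = 182, 5-point scales, 10.8%
MCAR.

## Numerical choices and degenerate inputs

- PSD repairs: eigenvalue clipping for correlation matrices (flagged),
  minimal ridge for planted precisions (condition applied before the
  unit-diagonal rescale, per the declared-truth convention above).
- Constant columns: errors that name the offending column (correlations,
  normal scores), or dropped with a warning (imputation).
- Edgeless networks: singleton communities with a warning; empty path list;
  zero efficiencies.
- Ties: mid-ranks everywhere; lexicographic tie-breaks in path selection;
  first-occurrence relabeling of community ids.

## Known limitations

- The nodewise CV estimator is slower than matrix-analytic alternatives
  (e.g. EBIC graphical lasso, deliberately out of scope) and its penalty
  choice is data-driven, so edge counts vary across seeds by a few edges.
- Percentile bootstrap intervals inherit LASSO shrinkage: coverage of strong
  planted edges measures ~97% at n = 500, but very weak edges near the
  selection boundary have asymmetric, occasionally degenerate intervals.
- The spinglass annealer is stochastic; identical data with different seeds
  can split one community differently. The pipeline's 10-restart default
  makes this rare at k = 25 but does not eliminate it.
- Problem sizes in the tests and the acceptance script (n = 500–2000,
  B = 100–200, 20-seed averages) are chosen as desk-scale validation runs;
  production analyses should raise the bootstrap counts to the module
  defaults.
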