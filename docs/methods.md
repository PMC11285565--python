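# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `memcpm`. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## The predictive procedure

Connectome-based predictive modeling is deliberately simple: univariate edge
screening, a one-dimensional summed-connectivity feature, and ordinary least
squares. Per cross-validation fold:

- **Selection** uses the *partial* Pearson correlation between each edge and
  the score, controlling for the configured covariates — by default per-scan
  maximum mean frame-to-frame displacement (FFD, mm), age (years) and their
  product. Both the edge column and the score are residualized on an
  intercept plus the covariates via a QR decomposition; the residual
  correlation is tested with $t = r\sqrt{\mathrm{df}/(1-r^2)}$,
  $\mathrm{df} = n - 2 - c$ ($c$ = number of covariates), two-sided
  $p < \alpha$ with $\alpha = 0.01$. With no covariates this reduces exactly
  to plain Pearson screening (a tested limit case). Covariates inform
  selection only; the fold-level prediction equation is score on summed
  connectivity alone. This is the convention of the covariate-adjusted CPM
  literature; a `covariates_in_model` flag adds the covariates to the fold
  OLS as a sensitivity variant.
- **Summed connectivity** is $\sum(\text{positive edges}) -
  \sum(\text{negative edges})$ ("combined" mode). The source protocol
  describes a single per-subject connectivity value while retaining signed
  edge sets; combined mode honors both. `positive`/`negative` single-set
  modes are provided for sensitivity analyses.
- **Degenerate folds** (no edge survives selection, or summed connectivity is
  constant in training) predict the training-mean score and are flagged,
  keeping the iteration ensemble intact instead of discarding data.
- **Folds** are unstratified uniform random partitions with sizes differing
  by at most 1 (stratification is not part of the protocol being modeled).
- **Median model**: iterations ranked by out-of-fold Spearman ρ ascending;
  the rank-⌈m/2⌉ iteration (lower median for even m) represents the model,
  ties broken by lower iteration index. Iterations with undefined ρ
  (all-degenerate) are excluded from ranking. These conventions are arbitrary
  but deterministic and documented.

**Cross-group transfer** re-runs the full fold-wise training inside the
source group each iteration; all k fold models predict every target-group
subject and their predictions are averaged before scoring. Applying a model
to its own group is a permitted degenerate case (resubstitution-style).

## Significance machinery

- Permutation null: the score vector is shuffled relative to (connectome,
  covariates). Shuffling outcomes rather than rows of the design preserves
  the confound structure under the null. Each permutation runs the full
  cross-validated procedure once; the unpermuted reference is the ensemble
  median, and $p = \#\{\rho_{null} \ge \rho_{median}\}/B$ (ties count
  against the model). $p = 0$ is displayed as $< 1/B$; the raw zero is kept
  in machine output.
- BH correction is the textbook step-up, applied within each subject group
  over the 7 scans × 3 scores = 21 models, and within each network over the
  7 scans for segregation. The implementation is direct (sort, cumulative
  minimum from the largest rank); a quadratic brute force and statsmodels'
  `fdr_bh` serve as independent cross-checks in tests.
- Female-vs-male performance distributions are compared with two-sided
  Wilcoxon rank-sum tests: exact enumeration for combined n ≤ 20 without
  ties, tie-corrected normal approximation otherwise (delegated to SciPy).

## Consensus edges and network summaries

An edge is *significant* for a sign when it is selected with that sign in at
least 2 of 5 folds in ≥ 40% of iterations. For non-default k the fold
minimum generalizes to ⌈0.4k⌉. "≥ 40%" is read inclusively (≥ 400 of 1,000).
An edge meeting the criterion in both signs keeps the sign with the larger
qualifying count; an exact tie removes the edge and logs it (the source
protocol never addresses this case; removal is conservative).

Between-network cells count significant edges between each network pair
normalized by pair capacity (|A||B| off-diagonal, |A|(|A|−1)/2 diagonal).
Within-network heatmaps sum signed fold-level selections over all
folds × iterations (bounds ±k·iters, the printed ±5,000 at 5 × 1,000); the
per-node summed vector is the row sum of the symmetric within-network matrix
divided by 2. The halving of a symmetric row sum is unusual but implemented
verbatim as specified; `halve_sv=False` offers the unhalved variant.

A caution established by the acceptance experiments: on a fixed dataset the
consensus rule behaves approximately like a full-sample p ≈ 0.01 threshold,
so it flags ≈ 1% of null edges as "significant" alongside the true ones.
Consensus edge lists are therefore trustworthy at the network-summary level
(where chance edges dilute across pair capacities) but not as a
false-discovery-controlled edge inventory.

## Association-ratio segregation

For network $V_k$ with weight matrix $w$:

$$\mathrm{AR}(V_k) = \frac{\sum_{i<j \in V_k} w_{ij}}
  {\sum_{i<j \in V_k} w_{ij} + \sum_{i \in V_k, j \notin V_k} w_{ij}}$$

The denominator is read as *all edges incident to the network* (within +
boundary, each edge once): "normalized by" suggests a superset denominator,
and this form is scale-invariant, equals 1 at perfect segregation and lies
in [0, 1] for non-negative weights. The strict boundary-only odds variant is
available via `denominator="boundary"`. Weights are raw signed Fisher-z
values — no thresholding or absolute value — so a near-zero denominator is
possible in principle; |den| < 1e−12 returns NaN and the cell is skipped.
Group comparisons default to the pooled-variance (Student) t-test with sign
convention t > 0 ⇔ female mean higher; Welch is a config option. The BH
family is the 7 scans within each network (the stated "7 significance tests
(for each model) across the 4 networks"); a pooled 28-test family is a
config option.

## The synthetic cohort

What it emulates: an aging-cohort fMRI study — n per sex (default 200), age
truncated-normal (mean 57, SD 14, range 36–100), per-scan FFD |N(0.12 mm,
0.06 mm)| so a realistic few subjects cross the 0.3 mm exclusion threshold,
seven scan labels, and three bounded integer memory scores. A latent
standardized memory propensity z drives everything: each score is a scaled
logistic of z plus independent noise (SD 0.5 latent units), rounded into its
legal range — monotone, so Spearman structure is preserved up to rounding
ties, with above-midpoint means as in healthy cohorts. Connectome edge
weights are baseline + βz on planted edges (per sex) + optional motion/age
confound leakage + i.i.d. N(0, σ²) edge noise, symmetrized with zero
diagonal, generated directly on the Fisher-z scale (the CPM-protocol
convention). The baseline is 0.25 with +0.15 within-network elevation —
plausible Fisher-z levels with block structure. σ = 0.25 reflects
across-subject edge variability at the upper end of test–retest estimates;
with the β = 0.5 effect used in the recovery experiments the implied
per-edge correlation is β/√(β²+σ²) ≈ 0.89 against the continuous propensity
(a closed form verified by Monte Carlo in the tests). All constants are
`GroundTruthSpec` fields.

What it does **not** emulate: hemodynamics, task block structure, spatial
autocorrelation between edges (edge noise is independent), scanner/site
effects, or demographic covariates beyond age and sex. A green recovery test
therefore establishes that the pipeline recovers linear edge signal under
independent noise — not that it would under realistic edge dependence. The
optional time-series mode samples multivariate-normal series from the
nearest-PSD-adjusted correlation target (eigenvalue clipping + diagonal
renormalization, projection distance reported) and exists to exercise the
connectome builder end to end, not to simulate fMRI.

The 10-network atlas (MF, FP, DMN, Mot, VI, VII, VAs, SAL, SC, CBL) ships
only as a synthetic stand-in: `synthetic_atlas` distributes nodes over the
networks in fixed plausible proportions; no real parcellation label table is
distributed.

## Numerical conventions

- Correlations are clipped to |r| ≤ 1 − 1e−7 before `atanh` (degenerate
  series give large finite z ≈ ±8.4, realistic values perturbed < 1e−7).
- An edge whose residual norm after covariate projection falls below 1e−8 of
  its raw norm is treated as constant/fully-confounded: partial r defined as
  0, never selected.
- Edge ordering everywhere is the strict upper triangle, row-major, 0-based
  (`np.triu_indices` order).
- Motion exclusion is strict (> 0.3 mm); a subject at exactly the threshold
  is kept. Missing FFD excludes the subject with reason `missing-motion`
  (conservative: unverifiable motion is treated as failing).
- All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds from the global seed and the (stage, group, scan, score) coordinates
  via `SeedSequence`, so any stage subset reproduces exactly and two runs
  with the same config are byte-identical in machine-readable outputs.

## Known limitations

- Only linear, unregularized CPM (no leave-one-out CV, no nonlinear or
  penalized variants — out of scope by design).
- The consensus edge list is not FDR-controlled (see above).
- Whether the modeled protocol entered covariates into the prediction
  equation, used combined vs separate signed models, or truncated negative
  weights in the segregation denominator is not documented at the source;
  each ambiguity is resolved by a documented default with the alternative
  behind a flag.
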