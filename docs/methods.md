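# Methods

This note records the models, the numerical choices, and the places where
the design was genuinely open — in enough detail that every number the
package produces can be traced to a decision made here.

## Synthetic data model

The generator emulates a two-class bulk microarray experiment. Log
intensity of gene *g* in sample *s* is

    log x_gs = μ0 + Δ·1[g < k, s cancer] + σ0 · z_gs,
    z_gs = sqrt(ρ)·u_bs + sqrt(1−ρ)·e_gs,

with `u_bs` shared across the genes of block *b* (consecutive blocks of
`block_size` genes), so genes within a block have correlation ρ on the log
scale. Intensities are `exp` of this: strictly positive, right-skewed and
heavy-tailed on the raw scale, as raw fluorescence intensities are.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_genes / n_cancer / n_normal | 2000 / 40 / 22 | the reference dataset's shape |
| n_informative, effect Δ | 50, 3.0 (natural-log units) | a clearly separable panel: Δ=3 is ≈ 20× raw fold change, typical of a strong tumour signature |
| μ0, σ0 | 8.6, 0.5 | raw-scale mean ≈ 6·10³, skewness ≈ 1.8, kurtosis ≈ 9 — matching the magnitude and the right-skew/heavy-tail regime of raw microarray summaries |
| block_size, ρ | 50, 0.3 | modest co-expression blocks; pooled off-diagonal gene–gene correlation stays small |

The informative genes are the *first* `n_informative` genes, shifted only in
the cancer class. What this emulates — and what it does not: classes differ
in **mean expression level** of a gene panel, with log-normal marginals and
block correlation. Real microarray data additionally carry array effects,
intensity-dependent variance, missing spots and class differences in
covariance structure; none of these are modelled. Consequences for
interpreting results are discussed under “Known limitations”.

The 85/15 train/test split floors the per-class **test** count
(`floor(0.15·n_class)`, remainder to training), which makes the counts
deterministic: 40/22 samples at 0.85 give 53 train / 9 test (6 cancer + 3
normal held out).

## Feature extraction

**STFT.** Each sample's gene-intensity vector, in input gene order, is the
"signal". Frames of length M = 256 start every hop = 128 positions; the tail
is zero-padded so the final partial frame is included, giving
`ceil((2000−256)/128)+1 = 15` frames. Each frame is multiplied by the
Blackman taper `0.42 − 0.5·cos(2πn/M) + 0.08·cos(4πn/M)` (period M, so
w[0] = 0 and, for even M, w[M/2] = 1) and discrete-Fourier transformed.
Per frame we keep mean |X|, max |X| and spectral energy Σ|X|² — 45 features.
Open choices made here: the per-sample-across-genes orientation (a
per-gene-across-samples alternative would not respect cross-validation),
and the three-statistic aggregation (the frame spectra themselves would be
3840-dimensional, defeating the purpose). Gene order is meaningful only in
the sense that co-located genes enter the same frame.

**LASSO.** Response is the ±1 class label (cancer = +1), centered; gene
columns are standardized. Cyclic coordinate descent with soft thresholding
minimizes `(1/2n)‖y − Xβ‖² + λ‖β‖₁`; after the first sweep the active set
is iterated, with full sweeps every tenth pass and at convergence
(`max |Δβ| < 1e-6`). λ runs down a 50-point log grid from
`λ_max = max|Xᵀy|/n` to `10⁻³ λ_max` with warm starts; λ is chosen by
10-fold cross-validated squared error (deterministic stratified folds), or
overridden by `target_n_features` (the smallest grid λ keeping at most that
many genes). Selected features are the **raw** intensities of the nonzero-β
genes. The inner loop is optionally numba-compiled; results are identical
either way.

**EHO wrapper.** Positions are continuous scores in [0,1]^2000; a position's
subset is its `n_select` top-scoring genes (ties to the lower index); the
fitness is the training MSE of a one-diagonal-Gaussian-per-class scorer on
the standardized candidate block, scored against the class targets. The
elephant-herding update moves every individual toward the working attractor
(`p += Υ·rand·(p_best − p)`), replaces the attractor by δ × the herd
centre, and re-seeds the worst individual uniformly (the raw draw spans
`p_max − p_min + 1` and is clamped). Defaults Υ = δ = 0.5, population 30,
100 iterations. A caveat measured during development: on strongly separable
data the wrapper fitness saturates at exactly 0 for many subsets, which
caps the selection pressure — recovery of a 20-gene informative panel is
11–13 of 20 across seeds, far above the chance expectation of 0.2 but not
complete. `n_select` defaults to 30 (also the minimum series length some
downstream classifiers need is easier to satisfy at 30, see DFA below).

## Optimizers

All four minimize over a box, clamp every emitted position, stop at
`max_iter` or when the best fitness reaches `mse_tol` (default 10⁻⁷, the
convergence criterion used for classifier training), and keep an **elitist
archive**: the reported best is the best position ever evaluated, so traces
are non-increasing even where an algorithm's own bookkeeping regresses
(EHO's attractor update δ·center can and does regress; the archive is the
reconciliation). Defaults for PSO (w=0.7, c1=c2=1.5, population 200,
1000 iterations), firefly (I₀=1, γ=0.1, β=0.6, α=0.1, population 200) and
FPO (δ=0.15, λ=1.5, ρ=0.65, population 200) follow the study's parameter
table.

Firefly: brightness is −fitness; for each ordered pair with *j* strictly
brighter, *i* moves by `β·exp(−γ r_ij²)·(x_j − x_i)` sequentially
(ascending index, in place), then one uniform perturbation `α·(rand−0.5)`
per dimension per iteration — so equally bright fireflies only random-walk,
and γ→∞ degenerates to a pure bounded random walk.

FPO: with probability ρ a global pollination step
`x + δ·L ⊙ (g_best − x)` with one Mantegna Lévy draw per dimension
(`s = U/|V|^{1/λ}`, `U ~ N(0, σ²)`, σ the closed-form Mantegna scale,
≈ 0.6966 at λ = 1.5), otherwise a local step `x + ε·(x_j − x_k)` with two
distinct partners. Moves are accepted **greedily** (only if they improve
that individual) — the acceptance rule was an open choice; greedy makes
convergence testable and keeps the population monotone.

## Classifiers

**Class targets.** Scores live on [0,1]; T_N = 0.85 and T_C = 0.1 with a
required separation ≥ 0.5. A probabilistic classifier's continuous score is
its posterior-weighted combination `p(normal)·T_N + p(cancer)·T_C`; the MSE
against each training sample's own target is the hybrid training loss.

**GMM.** One mixture per class, EM with seeded k-means++ initialization,
full covariances ridge-regularized by `1e-6·trace/D` on the diagonal
(escalated ×100 steps up to 1e-2 before declaring the component singular),
priors = class frequencies, G = 2 components per class by default (capped
at half the smaller class count). Prediction is Bayes' rule over the
per-class mixture densities; ties resolve toward cancer, as do all
tie-breaks in the package (sensitivity first).

**Hybrids (PSO/Firefly/FPO-GMM).** The study describes the metaheuristic as
changing the mixture's means, covariances and mixing coefficients; the
literal, testable reading implemented here optimizes the GMM parameter
vector: per class, flattened means, log diagonal covariances and weight
logits (softmax-decoded). The base EM fit uses diagonal covariances so the
encoding is lossless; the optimizer population is initialized at the EM
solution ± 0.1-scaled Gaussian perturbations (bounds at ±3 scales, scale =
per-dimension feature spread for means, 2.0 for the log terms), with the
exact EM vector as one individual — hence the tuned model's training MSE
never exceeds EM's. A zero-iteration budget returns the EM model verbatim.
On separable data EM already attains MSE 0 and the optimizers cannot
improve further; with overlapping classes (e.g. log-effect 0.7) FPO
strictly improves the EM loss in ≥ 8/10 seeds.

**DFA.** Profile = cumulative sum of the mean-removed series; window sizes
are integers from 4 up to length/4 in geometric steps of 1.6; windows
overlap 50%; each window is linearly detrended and F(n) is the RMS
fluctuation; the exponent is the log–log slope. Calibration: white noise
→ 0.5 ± 0.1, integrated noise → 1.5 ± 0.1 at length 4096. An all-constant
series yields a zero profile and is reported as exponent 0 with a
degenerate flag. Classification learns each class's mean exponent on
training rows (each sample's feature vector treated as a series — so at
least two ladder scales, i.e. ≥ 24 features, are required) and assigns the
nearer class mean. In the benchmark DFA sees **unstandardized** features:
per-column z-scoring would strip exactly the within-series structure the
exponent measures.

**NBC.** Gaussian naive Bayes in log space; every per-feature variance is
floored at `α × max feature variance` with α = 0.06 — the smoothing factor
interpreted as a variance floor, since Gaussian likelihoods have no count
smoothing to apply it to.

**SVM-RBF.** Kernel `exp(−‖x−z‖²/2σ²)`; SMO-style pairwise dual
optimization (KKT violation tolerance 10⁻⁵, random partner choice, stop
after 20 sweeps without an update), which preserves `0 ≤ α ≤ C` and
`Σ α_i y_i = 0` exactly. Defaults σ = 0.1, C = 1 per the study's table; at
the benchmark layer σ instead defaults to the median pairwise training
distance, because a fixed σ = 0.1 on z-scored features of 30–45 dimensions
makes every off-diagonal kernel entry vanish and the classifier degenerate
to the majority class.

## Evaluation

Pooled K-fold (default K = 10, valid 5–20, stratified): out-of-fold
predictions are pooled and the confusion matrix computed once, so metric
denominators equal the full sample count — the only convention consistent
with reporting accuracy as k/62 on a 62-sample design. All seven metric
formulas are the standard confusion-matrix expressions; degenerate
denominators (no predicted positives, a zero MCC margin product, chance
agreement 1) report 0 with a flag rather than NaN. Kappa bands: boundaries
belong to the upper band (0.2 → fair, 0.8 → very good).

Benchmark cells z-score features with training-fold statistics (except
DFA, above), cap mixture components by class counts, and use full
covariance only when every class has more samples than features (otherwise
diagonal — a full covariance would be rank-deficient). Hybrid cells run
with a scaled-down swarm budget (population 20, 30 iterations) — one
hybrid fit per fold × 21 cells makes the full table-scale budgets
(200 × 1000) pointless here, since the search starts at the EM optimum and
the elitist guarantee holds at any budget.

Feature statistics report per-class pooled mean, unbiased variance,
adjusted Fisher–Pearson skewness and bias-corrected Pearson kurtosis
(normal = 3), the mean off-diagonal Pearson correlation across features,
and the first canonical correlation between classes. CCA between classes of
unequal size has no natural pairing; the deterministic rule implemented —
truncate to the smaller class, order each class by per-sample mean feature
value, pair by rank — is an interpretation and is only used on synthetic
data. Whitening is ridge-regularized (1e-8), so CCA values match an exact
eigen-solution to ~1e-8, not machine precision.

## Known limitations

- The synthetic benchmark measures pipeline correctness, not clinical
  performance: classes differ only in mean level of a gene panel. In
  particular DFA — which classifies by autocorrelation structure — has
  almost no signal to use and performs near chance on most feature sets,
  and the 45-dimensional STFT summary carries its class signal in only the
  three frame-0 statistics (the informative panel occupies the first
  window), capping all classifiers near 0.8 accuracy on STFT features.
  Passing grids on LASSO/EHO features therefore show the pipeline works;
  they do not show STFT or DFA are competitive on real data.
- Feature extraction (LASSO, EHO) sees the full dataset before
  cross-validation, mirroring the study's pipeline ordering; the pooled CV
  metrics are therefore optimistic about generalization (selection bias).
  The 85/15 holdout split is available for unbiased estimates.
- The EHO wrapper fitness saturates at 0 on separable data (above), and
  the big-O complexity of the metaheuristic pipelines is documented
  nowhere here as an asserted property — runtime scaling was not a design
  target.
- No multiclass support, no probability calibration, no kernels beyond
  RBF, no CEL/GPR raw-format parsing, no normalization/background
  correction (upstream of this pipeline), and no fetcher for any public
  dataset: the loader reads delimited text matrices only.
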