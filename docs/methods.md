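# Methods

## The problem

Single-cell expression studies increasingly compare *individuals* — patients
vs. controls, severity grades, ages — rather than cells. Cells from the same
individual are correlated, so treating cells as independent replicates
inflates false positives, while pseudo-bulk aggregation (summing each
individual's cells and applying bulk RNA-seq machinery) discards everything
about the within-individual expression distribution except its mean. A gene
whose expression becomes more *variable* or more *frequently detected* in
cases, with an unchanged mean, is invisible to pseudo-bulk.

`discde` tests, gene by gene, whether the within-individual distribution of
expression is associated with individual-level variables of interest,
adjusting for covariates, with inference by permutation of individuals (the
exchangeable units).

## The test

Let X be the M × C count matrix for one cell subpopulation, with C_j cells
from individual j (j = 1…N), Y the N × p variables of interest and Z the
N × q covariates.

1. **Normalization.** Total-sum scaling: each cell's counts are divided by
   that cell's total, so columns sum to 1. No per-10k rescale is applied:
   the F statistic below is invariant to any common positive scaling of a
   feature, so the choice is immaterial (and is exercised by a test).
2. **Features.** For each gene i and individual j, K = 3 summaries
   w_{i,j,k} of the cell-level distribution: the proportion of zero cells,
   the mean of the non-zero normalized values, and their sample SD
   (denominator n − 1). The feature set is extensible at run time.
3. **Transforms.** u = g_k(w): a logit capped at ±7 for the zero proportion
   (exact ±7 at w ∈ {0, 1}, so no infinite intermediates), and a power
   transform w^ρ with ρ = 0.5 for the non-zero mean and SD.
4. **Per-feature F.** With H_D the orthogonal projection onto the column
   span of a design D, and writing 1 for the intercept,

       F_{k,i} = [Uᵀ(H_{1,Z,Y} − H_{1,Z})U / p] / [Uᵀ(I − H_{1,Z,Y})U / df],
       df = N − rank(1, Z, Y),

   the classical nested-model F computed via hat matrices.
5. **Omnibus.** F_{O,i} = max_k F_{k,i}: one composite statistic per gene
   covering all distributional aspects at once.
6. **Permutation p.** One plan of B permutations of 1…N (drawn uniformly
   with replacement from the permutation group; the identity is not
   excluded) is shared by all genes and features. Without covariates the
   rows of Y are permuted; with covariates, Smith's procedure is used: Y is
   residualized on (1, Z) column-wise, the residual rows are permuted, and
   the permuted residuals act as the variable of interest while Z stays in
   both projections. Then

       p_i = #{b : F^b_{O,i} ≥ F_{O,i}} / (B + 1).

   As printed, p = 0 is attainable; the conservative (1 + #)/(B + 1)
   convention is available via `pvalue_add_one`.
7. **Pooled-permutation FDR.** Sorting genes by decreasing F_O, the
   expected null count at threshold F_(i) is estimated from the pooled
   permutation statistics of all genes:

       q̃_(i) = max(#{(l, b) : F^b_{O,l} ≥ F_(i)}, 0.5) / (i · B),
       q_(i) = min_{j ≥ i} q̃_(j),

   mapped back to input order and capped at 1 for reporting (the raw value
   is kept). Ties among observed statistics are broken by stable gene
   order. The monotonicity step makes q non-decreasing along decreasing
   F_O, so thresholding q gives a contiguous top slice of the F_O ranking.

Sharing one permutation plan across genes is both what the pooled q̃ sum
requires and the main performance lever: the N × N projections are built
once per permutation, not once per gene, so the per-permutation cost for
all genes and features is two small matrix products.

### Numerical conventions

- A constant feature vector gives F = 0 (no evidence), not NaN, keeping the
  omnibus max defined; a perfect fit (zero residual with signal present)
  gives +inf, which sorts above every finite statistic.
- Quadratic forms below 1e-12 · (‖u‖² + 1) count as zero.
- The ≥ comparisons against observed statistics use a 1e-9 relative
  tolerance: a permutation can recreate the observed design exactly (e.g. a
  binary relabelling reproducing the same partition), making the permuted F
  mathematically equal but bitwise different; such numerical ties are
  counted as ties. This is also what makes the smith and plain schemes
  coincide exactly when Z is empty.
- Degrees of freedom are rank-based (df = N − rank(1, Z, Y)), which equals
  the textbook N − p − q − 1 for full-rank designs and stays correct for
  rank-deficient ones.
- An intercept is always added internally; user designs must not contain
  one.

### Design choices that were genuinely open

- **Sample vs. population SD** for the non-zero-SD feature: sample (n − 1).
  The F statistic absorbs the √(C_j/(C_j−1)) factor only when C_j is
  constant across individuals, so this is a real (documented) choice.
- **Degenerate individuals**: an all-zero individual contributes
  (zero_prop, mean, SD) = (1, 0, 0); a single non-zero cell contributes
  SD = 0. Zero is the fixed point of the power transform, so these keep U
  finite without special-casing downstream; both policies can be replaced
  by registering substitute features.
- **Smith's variant**: residualize-then-permute on the variable of
  interest. Residual-permutation schemes differ in detail across the
  literature; this variant is the one implemented, not asserted to be the
  only one.
- **Sparsity boundary**: a gene is removed only when its zero fraction
  strictly exceeds the threshold (default 0.8), i.e. "expressed in < 20% of
  cells" is removal.
- **Zero-total cells** are dropped with a warning rather than an error;
  they carry no information and occur in real data.

## The simulator

Counts are generated from a hierarchical zero-inflated negative binomial
model with three levels:

- **Population:** each gene carries (μ_i, φ_i, π_i, σ_i) on transformed
  scales — log mean, log dispersion, logit zero-probability, log of the
  between-cell SD of log-means — plus a 4 × 4 covariance Σ for the
  individual-level scatter.
- **Individual:** (μ_ij, φ_ij, π_ij, log σ_ij) ~ MVN with mean the gene's
  population vector and covariance Σ; a continuous covariate z_j ~ N(0, 1)
  shifts μ_ij by β z_j (default β = 0.1). The fourth coordinate is the
  *log* of σ so the SD stays positive under Gaussian sampling.
- **Cell:** log-mean ~ N(μ_ij, σ_ij²) (clipped to [−12, 6] before
  exponentiation); dispersion and zero-probability are inherited from the
  individual; the count is ZINB — zero with probability π, otherwise
  NB(mean m, size φ) with variance m + m²/φ, drawn via the exact
  gamma–Poisson mixture.

Half of the individuals (a random half) are cases. Per DE type
(mean / variance / both), a disjoint random 5% of genes is selected; each
DE gene is up- or down-regulated with equal probability. Mean-type genes
shift case μ_ij by ±log f; variance-type genes scale case σ_ij by f^±1;
"both" applies the two with one shared sign. f = 1 injects nothing and is
the global null.

**Default population parameters.** Real-data parameter estimation is out of
scope, so defaults are drawn from documented distributions:
μ_i ~ N(0.3, 1.0²), φ_i ~ N(0, 0.4²), π_i ~ N(−2, 0.8²),
log σ_i ~ N(log 0.35, 0.25²), Σ = diag(0.15², 0.10², 0.30², 0.10²). These
were chosen so that marginal gene sparsity falls mostly inside the
80%-sparsity filter (checked empirically: > 85% of generated genes
survive), per-gene mean counts span roughly 0.1–10 as in a typical
moderately expressed scRNA-seq panel, and between-individual variability is
modest but non-zero. They are configuration, not claims about any
particular tissue; every value can be overridden via a parameter TSV.

**Randomness architecture.** The master seed spawns independent child
streams per stage (population, individual draws, design, DE selection,
baseline counts, DE-block counts). Baseline counts are always emitted under
*null* parameters; DE gene × case-individual blocks are then regenerated
from their own stream with the shifted parameters. Because the NB/Poisson
samplers consume a parameter-dependent amount of their stream, this
separation is what makes two same-seed datasets at different fold changes
differ only in DE genes' case cells — a property the tests assert exactly.

**What the simulator does not emulate:** varying cell numbers across
individuals within one dataset, batch effects, doublets, ambient RNA,
gene–gene correlation (genes are conditionally independent given the
individual parameters), or library-size gradients unless a per-cell size
factor SD is switched on. Calibration and power results on this generator
therefore demonstrate correctness of the inference machinery under the
model's assumptions, not robustness to every artefact of real data — the
strongest claims that transfer are the permutation-based ones (type-I and
FDR control under exchangeability), which do not depend on the ZINB shape.

## The evaluation harness

A run = generate → filter (> 80% sparsity) → test → score. Scoring at
α = 5% and FDR target 10%: type-I error is the fraction of truly null genes
with raw p < α (averaged over runs; a pooled-across-runs variant is also
reported); FDP = FP / max(TP + FP, 1); TPR = TP / (TP + FN), overall and
per DE type. Genes removed by the sparsity filter are excluded from
scoring: they were never tested. Under a global null the mean FDP equals
the fraction of runs with any positive call (each run's FDP is 0 or 1),
and the harness asserts this identity. Per-run seeds derive
deterministically from (master seed, scenario index, run index).

**Problem sizes.** The package's standard study scale is 1000 genes,
24 individuals, 375 cells/individual, B = 99 permutations, with 100 runs
for null calibration and 20 runs per signal scenario; all reported rates
are proportions and do not depend on the gene count. The `--full` CLI flag
scales a study to 8000 genes, B = 999 and 1000 null / 50 power runs.

## Known limitations

- The permutation p-value as printed can be exactly 0; use
  `pvalue_add_one` when a strictly positive guarantee is needed.
- With B = 99 the smallest attainable q̃ at rank 1 is 0.5/99 ≈ 0.005;
  finer FDR resolution needs larger B.
- Features are tested marginally and combined by max; the omnibus does not
  model feature correlation (it does not need to — the permutation null
  preserves it), but per-feature F values are not independent evidence.
- Cells must arrive pre-assigned to a subpopulation; clustering and
  annotation are out of scope, as is h5ad ingestion.
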