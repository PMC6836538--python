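# Methods

This note documents the statistical machinery of `dese`, the choices made
where the design was genuinely open, and what the simulation-based tests do
and do not establish.

## Inputs and summarization

The pipeline consumes (1) a multi-tissue expression matrix (GCT 1.2 or TSV;
TPM units assumed, missing cells allowed in TSV), (2) GWAS summary statistics
(variant id, chromosome, position, p-value), (3) a gene model (1-based
inclusive coordinates; BED input is converted by `start+1`), and (4) an LD
reference — either reference-panel genotypes in VCF (Pearson correlation of
allele dosages) or precomputed per-block correlation matrices. All
coordinates must share one genome build; the package performs no liftover or
allele harmonization.

Expression is reduced per feature to per-tissue means `y_i` and standard
errors `s_i` (sample SD with n−1 denominator over √n). A tissue with a
single subject gets `s_i = 1` by convention. Identical replicates would give
`s_i = 0` and infinite downstream z-scores, so SEs are floored at
`1e-6 × (global mean expression + 1)`; affected features are flagged.

QC helpers mirror common multi-tissue hygiene: a TPM floor filter (drop
features ≤ cutoff in all tissues, or < cutoff in ≥ k tissues), exclusion of
tissues whose *median* Pearson correlation with the other tissues falls below
a threshold (default 0.3 — a median is robust to one aberrant pair; the
numeric cutoff is this package's choice, as published analyses report only
which tissues were excluded), a per-sample rank-to-normal transform
(`Φ⁻¹((rank − 0.5)/G)`, average ranks for ties), removal of samples whose
median pairwise correlation falls outside the 5%/95% quantiles of the pooled
pairwise-correlation distribution within a caller-defined group, and removal
of features with ≤ 9 observations.

## Selective-expression measures

**REZ.** Sorted ascending (stable sort, tissue label breaking ties, so
results are deterministic), a non-selective gene's tissue means approximately
follow a line in their rank; selective tissues deviate from it. The line is
fitted by iteratively reweighted least squares with Huber weights:

    y_(i) = β₀ + β₁·i + e_(i),   i = 1…N
    w_(i) = 1/s_(i)            if |u_(i)| ≤ k
    w_(i) = k/(s_(i)·|u_(i)|)  otherwise,   u_(i) = e_(i)/s_(i)

with `k = 1.345 ×` the standard deviation of the current weighted residuals
`w_(i)·e_(i)`, recomputed every iteration. The cutoff is applied to the
SE-standardized residual `u`, not the raw residual: this makes the procedure
invariant to the measurement units of `y` and `s` (rescaling both by any
constant leaves all scores unchanged) and reduces exactly to the classic
homoscedastic Huber rule when all SEs are 1, e.g. under the single-subject
convention. Applying the cutoff to raw residuals instead is not
unit-invariant, and with TPM-scale SEs its `k` recursion contracts
geometrically until all weight collapses onto one tissue — an artefact, not
robustness.

IRLS details: weights initialise at `1/s_(i)` (plain weighted least
squares); iteration stops when the largest *relative* weight change drops
below 1e-6 (relative, so the stopping rule is also unit-invariant) or after
100 iterations; if `k` reaches 0 (an exact linear fit, or degenerate
weights) the current weights are frozen. Gross outliers converge slowly
(the weight decays linearly per iteration); the returned weights at the
iteration cap are well-behaved and the `converged` flag records the state.

The converged weights, normalised to `ẁᵢ = wᵢ/Σwⱼ`, give the robust mean
`μ̂_w = Σ ẁᵢ yᵢ` and robust SD
`σ̂_w = √(Σ ẁᵢ(yᵢ−μ̂_w)² / (1 − Σ ẁᵢ²))`, and the score

    z̀ᵢ = (yᵢ − μ̂_w) / (σ̂_w · λ),   λ = √1.5 (configurable),

with two-sided standard-normal p-values. λ is an empirical calibration
constant: with 50 i.i.d. standard-normal tissue means per feature and unit
SEs, the null p-values are approximately uniform — empirical type-I ≈ 0.044
at nominal 0.05 and ≈ 0.010 at nominal 0.01, with a maximal CDF deviation
from uniform of ≈ 0.03. The calibration is thus best at the stringent
thresholds actually used for selectivity calls, and the marginal deviation
is real: a pooled Kolmogorov–Smirnov test at very large n rejects exact
uniformity, as the acceptance suite records. Calibration also degrades when
SEs are much smaller or larger than the between-tissue spread of the means
(the weighting then under- or over-saturates), which is the main caveat for
heteroscedastic real data.

Degenerate features (constant means, or one tissue holding all weight so
`Σẁᵢ² = 1`) receive score 0 and p 1 with a flag rather than NA, keeping
rank-based downstream steps total.

**Conventional z** `(yᵢ−μ̂)/σ̂` (n−1 SD, λ = 1), **MAD z**
`|yᵢ−M| / (1.4826 × median |yⱼ−M|)` with exact-zero deviations removed
before the median so the MAD cannot collapse (the sign of `yᵢ−M` is
recorded in a companion field), and **RVP** `yᵢ²/Σyⱼ²` complete the measure
set. MAD z and RVP carry no p-values. When a gene has several transcripts,
the transcript with the largest score represents the gene per tissue, the
representing transcript id is recorded, and its p-value is carried over.
Selectivity calls are Bonferroni-corrected: per gene over its transcript
count at transcript level, over the gene count at gene level (the gene-level
rule is this package's choice).

## Gene-based association (ECS)

Variants within `flank` bp (default 5 kb) of a gene's body are assigned to
it; a variant may serve several overlapping genes; cross-chromosome LD is 0.
Each variant p becomes a 1-df chi-square `q_k`; the gene statistic is
`T = Σ q_k`. For jointly normal variant z-scores with correlation matrix R,
the null law of T is exactly `Σ λᵢ χ²₁` with `λᵢ` the eigenvalues of R
(`cov(χ²ᵢ, χ²ⱼ) = 2r²ᵢⱼ`). The upper tail is approximated by three-moment
(skewness-matching) chi-square approximation, which is exact for a single
variant and for m variants in perfect LD (both collapse to the
single-variant p) and calibrates to ≈ 0.052/0.010 empirical type-I at
nominal 0.05/0.01 under blocked LD. Two-moment (Satterthwaite) matching was
measurably anticonservative (≈ 0.055 at 0.05) and was not retained. Input
p-values of 0 are clamped to 1e-300 with a warning. Note the approximation
is not exactly invariant to duplicating one variant among several; the
perfect-LD collapse is exact only when all variants coincide.

**Conditional ECS.** Genes enter in the caller-supplied order. Summary
p-values carry no effect direction, so z-scores are unsigned,
`|z| = Φ⁻¹(1−p/2)`; the magnitude removed by conditioning is therefore an
upper bound on the association genuinely explained by the selected genes —
a documented limitation of direction-free inputs. For a candidate with
variants c and selected-variant set s:

    z_resid = z_c − R_cs R_ss⁻¹ z_s
    R_resid = R_cc − R_cs R_ss⁻¹ R_sc

`R_ss` gets a ridge of 1e-6 before inversion (the condition number is
logged); residual variances are floored at 1e-4 before renormalising to a
correlation matrix; ECS on the standardized residuals gives the conditional
p. A gene is selected when its conditional p passes Bonferroni
`α / (number of genes in the queue)`. Genes with unconditional p above a
permissive screen (default 0.01) skip the quadratic-cost projection and keep
`cond_p = raw_p`; with an empty selected set the conditional p equals the
unconditional p exactly.

## Tissue enrichment, ranking score, and the loop

Per tissue, a one-sided Mann-Whitney U test compares the selective-expression
scores of the conditionally significant genes against all other profiled
genes (genes absent from the profile are excluded from both groups). The
exact null distribution is used when the smaller group has ≤ 25 members and
the total is ≤ 1,000: SciPy's exact method when the scores are tie-free,
full enumeration of label assignments when ties are present and the
combination count stays below 2×10⁵; otherwise the normal approximation with
tie and continuity corrections.

The ranking score `s_j = Σᵢ (k_{j,i}/Tᵢ)·(−log₁₀ pᵢ)` uses ascending average
ranks (tied genes contribute equally) over *all* N tissues of the current
iteration — non-significant tissues contribute little because `−log₁₀ p ≈ 0`.
Genes lacking a score in a tissue contribute 0 there and fall back to
(descending s_j, ascending conditional p, gene id) in the entry queue, which
makes re-ordering fully deterministic.

Iteration 0 orders genes by ascending unconditional gene p. Each subsequent
iteration re-runs the conditional analysis over the same candidate pool in
descending-s_j order, then re-tests all tissues. Convergence is declared
when `max over tissues |Δ(−log₁₀ p)| < tol` (default 0.01) between two
consecutive iterations, with a hard cap of 20 iterations; the exact
convergence rule is this package's quantification of "p-values stop
changing". If no gene is significant at iteration 0 the run returns an
empty driver report with `converged=False` rather than raising. Planted
simulations typically converge in 2–4 iterations.

`prioritized_genes` flags genes that are simultaneously (a) conditionally
significant and (b) selectively expressed in at least one significant driver
tissue (tissue p < α/N).

## Synthetic data

The generator emulates the structure the method assumes, not any particular
real dataset. Expression: per feature a baseline log-mean ~ N(2, 1), shared
across tissues; between-tissue noise N(0, 0.3) on the log scale (a
variance-matched uniform option exists); each tissue's planted selective
genes (disjoint sets, 2% of genes per tissue by default) get a
`selective_effect × tissue_sd` upward shift (default 5 SD) in their tissue;
10 samples per tissue with N(0, 0.5) log-scale noise, exponentiated to
TPM-like positives. GWAS: 10 variants per gene tiled through non-overlapping
gene bodies (10 kb genes, 20 kb gaps, 50 genes per chromosome); consecutive
variants form exchangeable-correlation LD blocks (size 20, ρ = 0.5);
z-scores are multivariate normal with covariance R and mean `R·ncp`, where
the non-centrality (6 by default) sits on the 8 causal genes' variants — the
`R·ncp` mean is what makes LD neighbours of causal genes show inflated
("shadow") signal, the redundancy the conditional test must remove. Causal
genes are drawn from the driver tissue's selective set (`causal_overlap = 1`
by default). Everything is deterministic given the seed, with independent
substreams per stage.

What the generator does *not* emulate: realistic between-tissue covariance
(tissues are exchangeable given the baseline), mean–variance relations of
RNA-seq counts, realistic LD maps, sample-size imbalance across tissues, and
signed effect directions. Passing tests therefore demonstrate correctness of
the machinery and recovery under the stated conditions, not performance on
any specific real cohort. One known interaction: the log-normal tissue noise
is right-skewed on the raw TPM scale, so null REZ p-values on generator
output are mildly anticonservative at stringent thresholds (≈ 3% at nominal
1%) even with no planted signal — a property of applying a
normal-majority model to skewed data, visible in real TPM matrices too.

## Default problem sizes

The simulation experiments are sized to run comfortably on one CPU: null
calibration at 5,000 features × 50 tissues, gene-test calibration at 10,000
draws, shadow-removal at 20 runs, and end-to-end recovery at 50 seeds of the
default 20-tissue × 500-gene planting (≈ 1 s per run). At those defaults the
planted driver ranks first in ~100% of runs and ~94% of planted causal genes
are prioritized.

## Known limitations

- Unsigned conditioning (no betas) over-removes shared association in the
  worst case; conditional p-values are conservative for genes in LD with
  selected genes.
- REZ p-values are approximate; their calibration depends on the ratio of
  expression SEs to the between-tissue spread and on the symmetry of the
  majority distribution.
- The Wilcoxon background is "all other profiled genes"; restricting it to
  genes with GWAS coverage is a caller decision (pass a filtered profile).
- The tissue-correlation QC threshold (0.3) and the convergence tolerance
  (0.01 on −log₁₀ p) are pragmatic defaults, both configurable.
- The ECS tail approximation is moment-based; for extremely small p-values
  (< 1e-300 inputs) values are clamped rather than computed in extended
  precision.
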