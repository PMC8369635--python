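# Methods

## Problem setting

Case-control single-cell RNA-seq data are hierarchical: cells belong to
individuals, and individuals — not cells — carry the disease label
W ∈ {0, 1}. Differential expression between conditions is therefore an
individual-level comparison of pseudo-bulk profiles λ_gi (the mean
activity of gene g in individual i). In observational cohorts, unknown
covariates can drive both the label assignment and the expression levels,
confounding the comparison. This package estimates, per gene and
individual, a multiplicative decomposition

    λ_gi = μ_gi · δ_gi

where μ_gi is a label-invariant confounder component and δ_gi is the
residual disease effect, and tests δ across individuals. The key
identification device is counterfactual matching: every cell is paired
with its nearest cells from the opposite condition, the unobserved
potential profile Ŷ^(1−w) is imputed from those matches, and μ is defined
as the component shared by the observed and imputed sides.

## Count model and variational posteriors

Counts follow Y_gj ~ Poisson(λ_gi ρ_j), with ρ_j a per-cell sequencing
depth. λ and ρ carry conjugate Gamma(1, 1) priors; under a fully factored
variational posterior the means satisfy

    E[λ_gi] = (Σ_{j∈S_i} Y_gj + 1) / (Σ_{j∈S_i} E[ρ_j] + 1)
    E[ρ_j]  = (Σ_g Y_gj + 1) / (Σ_g E[λ_gi(j)] + 1)

initialized at E[ρ] = 1 and alternated to convergence. The unit
pseudo-counts are the prior's contribution; a weaker Gamma prior is
exposed (`prior` argument) but defaults off because it destabilizes
shallowly sequenced cells. Zero-inflation is deliberately not modelled:
the data stay a count matrix throughout.

Stopping rule (not stated in the original description of the model; this
package's choice): maximum relative change of both parameter blocks
below `tol` (default 1e-6), at most `max_iter` (default 100) sweeps;
non-convergence returns the last iterate with a flag. The updates are
computed in vectorized per-individual blocks; the result is independent
of block order.

## Step 1 — matching and counterfactual imputation

Cells are embedded by a truncated SVD of the transformed count matrix and
each cell's k nearest neighbours (Euclidean distance) among
opposite-condition cells are found. Design choices:

- **Transform** (not specified by the original method): log(1+Y) per
  entry, then each cell column scaled to unit L2 norm
  (`transform="log1p_unit"`), which makes distances robust to sequencing
  depth. `raw` and plain `log1p` are available.
- **SVD**: ARPACK (`scipy.sparse.linalg.svds`) with a seeded start vector
  — deterministic and accurate even on the flat singular spectra of
  Poisson count matrices; dense SVD when the requested rank equals
  min(G, J). Cell coordinates are right singular vectors scaled by
  singular values. Defaults rank = 50 and k = 100 follow the published
  real-data analysis; the simulation experiments here use k = 50, the
  point at which ranking performance saturates under strong confounding.
- **kNN**: exact brute force up to 5,000 cells (the regime of all tests
  here); a graph-based approximate index (pynndescent, seeded) above.
  Distance ties break deterministically toward the lower cell index.

For each cell j (observed under condition w), the matched cells' profiles
form features F_gm = log(1 + Y_gm) and a per-cell Poisson regression

    Y_gj ~ Poisson(exp(β0 + Σ_m F_gm β_m))

is fitted across genes by coordinate-wise descent: the log-likelihood is
re-linearized at the current fit (Newton weighting) and cyclic coordinate
descent solves each quadratic; a small L2 penalty (`ridge`, default 1e-4)
on the slopes — never the intercept — stabilizes the collinear matched
features. Because the intercept is unpenalized, the fitted totals obey
Σ_g Ŷ_gj = Σ_g Y_gj exactly at convergence. The imputed potential profile
is Ŷ_gj^(1−w) = exp(β̂0 + F β̂), ignoring residual noise.

A non-parametric alternative (`method="knn_average"`) takes the
inverse-distance-weighted mean of the matched counts, rescaled to the
query's library size.

**Known behaviour**: the regression imputer's features are noisy
(Poisson) readings of the underlying log-means, so its fitted slopes are
attenuated and imputed profiles shrink toward the grand mean — lowly
expressed genes are over-predicted and highly expressed genes
under-predicted in relative terms, even with no disease effect and no
confounding. Per-cell totals and the gene ranking are preserved, and the
downstream decomposition is unaffected in rank terms (μ and δ estimates
pool observed counts with the imputed side only through sufficient
statistics). The kNN-average imputer is mean-unbiased under the null and
is the reference for the unbiasedness checks.

## Step 2 — shared confounder

Observed and imputed profiles are modelled jointly, each side with its
own condition-specific depth:

    Y_gj^(w) ~ Poisson(μ_gi ρ_j^(w)),  w ∈ {0, 1}

with μ shared — hence label-invariant by construction. Variational
updates mirror the pseudo-bulk ones with both sides summed in the
numerator/denominator. Imputed values enter only through their sums, so
they need not be integers (the Poisson normalizing constant is irrelevant
to the variational means).

## Step 3 — residual disease effect

Fixing μ̂ at its posterior mean, the observed counts are re-modelled as
Y_gj ~ Poisson(μ̂_gi δ_gi ρ_j), giving

    E[δ_gi]    = (1 + Σ_j Y_gj) / (1 + μ̂_gi Σ_j E[ρ_j])
    E[ln δ_gi] = ψ(1 + Σ_j Y_gj) − ln(1 + μ̂_gi Σ_j E[ρ_j])
    V[ln δ_gi] = (Σ_j Y_gj)^{-1}

(ψ the digamma function). The depth update uses a single unit
pseudo-count in the numerator, the same form as every other update. The
ln-scale summaries require at least one read for the individual (the
Gaussian approximation of the Gamma posterior needs α > 1); (g, i) pairs
with zero reads keep a pseudo-count-defined E[δ] but NaN ln-scale
summaries and drop out of the meta-analysis.

## Gaussian approximation and meta-analysis

For λ ~ Gamma(α, β), a quadratic expansion of the log-density of
ϕ = ln λ at the mode gives ϕ ≈ N(ln((α−1)/β), (α−1)^{-1}) for α > 1; for
0 < α ≤ 1 the expansion moves to the mean: N(ln(α/β), α^{-1}).

Per-individual posteriors (η_i, σ_i²) of ln δ combine across individuals
by inverse-variance weighting:

    ADE = Σ_i η_i/σ_i² / Σ_i 1/σ_i²,   SE = (Σ_i 1/σ_i²)^{-1/2}

and the gene-level Wald statistic is Z = ADE/SE. Per-individual
standardized effects default to the Wald convention E[ln δ]/√V[ln δ];
the E/V form is available (`z_mode="ev_ratio"`).

## Testing and evaluation

Genes are ranked by a two-sided Wilcoxon rank-sum test on E[δ_gi] between
case and control individuals (exact null distribution when n1+n2 ≤ 12
without ties; tie- and continuity-corrected normal approximation
otherwise — every realistic cohort is on the asymptotic branch).
Multiplicity control: Benjamini-Hochberg (default), Storey q-values with
the fixed-λ = 0.5 π0 estimator (chosen over the spline smoother for
dependency-free determinism), Bonferroni and Holm for family-wise error.

Evaluation metrics for simulation studies: AUPRC by trapezoidal
integration of the precision-recall curve with tied scores grouped into
single curve points, and empirical FDR — the fraction of truly non-causal
genes among q < 0.01 discoveries, defined as 0 when nothing is
discovered.

## Cell-type stratification

When an annotation is provided, the entire pipeline — including matching —
runs independently within each cell type, because confounder structure
may be cell-type-specific. A stratum whose individuals carry only one
label violates the overlap assumption and is skipped with a warning.

## Cell-type annotation

Cells are classified on the unit sphere of their marker-gene profiles
(log(1+Y) restricted to marker genes, L2-normalized; all-zero cells are
flagged unassignable). Each type k is a mean direction θ_k constrained to
the support of its own markers, with one shared concentration κ. A
stochastic EM alternates sampling hard assignments z_j ∝ exp(κ m_j·θ_k)
with the constrained mean update and the closed form
κ = (r d − r³)/(1 − r²), where r = ‖Σ_j m_j‖/n is the global resultant
length — assignment-independent, so κ is set once from the data (a
deliberate simplification of the classical per-component estimate; r is
capped at 1 − 1e-8). The sampling weights include κ, consistent with the
stated likelihood (`kappa_in_estep=False` reproduces the κ-free variant).
Defaults: 100 steps, burn-in 50, modal assignment over the last 10
E-steps; empty clusters reinitialize at their marker centroid.

## Simulation framework

Individual covariates split into confounders X (affecting label and
expression) and batch effects B (expression only), all standard normal.
The label model draws α and ε_W from isotropic Gaussians, orthogonalizes
ε_W against Xα and rescales it so the realized variance ratio
V[Xα]/V[Xα+ε_W] equals σ²_{X→W} exactly per replicate, then
W_i ~ Bernoulli(sigmoid(Xα + ε_W)) (the sign of the logit is
distributionally irrelevant because α is symmetric about zero).
Expression means follow

    ln λ_gi = τ_g W_i + Σ_k X_ik β_kg + Σ_l B_il γ_lg + ε_λ

with β, γ ~ N(0, σ²_{X,B→Y}/(d_C+d_B)), τ_g ~ N(0, σ²_{W→Y}) on a random
subset of n_causal genes (exactly zero elsewhere, drawn once per gene and
individual-invariant), and ε_λ ~ N(0, 1−σ²_{X,B→Y}−σ²_{W→Y}). Cells per
individual are Poisson around the configured mean with floor 1
(`fixed_cells=True` for exact counts); depths ρ_j ~ Gamma(6.25, 6.25)
(mean 1, variance 0.16); counts Y_gj ~ Poisson(λ_gi ρ_j). Everything is a
pure function of (config, seed).

What the simulator does **not** emulate: cell-type mixtures within an
individual, gene-gene correlation beyond the shared covariates,
zero-inflation or technical dropout beyond Poisson sparsity, and
cell-level state variation within an individual (all cells of an
individual share λ_gi). Passing tests therefore demonstrate confounder
recovery and calibration under the stated generative model, not
robustness to arbitrary real-data artefacts.

## Study-scale test conditions

The end-to-end statistical checks run at 2,000 genes / 50 causal / 40
individuals / ~50 cells per individual, σ²_{X→W} = 0.5, σ²_{X,B→Y} = 0.5
(d_C = 5, d_B = 0), σ²_{W→Y} ∈ {0.2, 0.3}, five replicate seeds (three
for the k-sensitivity comparison), with rank 50 and k = 50. These sizes
were chosen as the smallest cohort at which the power ordering and
calibration behaviour are stable across seeds.

## Numerical details

- Linear predictors in the Poisson regression are capped at 30 on the log
  scale; an all-zero response returns slopes 0 with intercept −30.
- Newton/coordinate steps are clipped to ±2 per outer iteration.
- All fixed-point iterations report a convergence flag instead of raising
  on `max_iter`.
- Distance ties in matching and score ties in AUPRC are handled
  deterministically (lower index; tie-grouped curve points).
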