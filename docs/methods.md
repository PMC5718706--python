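# Methods

## The mixture model

A bulk expression vector is modeled as a linear superposition of
cell-type expression profiles, `b = C × p`, with m mixture components of
which m−1 (immune, stromal, endothelial types) have known reference
profiles and one — the uncharacterized component, chiefly cancer cells —
does not. All quantities are TPM-normalized: per sample,
`b̄_i = 10⁶ · (b_i/l_i) / Σ_k (b_k/l_k)` with gene lengths l in
kilobases, and reference columns likewise sum to 10⁶. Under this
normalization the transformed proportions p̄ are shares of total mRNA and
sum to exactly one, which is what lets the uncharacterized share be read
off as a complement.

The fit is restricted to signature genes S, chosen so that
uncharacterized cells express them negligibly. On S the unknown column
drops out and the characterized mRNA shares p̄\* minimize the weighted
residual `Σ_{i∈S} w_i (b̄_i − (C̄* p̄*)_i)²` subject to `p̄*_j ≥ 0` and
`Σ p̄*_j ≤ 1`. The weights favor reproducible signature genes:
`u_i = Σ_j C̄*_ij/(V̄_ij + ε)` and `w_i = min(u_i, 100·median(u))`, the
cap keeping a handful of near-constant genes from dominating the
objective. ε defaults to 1e-9 (configurable); it only guards the
division and is irrelevant once any variability entry is ≳ 1e-6.

The uncharacterized mRNA share is `p̄_m = 1 − Σ_j p̄*_j`. mRNA shares are
converted to cell-number fractions by `p_j = α·p̄_j/r_j` where r_j is the
per-cell mRNA mass in pg and α normalizes the result to sum to one.

## Normalization conventions

Both the bulk columns and the reference columns are rescaled to sum 10⁶
over the **shared** gene universe before subsetting to S, and the
reference variability is rescaled by the same per-column factor (it is a
TPM-scale quantity). A consistent normalization universe on both sides
is required for the `Σ p̄ = 1` identity to carry through when bulk and
reference annotations only partially overlap. Gene matching is exact,
case-sensitive string equality, with an optional uppercase pre-pass;
duplicate gene rows in input tables are collapsed by arithmetic mean
(symmetric and order-independent). Signature genes with zero expression
in every characterized reference type carry no information and are
dropped with a warning before weighting.

## Solver

The problem is a small convex QP (m−1 variables, typically < 10), so the
library choice cannot change the answer — only fail to reach it. The
default path runs SLSQP on the weighted, scale-normalized problem, then
re-solves exactly on the identified active set (an equality-constrained
least-squares / KKT linear solve) and accepts the polished point only
when primal feasibility and the KKT multiplier signs check out. If SLSQP
fails to converge or the polish is rejected, an accelerated
projected-gradient solver (projection onto {p ≥ 0, Σp ≤ 1}) provides a
certifiably convergent fallback, and the candidate with the lowest
objective wins; the winning route is recorded per sample in the
diagnostics, alongside the weighted residual norm and the condition
number of the weighted design. Collinear reference columns are not
tie-broken — they surface as a large condition number and a warning, and
users should merge such types. Constraint violations below 1e-9 are
treated as floating-point dust and clipped; anything larger raises.

## Reference construction

*Sorted-cell bulk replicates*: per-gene median (profile) and
interquartile range (variability) per cell type, requiring ≥ 2
replicates. Quartiles use linear interpolation between order statistics
(the "type 7" rule) — the most widespread convention and deterministic.

*Labeled single cells*: per-gene mean and standard deviation, the robust
pair being too brittle under dropout-heavy single-cell data. Within each
patient only cell types with ≥ 3 cells (configurable) contribute; the
per-patient means are then averaged across patients so that a deeply
sampled patient cannot dominate the profile. The SD is taken across all
qualifying cells with ddof = 1 (the R/pandas sample convention,
configurable); variability here is a weighting heuristic, not an
estimator, so the convention is documented rather than agonized over.

Cell types can be merged or renamed (merged columns are averaged), e.g.
combining granulocytes with neutrophils, or using a monocyte profile as
a macrophage proxy when deconvolving tumors with blood-derived
references.

*mRNA contents*: B, NK and T lymphocytes and cancer cells carry a
comparable mRNA mass and default to 0.4 pg/cell, which is also the
uncharacterized default; types outside that class fall back to a
configurable value (default 0.4 pg) with a warning, because their true
content should be measured or supplied. The whole table is
user-overridable.

## Signature selection

A marker for cell type t must be significantly overexpressed —
one-sided Wilcoxon rank-sum on TPM, Benjamini–Hochberg adjusted across
genes, adjusted p < 0.01 — against **every** other cell type and
**every** background tissue, with fold change
`(mean+1)/(mean+1) ≥ 2` in each comparison. Survivors are ranked by
their minimum fold change, truncated to the top 50 per type, and genes
whose group-mean expression exceeds 1000 TPM anywhere are removed, since
extreme genes would bias the weighted least squares toward themselves.
The rank-sum test is distribution-free, needs no dispersion estimation
and is deterministic; the selection logic (significant against all
comparisons, fold-change ranking, extreme-expression removal) is what
defines the signature. A shared T-cell list pools CD4 and CD8 samples,
applies the same selection against all non-T groups, and keeps genes
with |log2 fold change| ≤ 1 between the two subsets ("expressed at
similar levels" made precise). All thresholds (alpha 0.01, fold 2,
top-k 50, cap 1000 TPM, similarity bound 1) are configurable; with the
small group sizes typical of sorted-cell datasets, note that exact
rank-sum p-values are bounded below by the permutation count, so alpha
= 0.01 needs roughly ≥ 7–8 samples per group to be attainable at all.

## A-priori content rescaling

The standard estimator renormalizes by mRNA content *after* fitting. The
a-priori variant folds the contents into the reference instead: each
column (profile and variability) is scaled by r_j, so a fitted
coefficient q_j = p̄_j/r_j is directly proportional to cell numbers. The
feasible set maps accordingly — the budget constraint becomes
`Σ_j r_j q_j ≤ 1` — and the solver supports this generalized constraint
natively. The uncharacterized slack `1 − Σ r_j q_j` is a mRNA share and
is converted with its own content r_m; a final sum-to-one normalization
yields cell fractions without any a-posteriori division. In the
noiseless limit the two routes are algebraically identical; under noise
they differ only through the (slightly) different weights, and both are
exposed.

## Synthetic testbed

The generators produce: reference profiles with a lognormal expression
baseline shared across types plus planted, perfectly type-exclusive
markers (so recovery can be checked exactly); cancer profiles with
lognormal expression on non-signature genes and a configurable "leakage"
level on signature genes (0 = the identifying assumption holds); bulk
mixtures assembled at the mRNA level — mRNA fractions ∝ cell fraction ×
per-cell content — with i.i.d. per-gene multiplicative lognormal noise;
and single-cell cohorts with per-cell lognormal noise and independent
Bernoulli dropout, with per-patient cell-count ground truth. All
randomness flows from one explicit seed.

What this testbed does *not* emulate: correlated gene modules, batch and
platform effects, partially shared markers between related cell types
(e.g. Treg vs T-helper), compositional noise, UMI counting, or cancer
cells that genuinely express immune markers beyond the scalar leakage
knob. Passing tests therefore demonstrate correctness of the estimator
under its own model assumptions and graceful degradation under generic
noise — not accuracy on any particular real cohort, where reference
mismatch is usually the dominant error source.

Default study conditions used by the test suite: mixtures of 3–4
characterized types plus cancer over 200–1000 genes with 3–5 planted
markers per type; noiseless closure checked to 1e-6; σ = 0.2 noise over
20 mixtures against a pooled cell-fraction RMSE bound of 0.08
(deconvolution of low-abundance types is generally considered reliable
only to within a high single-digit percentage error); leave-one-out
cohorts of 4 patients with 5–25 cells per type and 30% dropout against a
pooled Pearson R bound of 0.9. The solver is cross-checked against an
exhaustive simplex-grid search at resolution 10⁻² on 100 random 2–3 type
instances and against the projected-gradient route to 1e-8.

## Known limitations

- Cell types with highly similar transcriptomes are weakly identifiable;
  the package reports the design's condition number instead of
  tie-breaking.
- The uncharacterized estimate absorbs *every* unprofiled component
  (epithelium, dead cells), not only cancer.
- Signature quality is the accuracy ceiling: markers expressed by the
  uncharacterized cells (leakage) bias all shares; the selection
  thresholds here are deterministic stand-ins for what is, in practice,
  partly manual curation.
- No uncertainty quantification on the fitted fractions.
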