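# Methods

This note documents the statistical and optimization models the package
implements, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical policies that make
results deterministic.

## Count model and differential expression

Counts are modeled as negative binomial with a gene- and group-specific mean
μ and a single **common dispersion** φ, variance μ + φμ². A common φ (rather
than gene-wise or shrunken dispersions) matches the simplest defensible model
for a 4 vs 4 design and makes the estimator and the exact test mutually
consistent; gene-wise/shrinkage dispersion estimation is deliberately out of
scope.

**TMM normalization.** The factor of sample k against reference r is
2^f with f the weighted mean of gene-wise M-values, after symmetric trimming
of 30% per tail by M and 5% per tail by A (the established defaults), with
weights the inverse of the approximate binomial variance
(N_k − y_k)/(N_k y_k) + (N_r − y_r)/(N_r y_r). The reference sample is the
one whose 75th-percentile count fraction is closest to the mean across
samples. Factors are rescaled to geometric mean 1. The implementation is
verified in the test suite against the Bioconductor edgeR reference
implementation to ~1e-12 on a shared fixture, and against a direct symbolic
transcription of the formula on a 6-gene matrix.

**Pseudo-counts.** Both the dispersion estimator and the exact test first
scale each sample's counts to the geometric-mean effective library size
(library size × TMM factor). Group sums of these pseudo-counts are rounded
to the nearest integer for the exact test; at the default sequencing depth
(counts in the hundreds to thousands) the rounding error is negligible
relative to sampling noise.

**Common dispersion.** φ maximizes the *conditional* likelihood of the
replicates given their group sums — for n iid NB replicates this conditional
distribution is negative hypergeometric and free of the mean, making it the
natural common-dispersion criterion; its φ → 0 limit is multinomial. The
maximizer is located on [0, 5] by a coarse geometric bracket followed by a
uniform grid of step 1e-3, and clamped at 0 for sub-Poisson data. Recovery
is tested at φ = 0 (estimate ≤ 0.05) and φ = 0.2 with 50 replicates
(±30%).

**Exact test.** Per gene, the two group pseudo-sums S₁, S₂ are NB with
means n₁μ, n₂μ and dispersions φ/n₁, φ/n₂ under the null. Conditioning on
s = S₁ + S₂, the two-sided p-value sums the probabilities of all splits no
more likely than the observed one (double tail), computed in log space. At
φ = 0 this reduces exactly to the conditional binomial test, which the test
suite checks against `scipy.stats.binomtest`. Calibration: on a 2,000-gene
null at the study design (4 vs 4, φ = 0.1, library mean 1e6) the empirical
type-I error must fall inside the 99% binomial interval around α = 0.05.

**Significance policy.** Raw p < 0.05, no multiple-testing correction — this
mirrors the analysis convention of the study system the pipeline models. An
optional Benjamini–Hochberg flag exists but is off by default. Genes with
zero counts in every sample are dropped before normalization and testing.
Log fold changes use a prior count of 0.5 per group mean to stabilize zeros;
the signed fold-change convention is +2^|log2FC| for up, −2^|log2FC| for
down.

## Functional categories

The COG tally is a deterministic join of DE status with an input annotation
table restricted to the 23 one-letter categories. Multi-coded genes count
once in *each* category by default (configurable to first-code-only), and a
(gene, code) pair never counts twice in one direction. Unannotated DE genes
are reported under `unassigned` rather than silently dropped, so the tallies
always account for every DE gene.

## Constraint-based core

A model is metabolites, reactions (stoichiometry, bounds, GPR rule,
objective coefficient) in the community JSON dialect (read and written; SBML-FBC
is read-only). All LPs run on scipy's HiGHS interface, which is
deterministic for a fixed problem; infinite bounds are capped at ±1e4 inside
the solver and left untouched on the model.

* **FBA** maximizes the model objective subject to S·v = 0 and bounds.
* **pFBA** re-imposes the optimum (relative slack 1e-9) and minimizes Σ|v|
  via the standard v/t split. It is used to uniquify the reference flux
  state: the optimum and Σ|v| at the optimum are unique even when the flux
  vector is not, and the deterministic solver fixes the remaining ties.
* **FVA** minimizes and maximizes each reaction's flux, optionally with the
  objective pinned at a stated value.

On every shipped toy network (≤ 10 reactions) FBA and FVA are required to
agree with an exhaustive vertex-enumeration oracle to 1e-8.

## gx-FBA realization

The expression-integration method is specified here concretely because its
published descriptions are verbal; every policy below is a visible parameter
so alternative realizations can be swapped in and re-validated against the
planted-response suite.

* Per-reaction expression ratio C: significant genes contribute 2^log2FC,
  all others 1 (neutral); AND = `min` (complex limited by its scarcest
  subunit), OR = `max` (dominant isozyme). `mean` is available for both;
  note `mean` is applied n-ary over a rule level, not by pairwise chaining.
* Constrained set T: reactions with a non-empty GPR, at least one
  significant gene, C ≠ 1, |v_mean| ≥ ε, and no direction conflict. A
  conflict is flagged when both up- and down-regulated genes appear in the
  rule *and* the combined ratio falls on opposite sides of 1 under the
  chosen rules versus their duals (min↔max swapped) — i.e. the sign of the
  predicted regulation would be an artifact of the aggregation order.
* v_mean is the midpoint of the unconstrained stress-environment FVA range;
  it normalizes objective weights across reactions of different scale and
  supplies the direction for reactions silent in the reference state.
* Direction d = sign(v_ref) when |v_ref| ≥ ε, else sign(v_mean). Constraints
  d·v ≥ 0 (no flip) and d·v ≤ C·max(|v_ref|, |v_mean|) (cap); the cap also
  guarantees a bounded objective. A configurable `cap_relaxation` factor
  (≥ 1) loosens the caps when a model/environment combination turns the
  capped LP infeasible.
* Objective Z = Σ log2(C_i)·d_i·v_i/|v_mean,i| over T, maximized; then the
  post-optimal flux ranges fix Z within relative 1e-6 (the classification is
  defined on exactly these bounds), and a parsimonious representative flux
  is computed at the same fixed Z. Exchange (secretion) bounds are never
  modified by the expression data.

## Classification

Labels are evaluated in the precedence `no_flux` → `down` → `up` →
`ambiguous`, because the no-flux definition overlaps the ambiguous one when
all quantities are zero. Comparisons are signed (bounds against the signed
reference flux); a magnitude mode exists for sensitivity analysis because
the two conventions disagree for reversible reactions carrying negative
reference flux. A reaction with v_ref = 0 and stress bounds straddling zero
is `ambiguous` under these rules — documented, not special-cased. ε defaults
to 1e-6 (the shared "carries flux" tolerance) and growing ε can only move
reactions *toward* `ambiguous`/`no_flux`, never create new directional
calls (property-tested).

The generic response across conditions takes per-reaction elementwise
medians of v_ref, L and U (even counts: mean of the two middle values) and
classifies the medians with the same rules.

## Synthetic data: what it emulates, what it does not

The generator's defaults are the study conditions the pipeline models:
3,898 expressed genes, 4 control vs 4 treated replicates, library-size mean
1e7 (the study sequenced > 10 million reads per sample), NB counts with
common φ = 0.1, 18.2% of genes differentially expressed with |FC| uniform in
log2 on [3.5, 30] and 58% of the DE genes up-regulated. Library sizes are
log-normal with CV 0.2 so TMM has non-trivial work; per-gene relative
abundances are log-normal with σ = 1. The study did not publish its
mean–variance behavior, so φ = 0.1 is this package's choice of a typical
bulk-RNA-seq common dispersion, exposed in `SimCountSpec` and the run configuration.

Not emulated: read-level artifacts (mapping, multi-mapping, strandedness),
gene-length effects, batch structure, correlated genes, and gene-wise
dispersion variation. Passing tests therefore demonstrate correctness of
the *algorithms* under the stated model, not robustness to every real-data
pathology.

Toy networks (chain; branched with yield-1 and yield-0.5 routes; chain with
a futile cycle) have analytic optima recorded in their metadata and stand in
for a genome-scale model; they exercise exchange bounds, maintenance
requirements, multi-gene GPRs, degenerate optima and reversibility, but not
the scale or numerical conditioning of a 2,700-reaction network.

## Problem sizes and determinism

The test suite and the acceptance script run the full-scale synthetic DE
analysis at 3,898 genes and the calibration at 2,000 genes; LP-oracle
comparisons use the ≤ 10-reaction toys, where exhaustive vertex enumeration
is feasible. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration + seed reproduces
byte-identical TSV outputs (the run report's wall-time fields excepted).

## Known limitations

* Common dispersion only; strongly gene-wise-dispersed data will be
  mis-calibrated at the extremes.
* The exact test's pseudo-count rounding is an approximation at very low
  counts (< ~10 per group sum).
* gx-FBA predictions depend on the chosen realization (v_mean definition,
  caps, GPR rules); conclusions should be checked for stability under the
  exposed alternatives.
* No loopless/thermodynamic constraints: futile cycles are suppressed only
  by parsimony in the representative flux, not excluded from FVA ranges.
* SBML-FBC models are read through cobrapy; writing is JSON-only.
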