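# Methods

This note documents the models, conventions and numerical choices behind
`senesurf`, and what the synthetic-data generator does and does not
emulate.

## Synthetic proteomics data

Each protein *g* carries a latent log2 abundance μ_g ~ Normal(8.2, 1.5²)
(median ≈ 300 PSMs, spanning the dynamic range typical of label-free
surface-enrichment experiments). The default design has eight senescence
comparisons — three human (NHLF·ETO, NHLF·H2O2, HUVEC·H2O2) and five mouse
(MEF·ETO, MEF·H2O2, AST·ETO, AST·H2O2, AST·EPO) — each with senescent and
control groups of **three technical replicates**. A fraction `frac_dep`
(default 0.2) of proteins receives planted effects: for each such protein,
every comparison is independently perturbed with probability 0.5 (at least
one forced), downregulated with probability 0.3, with |log2FC| drawn
uniformly from `planted_log2fc` (default [1, 3]; the lower bound is
constrained to ≥ log2 1.5 so every planted effect is callable in
principle). Replicates are multiplicative log-normal:
value = 2^(μ+Δ) · exp(σε) with σ = sqrt(ln(1+cv²)), so the coefficient of
variation across technical replicates equals `cv_technical` (default 0.2)
and fold changes on the mean scale are preserved exactly.

Missingness is missing-at-random at rate `missing_rate` (default 0.10);
an `intensity` mechanism (left-censoring with probability decreasing in
the value's global rank) is available because real PSM missingness is
intensity-biased. After masking, one entry per protein per condition group
is unmasked if the group would otherwise be empty, so the imputation
preconditions always hold; at the default settings this protection binds
for ~0.1% of groups and the realized missing rate stays within binomial
99% bounds of the nominal rate.

The generator's defaults are assumptions, not estimates: the original
experiments do not report their noise or missingness structure. Surface
flags are Bernoulli(0.32) per latent gene (the observed share of surface
annotations among identified proteins), homolog coverage is 0.93 (≈658 of
704), and 5% of genes are designated low-in-all-tissues.

What the generator does **not** emulate: peptide/spectrum-level structure
(no retention times or search scores), correlated effects across
comparisons beyond the shared latent gene, batch effects, and any actual
senescence biology — effects are purely statistical. Passing tests
therefore demonstrate the correctness of the pipeline's arithmetic and set
logic under its stated assumptions, not biological validity on real data.

## Ground truth and the funnel

Annotation tables are derived deterministically from the same master seed
as the PSM matrix, so surface flags, homolog pairs, tissue levels and
signature memberships are consistent with the planted labels. The expected
candidate set is computed from the labels by a plain restatement of the
funnel rules (a separate code path from `senesurf.funnel`): surface AND
human-DEP AND homolog-covered AND ((mouse-DEP AND up in ≥ 2 comparisons)
OR in ≥ 1 published signature) AND low-in-all-tissues. Funnel candidates
are reported as human ids; mouse evidence is collapsed onto the human id
of each homolog pair, and with one-to-many homology a protein counts as
"low in both species" when any paired homolog passes the tissue filter
(the most permissive reading, matching how cross-species overlaps are
counted).

The tissue atlas gives designated low genes levels in [0, 0.5) and all
other genes levels ≥ 5, so the default threshold — the 10th percentile of
the atlas's nonzero values — separates them exactly. On real atlases the
"absent or low expression" cut is qualitative; `level_threshold` and
`fraction_tissues` are therefore explicit parameters, and the defaults are
this package's own operationalization.

The "upregulated in at least two senescence conditions" filter (k = 2)
counts comparisons of both species pooled at the collapsed gene level,
since the upstream cross-species overlap already requires DEP status in
each species separately.

## PSM transformations

- **Imputation** is chained-equations regression: each sample column with
  missing values is regressed on the other columns over proteins
  (ordinary least squares inside scikit-learn's iterative imputer),
  initialized at column means, iterated round-robin (max_iter = 10,
  tol = 1e-3 by default, both configurable), clamped to ≥ 0, and observed
  entries are restored bit-identically. OLS (rather than a shrinkage
  estimator) makes exactly collinear columns recover held-out entries to
  machine precision.
- **Control z-scores** use the mean and sd of the matched (cell model,
  inducer) CTRL replicates per protein, with an sd floor of
  1e-8·(protein mean + 1) so constant control groups stay finite. The
  per-condition column is the mean over the condition's technical
  replicates (replicate aggregation is otherwise unspecified).
- **Signed log10**: sign(z)·log10(|z|+1). The source description of the
  +1 offset and the negative-value handling is ambiguous about operation
  order; this odd, continuous, zero-preserving composition was chosen so
  up- and downregulation are treated symmetrically and the map is
  invertible (inverse sign(y)·(10^|y|−1)).
- **PCA** consumes condition profiles of the imputed matrix, mean-centers
  internally, and fixes each component's sign so its largest-magnitude
  loading is positive (repeated runs are identical).
- **Fuzzy c-means** implements the standard alternating updates
  (centroids = u^m-weighted means; memberships by the inverse
  squared-distance ratio rule with exponent 1/(m−1)), with per-protein
  standardization before clustering, seeded initialization at c distinct
  observed profiles, membership 1 for a profile exactly on a centroid
  (lowest cluster index wins ties), and convergence when the largest
  membership change drops below tol. Defaults m = 1.25 (soft but close to
  k-means, appropriate for standardized expression trajectories) and
  c chosen by the caller; the objective Σ u^m d² is recorded per
  iteration and is non-increasing.

## Differential expression

The original study's per-protein p-values came from unstated software
internals, so the test here is a deliberate, documented choice: Welch
(unequal-variance) two-sample t on log2(PSM + ε), ε = 1, two-sided. FC is
computed on condition means of the pseudocounted PSM scale. Degenerate
conventions: both groups exactly constant and equal → p = 1; constant but
different → p is the machine floor with a warning (t undefined at zero
variance). Thresholds are inclusive for FC (≥ 1.5 is "at least 1.5") and
strict for p (< 0.05). No multiple-testing correction is applied by
default, mirroring the per-protein p < 0.05 rule; Benjamini–Hochberg is
available (`adjust="bh"`). At n = 3 replicates the realized null
false-positive rate of this test is near but not exactly 0.05 (typically
0.03–0.04 under the generator's log-normal noise); it is measured, not
assumed.

Printed percentages use half-away-from-zero rounding at 0 or 1 decimals
(`percent()`); note 16/27 = 59.26% rounds to 59.3 under this rule.

## Single-cell stage

Binarization is count > 0 (so normalized fractional counts are
"expressed"). Age groups are young ≤ 3 months, old ≥ 18 months, both
inclusive; intermediate ages are excluded with a logged count; tissues
present in only one age group are dropped. Dataset merging requires
disjoint cell ids and uses the gene-vocabulary intersection.

LORs are natural-log by default (base configurable), computed per
(tissue, cell type) unit over all cells pooled across ages — the
co-expression analysis is distinct from the young/old fraction analysis,
which stratifies by age. The Haldane–Anscombe 0.5 is added to all four
cells only when some cell is zero, keeping heat-map values finite; the
Fisher p is always computed on the raw counts. The two-sided Fisher
convention is the point-probability method (sum of the probabilities of
all tables with the observed margins that are no more probable than the
observed table); ties between floating-point representations of exactly
equal rational probabilities are absorbed by a relative guard of 1e-7,
and the implementation agrees with full hypergeometric enumeration to
< 1e-12 over every table with n ≤ 30. "Age-dependent increase" is the
strict inequality fraction_old > fraction_young with no significance
filter; the Fisher test applies to co-expression, not to the increase
flags.

The planted-OR generator solves the Plackett joint-Bernoulli quadratic
(OR−1)p11² − (1+(OR−1)(p1+p2))p11 + OR·p1·p2 = 0 for the root inside the
Fréchet bounds, draws the marker Bernoulli(p1) and each candidate
conditionally on the marker; candidates are conditionally independent
given the marker. Degenerate marginals (p ∈ {0,1}) fall back to the
product measure. Infeasible (marginal, OR) combinations raise with a
clear message.

## Determinism and problem sizes

One master seed drives everything; per-stage child generators are derived
as SeedSequence(entropy=master, spawn_key=(stage,)) with stages 0–3 for
truth planting, PSM noise, annotations and single-cell draws, so stages
can be regenerated independently and reruns are byte-identical. Test and
acceptance problem sizes (≤ 2000 proteins, 10⁴ cells per unit, 20 seeds
per odds ratio, all 2×2 tables with n ≤ 30) were chosen as the smallest
sizes at which the Monte-Carlo bounds in the checks are comfortably
informative.

## Known limitations

- The DEP p-value procedure is a stand-in convention; absolute DEP counts
  are not comparable with any specific MS software's output.
- The tissue filter's defaults encode a qualitative judgement; real-data
  use requires choosing a threshold against the atlas in hand.
- Gene identifiers are matched as exact strings with species prefixes in
  synthetic data; reconciling real-world symbol/ID systems is the
  caller's job.
- Fuzzy c-means converges to a local optimum; different seeds can yield
  different partitions on weakly separated profiles.
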