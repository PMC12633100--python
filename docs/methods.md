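# Methods

This note documents the statistical model behind `xdprescue`, the
assumptions it makes, the tunable parameters, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
taken where more than one reasonable option existed.

## Differential expression model

Counts are filtered per comparison: a gene is removed when its CPM
(count · 10⁶ / library size) falls below `cpm_threshold` (default 0.1) in
at least `cpm_fraction` (default 50%) of *either* genotype group. Retained
counts are normalized by median-of-ratios size factors: for each gene with
strictly positive counts in every sample, the ratio of each sample's count
to the gene's geometric mean is formed, and a sample's factor is the
median of those ratios. Factors are rescaled to geometric mean 1 — a pure
convention (a global constant cancels from every fold-change and test
statistic) with the convenient consequence that normalization is
idempotent: factors recomputed on normalized counts are exactly 1. The
median is taken on the ratio scale; taking it on the log scale instead
differs only when the number of usable genes is even (geometric vs
arithmetic interpolation of the two middle ratios).

Sample outliers are flagged in PCA space: samples are projected onto the
top `n_pcs` (default 2) principal components of ln(normalized + 1), and a
sample is excluded when its Euclidean distance to the sample centroid
exceeds mean + `sd_mult` (default 2) standard deviations of the distances.
The number of components and the multiplier are configurable because the
"2 SD from the centroid" rule underdetermines both.

Latent technical structure is estimated as surrogate variables: log
expression is residualized against the primary design (intercept +
condition), and the leading right-singular vectors of the residual matrix
become per-sample SV scores. With `k="auto"`, k is selected by permutation
parallel analysis: each gene's values are permuted across samples, the
permuted matrix is re-residualized against the same design, and k is the
number of leading observed singular values exceeding the 95th percentile
of their permuted counterparts (100 permutations, seeded). Re-residualizing
the permuted data is essential: observed residuals live in an
(n − rank) -dimensional subspace, and comparing them against unprojected
permutations systematically inflates the selected k.

The per-gene GLM is, by default, ordinary least squares of ln(normalized
counts + 1) on the design (intercept, condition, SVs, optional batch
dummies), vectorized across genes. This Gaussian log-linear family matches
the adjusted-count reconstruction exactly (additive residuals on the
natural-log scale); coefficients are natural-log fold-changes. Inference is
a Wald test with a t reference on the residual degrees of freedom, and BH
FDR across genes. A negative-binomial family (log link, per-gene dispersion
initialized by method of moments from a Poisson fit and refined by one
numeric Newton step on the profile likelihood) is provided for robustness
studies; it uses a normal reference. Signature genes are those with
q < `fdr_threshold` (default 0.10), annotated up/down by the sign of the
condition coefficient.

## Paired rescue

For each treatment *j*, a separate GLM is fitted to that treatment's
treated libraries plus their untreated partners. Adjusted counts are
reconstructed as Y_j = β_keep·M_keepᵀ + R with
`keep_vars = (intercept, condition)`: the fitted contributions of every
nuisance variable (SVs, batch) are subtracted from the observed log
expression. Because β·Mᵀ + R lives on the log scale and the exponential is
strictly positive, the equivalent exponentiate–floor–log form reduces to
this linear identity; no floor is needed. Retaining the condition term is
deliberate: dropping it would force every paired difference to be pure
residual noise, making the treatment effect unestimable.

Pairing is clone-level: each treated library is differenced against the
untreated library of the same clone, D = Y[treated] − Y[untreated], giving
a per-pair log fold-change. The per-gene summary is the arithmetic mean D̄
over pairs with a t-based 95% CI (df = pairs − 1); with a single pair the
CI is reported unavailable rather than fabricated.

The nominal rescue rule: a gene is rescued by treatment *j* iff it is a
signature gene and its treated-vs-control Wald p exceeds α (default 0.05).
Among rescued genes, reversal is sign(D̄) = −sign(disease fold-change);
an exactly-zero D̄ is indeterminate and excluded from both numerator and
denominator of the reversal fraction. Rescued-set overlap uses a one-tailed
(greater) Fisher exact test with the signature-gene set as the default
universe (configurable; the choice of universe is not determined by the
rescue definitions themselves). Gene-set enrichment intersects each GMT
term with the analysis universe (annotated ∩ analyzed genes) and applies
Bonferroni or BH correction across terms.

The CRISPR-edited (ΔSVA) clones are handled as an implicit clone-level
"treatment": edited clones are matched to unedited clones of the same
subject, so the same rescue, reversal and overlap machinery applies to the
CRISPR comparator and to the ASOs.

## Bootstrap engine

Each bootstrap draws `n_per_group` (default 6) untreated controls and
disease samples without replacement and reruns the complete workflow — CPM
filter, size factors, SV estimation (re-estimated within each bootstrap),
GLM, Wald test, and BH correction within that bootstrap. Per-gene outputs
are frequencies over bootstraps: filter passage (over all bootstraps) and,
among passing bootstraps, direction and direction-with-significance at p
and FDR thresholds; the nesting f_sig_fdr ≤ f_sig_p ≤ f_direction holds by
construction. Duplicate subsets across bootstraps are allowed. A test hook
accepts an explicit subset list so the engine can be verified to add no
computation beyond repeated direct DE runs. Gene universes differ across
bootstraps because the CPM filter is subset-dependent.

## Splice screen

Junction counts are normalized by size factors; group fold-changes are
ratios of geometric means (difference of log means back-transformed) with
a Welch t 95% CI. When zeros are present a pseudocount (default 0.5) is
added before taking logs and the result is flagged; a baseline group that
is entirely zero is undefined. The intron-retention ratio uses the bounded
convention intronic/(intronic + spliced) ∈ [0, 1] (the convention of
read-level IR tools); the unbounded intronic/spliced form is available via
`convention="simple"`. The IR group model is an identity-link linear model
of the ratio on genotype and treatment indicators.

qPCR quantification is 2^(−ΔCT) with optional normalization to a reference
condition. Dose-response fits minimize least squares for
y = 1/(1 + (x/EC50)^h) with top and bottom fixed at 1 and 0, optimizing
over (log EC50, log h) from a 3×3 grid of starts (log-concentration
quartiles × slope guesses 0.5/1/2) and keeping the best by residual sum of
squares. A fitted EC50 more than 100× outside the assayed concentration
range is flagged as a boundary fit (flat or non-monotone data) and treated
as non-converged; ranking places non-converged fits last, with EC50 ties
broken by lower RSS and then identifier.

## Synthetic-data generator

The generator emulates the NSC experiment: 8 controls, 9 naive + 21
unedited disease clones, 30 edited (ΔSVA) clones, and one treated library
per disease clone per treatment (seven ASO treatments by default), with
clone-level pairing recorded in the sample sheet. Counts are gamma-Poisson
(variance μ + αμ² with dispersion α = 0.05 by default, typical of deeply
sequenced cell-line bulk RNA-seq), with natural-log means assembled from:

- per-gene baselines ~ Normal(4, 1.5²) on the log scale (median ≈ 55
  counts) — the baseline and dispersion distributions are calibration
  choices, not values taken from data;
- genotype effects on a `frac_signature` (default 20%) subset, with
  magnitude 1 + |N(0, 0.25)| ln-units and random sign, applied to samples
  carrying the insertion;
- treatment effects that exactly cancel the genotype effect for a
  `frac_rescued` (default 30%) subset of signature genes (half-cancel for
  an optional "partial" fraction, untouched otherwise); edited clones act
  through the same labels;
- latent confounders (default 2) entering additively on the log-mean with
  Gaussian loadings (scale 0.2) and **clone-level** scores: all libraries
  of a clone share one score vector. Library-level scores would let the
  chance imbalance between a clone's treated and untreated libraries load
  on the retained condition coefficient, coherently biasing all genes'
  paired effects; clone-level confounding is also what the paired design
  exists to cancel (per-individual variation);
- balanced batch assignment (round-robin) with per-gene batch effects
  (SD 0.1) and log-normal library-size variation (SD 0.15).

The junction generator draws negative-binomial counts (dispersion 0.25,
reflecting ~50% biological CV across clones) with group means 425.4
(disease), 2.3 (control) and 425.4 × 0.016 (edited) — the reported group
levels of the disease-exclusive junction. The dose-response generator
evaluates the decreasing logistic and adds truncated Gaussian noise; its
default of 6 measurements per dose reflects the screen's assay design of
two patient cell lines each measured in qPCR technical triplicate (a
single measurement per dose cannot support a 10%-accurate EC50 at noise
SD 0.05).

What the generator does **not** emulate: read-level artifacts (mapping,
positional bias, gene length), isoform structure, count correlation between
genes beyond the planted factors, overdispersion heterogeneity across
genes, or capture bias in targeted sequencing. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every failure mode of real libraries.

## Verification problem sizes

The automated checks run at desk scale: calibration on 10,000 simulated
null genes (6 vs 6), CI coverage on 2,000 genes with 30 pairs, rescue
recovery on the full default design (2,000 genes, ~280 libraries),
200 bootstraps over a 20+20 pool of 400 genes, 100 noisy EC50 replicates,
and 60–200 junction-table replicates. The exact-test oracle enumerates all
46,375 2×2 tables with total ≤ 30; the size-factor oracle covers 100
random 5×4 matrices at 10⁻¹² tolerance.

## Known limitations

- Latent confounding that is correlated with the condition contrast is
  fundamentally unidentifiable from the data; SV adjustment removes only
  the orthogonal component. Under the default generator (clone-level
  confounders, 30+8 clones) this depresses the nominal rescue rate by a
  few percent below 1 − α; the exact nominal level is recovered when the
  residual effect is exactly zero.
- The Gaussian log-linear family relies on ln(x+1) normality; for very
  low counts its Wald test is conservative. The CPM filter removes most
  such genes before testing.
- The negative-binomial path fits per gene via statsmodels and is orders
  of magnitude slower than the vectorized Gaussian path; it is intended
  for robustness checks, not for the bootstrap engine.
- Fisher overlap p-values depend strongly on the chosen universe; defaults
  are documented and configurable, and cross-universe comparability is not
  claimed.
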