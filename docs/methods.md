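# Methods

This note documents the statistical model, the numerical choices, and
the synthetic-data design behind `smckat`, including the places where
the design was genuinely open and what the package chose.

## Model and test

A subject's CNV profile is the list of its variants sorted by
(karyotype chromosome order 1..22, X, Y; then start, end, type).
Coordinates are 1-based inclusive everywhere internally; UCSC-style
0-based half-open inputs are shifted on read, and intersection lengths
are `max(0, min(ends) − max(starts) + 1)`.

The three-level kernel (single pair → position-paired window average →
sum of best-of-three-neighbour window matches) is described in the
README. Three constructional details deserve justification:

* **Symmetrization.** The group-series kernel anchors the sum on the
  first profile and searches neighbours in the second, so
  `KWG(Pi, Pj) ≠ KWG(Pj, Pi)` when the series lengths differ. The score
  test treats `K` as a covariance, which must be symmetric, so the
  matrix is `(K + Kᵀ)/2`. When series lengths differ the anchor index
  runs to `max(pi, qj)` (anchors beyond the first series contribute 0;
  neighbour indices outside the second series are skipped); a
  `sum_bound="min"` variant is exposed because the defining sum is
  ambiguous for unequal lengths, and a `normalized` mode divides by the
  anchor count (both off by default — the raw max-bound sum is the
  defined quantity).
* **PSD projection.** The per-window maximum makes `K` potentially
  indefinite. Negative eigenvalues are clipped to zero by default
  (`psd_fix`), the adjustment is recorded on the matrix, and the
  diagonal before adjustment equals each subject's window count.
* **Empty profiles.** A subject with fewer CNVs than the window size
  contributes an all-zero row/column (with a warning naming it) rather
  than being dropped: dropping would silently change the cohort and the
  null fit.

The null logistic model (intercept plus optional covariates) is fit by
IRLS (statsmodels GLM, tolerance 1e-8, ≤ 50 iterations), with explicit
errors for a single phenotype class, rank-deficient covariates, and
(quasi-)perfect separation. The score statistic is
`Q = (y − ŷ)' K (y − ŷ)`; its classical null approximation is the
chi-square mixture with weights the eigenvalues of `P^{1/2} K P^{1/2}`,
`P = V − V X (X'VX)⁻¹ X'V`, `V = diag(ŷ(1 − ŷ))`, discarding
eigenvalues below 1e-10 of the largest.

### Tail probabilities

`P(Σ λ_j χ²₁ > q)` is computed by numerical inversion of the
characteristic function (the Gil-Pelaez/Imhof integral underlying
Davies' method): adaptive quadrature up to the point where the
integrand's phase turns monotone, then one half-period lobe at a time
with the near-alternating lobe sums accelerated by repeated averaging.
Absolute accuracy 1e-6 by default; when the first pass lands below
100× that accuracy the tail is re-inverted at an accuracy proportional
to the estimate so relative error stays controlled. On any fault — or
beyond what the integration can certify (~1e-12) — the Liu-type
four-cumulant moment match to a (non-central) chi-square takes over and
the result is labelled `moment_matching`. Reported p-values are clipped
to [1e-300, 1] and never printed as exactly zero.

### Small-sample calibration for binary traits

The chi-square mixture assumes the residuals `y − ŷ` behave like
normals. Binary residuals are two-point variables, and at cohort sizes
of a few hundred or less the exact null distribution of `Q` —
conditional on the case count, it is the permutation distribution of
the labels — has visibly different shape: its skewness can be near zero
or negative, which no non-negative mixture of chi-squares can
reproduce. The practical consequence is a badly conservative test: in
our null simulations at d = 60 the mixture p-values rejected at a 0.05
level only ~0.2–3% of the time and were far from uniform.

The package therefore defaults (`small_sample="auto"`) to a
conditional-moment p-value for intercept-only binary models of up to
2000 subjects: the first three moments of the permutation null of `Q`
are estimated from 500 label resamples (no model refit — each resample
is a single quadratic form; the resampler is internally seeded, so the
p-value is a deterministic function of its inputs), and the tail comes
from a three-moment chi-square fit, reflected when the skew is negative
and degrading gracefully to a normal when the skew vanishes. This is
*not* a permutation p-value — the tail is analytic and continuous; the
resamples only pin down three moments. It is the same species of
correction that established kernel-machine packages apply by default to
binary traits at small sample sizes. With it, the null simulations at
d = 60 give rejection ≈ 0.05 at the 0.05 level and p-values
indistinguishable from uniform (KS p ≈ 0.6–0.9). The mixture p-value is
always computed as well and recorded (`p_value_mixture`); covariate
models and `small_sample="never"` report the mixture p-value directly.
The moment estimates use 500 resamples, so reported p-values below
~1e-4 carry extrapolation uncertainty from the fitted tail; for
region-scan significance calls at Bonferroni thresholds of ~1e-3 this
is immaterial, but individual deep-tail p-values should be read as
order-of-magnitude statements.

### Region scans

A CNV is assigned to a cytogenetic band iff its midpoint lies in the
band, so any non-overlapping banding partitions each chromosome's CNVs
— the alternative (counting straddlers in every band they touch) would
double-count boundary CNVs. Scans apply Bonferroni control at the
requested family-wise error rate over however many regions were tested;
regions with no CNVs are reported as degenerate (p = 1) and still count
in the denominator. Thresholds are reported to two significant figures
using decimal round-half-even (0.05/40 reports as 1.2e-3).

## Synthetic cohorts

The generator emulates two CNV classes at desk scale:

| parameter | rare regime | common regime |
|---|---|---|
| CNVs/subject (Poisson mean) | 4 | 30 |
| length (log-uniform, bp) | 1e5 – 1e6 | 1e3 – 5e4 |
| placement region | 20 Mb | 5 Mb |
| deletion probability | 0.5 | 0.5 |

Rare variants are few and long (hundreds of kb to ~1 Mb); common copy
number polymorphisms are many and short (kb scale). Dosages are 0 or 1
with probability 0.5 each for deletions and 3..7 with probability 0.2
each for amplifications, independent of regime. CNVs are placed
uniformly on a single configurable region; the default region sizes are
chosen so that profiles overlap at realistic rates — they emulate a
CNV-dense region of the kind a per-chromosome or per-band scan targets,
not a whole uniform genome (uniformly scattering a handful of rare
variants over 3 Gb would make every between-subject similarity
essentially zero). What the generator deliberately does **not**
reproduce: recurrent hotspot structure, correlated types at shared
loci, GC/telomere placement bias, and linkage between CNVs — so passing
simulations demonstrate statistical calibration and sensitivity of the
machinery, not performance guarantees on any particular real cohort.

Phenotypes come from a logistic model whose linear predictor sums, over
a subject's CNVs: a length term (per Mb), deletion/amplification
indicator terms constrained to equal magnitude and opposite sign, a
|dosage − 2| term, and two length × type × dosage interactions. A
reduced two-feature model (type indicator × length) is provided for
comparison studies against content-only tests. Setting every effect to
zero gives the null, with baseline prevalence 0.3 by default.

The default alternative uses effects
(β_len, β_del, β_dsg, β_len·del·dsg, β_len·amp·dsg) =
(0.4, 0.2, 0.075, 0.15, −0.075) with the baseline log-odds centered
against the expected per-profile effect contribution (4 CNVs × mean
0.391 Mb, mean |dosage − 2| = 2.25), so the marginal prevalence stays
near 0.3 while subjects differ in risk. These values were fixed once so
that power at α = 0.05, d = 100, rare regime, n = 2 sits in the
0.5–0.8 band (measured ≈ 0.70), with a scale knob for power curves
(≈ 0.31 / 0.70 / 0.90 at scale 0.5 / 1.0 / 1.5).

The calibration harness replicates simulate → phenotype → test with
per-replicate seeds spawned from one master seed; every operation is
byte-reproducible from its seed. Degenerate replicates (single
phenotype class, or no subject with enough CNVs) are recorded, never
dropped, and never count as rejections. Desk-scale defaults are 2000
replicates at d = 60 for type-I error and 200 replicates at d = 100 for
power; these sizes give binomial standard errors of ~0.005 and ~0.035
at the 0.05 level, adequate for the calibration and monotonicity checks
the tests make.

## Known limitations

* Binary traits only; quantitative traits are out of scope.
* The small-sample conditional-moment calibration applies to
  intercept-only models; with covariates the mixture p-value is used
  and inherits the conservativeness described above at small d.
* The group-series kernel is O(profile length) per pair and the matrix
  O(d²) pairs; cohorts of a few thousand subjects are comfortable, but
  no sketching/approximation is provided for very large cohorts.
* p-values below ~1e-4 from the conditional-moment route are
  tail-model extrapolations (see above).
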