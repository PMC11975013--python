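# Methods

## Scientific setting

Gut microbes can synthesize essential amino acids (EAAs) and release them
for host absorption. Because catabolic loss of ¹³C-depleted CO₂ enriches
the residual carbon pool, microbially synthesized EAAs carry δ¹³C values
offset from the diet, and the multivariate δ¹³C pattern across EAAs
("fingerprint") is diagnostic of biosynthetic origin — bacteria, fungi
and plants occupy distinct regions of fingerprint space. `isofinger`
operationalizes the comparison of a germ-free (GF) control arm with a
conventionalized (CVZ) arm: under the null hypothesis the two arms
overlap in δ¹³C-EAA space; under the alternative the CVZ arm is enriched
toward the microbial endmember.

## Generative model (simulate)

Tissues are modelled as a single carbon pool that replaces a fraction
`p` of its carbon over the feeding window (defaults: liver 0.75, kidney
0.60, muscle 0.45, brain 0.30, the literature values for single amino
acids in mice over 20 days). Mixing is linear in δ space — the standard
first-order CSIA approximation, ignoring concentration and flux
weighting:

    E[δ_a] = p · ((1−f)·diet_new_a + f·microbe_a + trophic_a) + (1−p)·diet_old_a

with `f` the microbial contribution fraction (0 in the GF arm by
definition), `trophic_a` an optional per-EAA offset (default 0), and
`diet_old` the pre-switch diet. The microbial source feeds only the
newly incorporated fraction, consistent with a diet-switch design whose
microbes grow on the current diet. Analytical replicates add independent
Gaussian noise, SD 0.2 ‰ (the typical duplicate precision of GC-IRMS
amino-acid measurements; the QC bound is 0.4 ‰).

Default parameter choices, in ‰ vs VPDB:

* **Endmember class means** (bacteria / fungi / plants) are spaced
  several ‰ apart on all six EAAs with within-class SD 1.0 ‰, mirroring
  the separability of published reference compilations; class sizes
  default to 12 / 9 / 11 profiles.
* **Experimental diet** (`diet_new`) is a C3-dairy-casein-like profile
  (≈ −17 to −28 ‰ across EAAs).
* **Pre-switch diet** (`diet_old`) defaults to `diet_new + 7 ‰`,
  emulating a C4/marine-influenced maintenance chow. Incomplete turnover
  then leaves organ-dependent diet offsets of (1−p)·7 ≈ 1.8–4.9 ‰ even
  without any microbial contribution — the magnitude range reported for
  this design — which is exactly why the pipeline screens differentially
  (below).
* **Microbial source** defaults to the bacterial endmember mean
  (4.5–8.5 ‰ above the diet per EAA).
* Study size: 2 arms × 4 organs × 5 animals × 6 EAAs × 2 replicates
  (480 consumer measurements), plus 2 diet samples shared by both arms
  (both diets use the same single protein source) and the endmember
  tables.

Randomness uses one root seed with fixed per-component substreams
(endmembers, diet, each group×organ block), so enlarging one component
never perturbs the draws of another, and identical config + seed
reproduces a study exactly.

**What the simulator does not emulate:** inter-individual biological
variance beyond measurement noise (all animals in a cell share one
expectation), per-EAA turnover heterogeneity (one `p` per organ),
non-essential amino acids, multi-pool turnover kinetics, and any
systematic interlaboratory offset in the training data (exposed only as
an optional additive calibration). Passing tests therefore demonstrate
correctness of the inference chain under these idealized conditions, not
performance on real tissues, where biological scatter will widen all
intervals.

## Diet offsets and the provisioning screen (isotope_io)

Canonical storage is long format (one row per sample × analyte ×
replicate); a wide reader/writer is provided. Replicates aggregate to
per-sample profiles with sample (n−1) SD; a single replicate yields
SD 0 with a `single_replicate` flag so QC stays total and explicit. A
sample is `qc_flagged` iff any analyte SD exceeds the bound (default
0.4 ‰). Offsets Δδ¹³C are computed per EAA against the per-analyte mean
of the diet's replicate profiles; analytes missing from either side are
dropped (never imputed). The screen compares per-EAA mean offsets
against a strict `>` threshold, default 1.0 ‰.

Inside the pipeline the screen is applied to **differential offsets**:
each CVZ sample's offset minus the mean GF offset of the same organ and
EAA. The GF arm is the no-microbiome control, so diet-memory and trophic
contributions common to both arms cancel and only microbially driven
enrichment can exceed the threshold. On raw (diet-referenced) offsets
the turnover memory term would dominate the screen in any realistic
diet-switch design.

## Discriminant fingerprinting (fingerprint_lda)

Axes solve the symmetric-definite generalized eigenproblem
`B v = λ W v`, where `W` is the pooled within-class covariance (plus an
optional explicit ridge; default 0 — no silent regularization) and `B`
the class-size-weighted between-class covariance. Axes are sorted by
decreasing eigenvalue, truncated to `min(g−1, p)`, scaled so each axis
has **unit pooled within-class variance** (classical canonical
discriminant scaling, making score-space within-class geometry
spherical), and sign-fixed so each axis's largest-magnitude coefficient
is positive (eigenvectors are sign-ambiguous; plots must reproduce).
Projection is `(x − grand centroid) · coefficients`. Posteriors use
equal-covariance Gaussian densities in score space with uniform priors
by default — endmember class sizes reflect data availability, not
prevalence. Confidence ellipses scale the group score covariance by the
χ²(2 df) quantile. Fingerprinting runs on raw δ¹³C-EAA values (not
diet-normalized); a calibration hook applies per-analyte additive
offsets to the training set before fitting.

## Overlap (overlap)

The Bhattacharyya coefficient of two Gaussians is computed in closed
form (BC = exp(−D_B)); non-positive-definite covariances raise an error
advising shrinkage. Two group estimators are provided:

* `empirical_group`: per-group sample mean and covariance with optional
  shrinkage toward its own diagonal;
* `empirical_groups_pooled` (pipeline default): per-group means with a
  single pooled within-group covariance, consistent with the
  discriminant model's equal-covariance assumption.

The pooled estimator is the default because a 2-D covariance estimated
from n = 5 is so noisy that the estimated BC of two *identical*
distributions has a null median near 0.72; with the pooled covariance
the null median rises to ≈ 0.92 and the BC is driven by mean separation
alone. The pairing scheme (matched GF/CVZ organ pairs by default, or all
pairs) is always recorded in the result; the headline summary is the
**median** BC over the scheme's pairs.

## Group statistics (stats)

* **Two-way ANOVA** with interaction: classical decomposition on
  balanced designs (all SS types coincide); Type II by model comparison
  on unbalanced data. Zero residual variance (up to numerical noise) is
  flagged and F reported as undefined rather than 0/0. p-values below
  1e−4 format as "< 0.0001".
* **Pillai's trace** V = tr(H(H+E)⁻¹) with the standard F
  approximation, exact when min(responses, groups−1) = 1.
* **Tukey–Kramer letters**: all pairwise comparisons against the
  studentized-range criterion, letters assigned by insert-and-absorb on
  descending means (ties broken by level name). The display satisfies
  the biconditional: two levels share a letter iff their comparison is
  non-significant.
* **Contribution fraction**: Δδₐ = f·mₐ + εₐ with
  mₐ = δ¹³C(microbe)ₐ − δ¹³C(diet)ₐ, solved by least squares and clamped
  to [0, 1]; the interval is a seeded bootstrap over amino acids
  (default 1000 draws). A per-EAA variant (fₐ = Δδₐ/mₐ) is reported for
  comparison with single-EAA literature values. The pipeline feeds the
  estimator **turnover-corrected differential offsets**: raw offsets are
  first inverted through
  `(offset − (1−p)·(δ_old − δ_new)) / p` per organ, then the GF mean is
  subtracted, leaving f·mₐ + noise per organ × EAA. The correction uses
  the same literature turnover fractions a practitioner would use; at
  zero noise recovery is exact.

## Verdict rule and calibration (pipeline)

The report's verdict is a conjunction-first tri-state:

* `evidence` — some organ has a Holm-adjusted significant GF-vs-CVZ
  Pillai test (α = 0.05 family-wise across the four organs) **and** at
  least one EAA in that organ exceeds the differential screen threshold
  in the microbial (positive) direction;
* `no_evidence` — no organ shows that joint signature and the median
  matched-organ BC is ≥ the high-overlap bound;
* `mixed` — otherwise (e.g. fingerprint distributions separate without
  offset corroboration).

An isolated significant MANOVA without screen corroboration does not
block a null call: offsets below the analytical margin are, by the
design's own logic, not evidence of provisioning, and with four organ
tests a lone false positive is expected in ~19 % of null studies.

The high-overlap bound defaults to **0.7**. It is calibrated against the
null sampling distribution of the median matched-organ BC at the default
study size (n = 5 per cell, 2 axes, pooled covariance): over 400
simulated null studies the median BC had median ≈ 0.92 and never fell
below 0.74, so 0.7 sits below the ≈ 0.1st percentile — a truly
overlapping study is essentially never misread — while studies with
genuine separation fall far below it. A bound near 1 (e.g. 0.9) would
misclassify roughly a fifth of truly null studies of this size as
ambiguous, purely from covariance estimation noise. Both the bound and
the estimator (`cov_estimator="per_group"`) are configurable.

## Numerical choices

* Generalized eigensolve via `scipy.linalg.eigh(B, W)` after an explicit
  Cholesky check of `W`; singularity raises an error advising a small
  ridge rather than regularizing silently.
* Eigenvalues clipped at 0; D_B clipped at 0 (BC ≤ 1) against roundoff.
* Covariance PD checks by Cholesky; errors name the remedy (shrinkage).
* Degenerate ANOVA residuals detected at 1e−12 relative to the response
  scale.
* All simulation substreams derive from `(seed, component-code)` pairs;
  seeds are kept below 2³¹.
* Problem sizes in the test-suite and acceptance script (100-study rate
  estimates, 250 studies × 4 organs for test size, 200 studies for the
  screen null rate) were chosen so that binomial standard errors are a
  few tenths of a percentage point — small relative to the asserted
  margins — while the whole suite runs in about a minute.

## Known limitations

* The verdict's evidence criterion requires the screen to fire; very
  small true contributions (roughly f·p·mₐ < 1 ‰, e.g. f ≈ 0.1 with the
  default sources) register in the MANOVA and the contribution estimate
  but yield `mixed` rather than `evidence` — by design, mirroring the
  field's analytical-margin convention.
* The Gaussian closed form is the only BC estimator; with n = 5 per
  group nonparametric overlap estimation is hopeless, and the Gaussian
  assumption is made explicit rather than hidden.
* The contribution estimator assumes a single microbial source pool and
  known turnover fractions; errors in the assumed `p` propagate
  inversely into f̂ for slow-turnover organs.
* Reported per-organ F statistics use the standard one-way MANOVA /
  two-way ANOVA models; published df from other software can reflect
  different model parameterizations and need not match.
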