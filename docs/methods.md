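# Methods

This note documents the models implemented in `eaafinger`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Offsets and the detection rule

All inference runs on diet-normalized offsets Δδ¹³C = δ¹³C(consumer) −
δ¹³C(diet), computed per amino acid against a replicate-averaged diet profile.
Offsets are carried at full floating precision; the single reporting routine
rounds half away from zero (default one decimal, the conventional precision
for δ¹³C data).

The provisioning decision is deliberately strict and directional: microbial
resynthesis predicts the conventionalized (CVZ) group to be *more* ¹³C-enriched
than the germ-free (GF) group, and the conventional 1‰ margin absorbs combined
analytical and biological variability. `detected` therefore requires
`mean(CVZ) − mean(GF) > threshold` with strict inequality; a difference in the
GF-enriched direction sets `direction_consistent = False` and can never be a
detection, whatever its size. Group means are means of per-mouse panel means,
so each mouse contributes one observation regardless of how many replicate
injections it received.

Welch's t is computed from first principles (so printed summary tables can be
tested without raw data): t = (m₁−m₂)/√(s₁²/n₁+s₂²/n₂) with
Welch–Satterthwaite fractional degrees of freedom and a two-sided Student
reference. P values are reported per organ × EAA without multiplicity
correction, matching the per-cell reporting convention of this assay; a Holm
adjustment can be applied downstream by the caller if desired. Degenerate
zero-variance/zero-difference input returns t = 0, p = 1; variance underflow
falls back to the pooled df.

One-way MANOVA uses Pillai's trace V = tr(H(H+E)⁻¹) from between- and
within-group scatter matrices with the standard F approximation
(s = min(p, g−1), m = (|p−g+1|−1)/2, n′ = (N−g−p−1)/2). A ridge of
1e-8 · tr(H+E)/p is added only when H+E is numerically singular. Questions
pooled across factors (e.g. group × organ) are answered by crossing labels
into a single factor on the same machinery; no factorial decomposition is
implemented.

Fligner–Killeen variance testing delegates to `scipy.stats.fligner`. Its
chi-square reference is asymptotic: at n ≲ 20 per group the test is
conservative (measured type-I rates of 0–0.04 at the 5% level), approaching
the nominal rate around n ≈ 100. The calibration check in the test suite
therefore uses large groups; users screening small cohorts should read
non-significance cautiously.

## Fingerprints and the discriminant model

A fingerprint is a sample's EAA vector minus its own mean — a zero-sum pattern
invariant to bulk isotopic shifts (diet baseline, trophic enrichment,
inter-laboratory offsets that are constant across amino acids). Inter-lab
calibration applies a per-EAA additive correction (known − measured reference);
only its non-constant component survives mean-centring. Validation never
imputes: a sample missing any of the six panel EAAs is an error.

The linear discriminant analysis is authored in full rather than delegated, so
its internals are inspectable and serialisable (JSON round trip reproduces
scores bit-for-bit). The fit computes class means, the pooled within-class
covariance W (divisor N−g), and the between-class scatter B of class means
about the overall mean weighted by class sizes; discriminants come from the
symmetric eigenproblem of B in the W-whitened space. Numerical conventions:

- **Zero-sum degeneracy.** Fingerprints live on a (p−1)-dimensional subspace,
  so W is always singular along the all-ones direction. The fit works in the
  span of W's non-null eigenvectors (relative tolerance 1e-10). A ridge of
  1e-8 · tr(W)/p is applied instead — with a logged warning — only if the
  discarded null space carries between-class signal (perfect-separation
  pathology), where truncation would lose information.
- **Scaling normalization.** Columns are scaled so projected within-class
  covariance is the identity; discriminants are ordered by decreasing
  between-class eigenvalue, and the retained count defaults to g−1 (two for
  the three-class bacteria/fungi/plants model).
- **Sign convention.** Each discriminant is flipped so its largest-magnitude
  loading is positive, making plots and serialized models reproducible across
  linear-algebra backends.
- **Priors.** Default to training-class proportions (the behaviour of the
  classical implementations of this analysis); a uniform switch is provided
  because reference libraries are not sampled proportionally to prevalence.
- **Classification.** Gaussian class-conditionals with shared identity
  covariance in score space; posteriors ∝ prior × density; ties (within 1e-12)
  resolve to the first class in sorted label order. With all g−1 discriminants
  retained this is exactly minimum-Mahalanobis-distance classification under
  equal priors, which the tests assert.

Leave-one-out cross-validation refits the model excluding each reference
organism in turn (requiring n ≥ 3 per class so folds stay trainable).
Confidence ellipses use the sample mean and covariance of a group's 2-D
scores with axis half-lengths √(eigenvalue · χ²₂(level)); degenerate
covariance is an error naming the deficiency rather than a silently flat
ellipse.

## Bhattacharyya overlap

Group overlap in discriminant space uses the closed-form Gaussian
Bhattacharyya coefficient, BC = exp(−D_B) with
D_B = ⅛ dᵀΣ̄⁻¹d + ½ ln(det Σ̄ / √(det Σₐ det Σ_b)), Σ̄ = (Σₐ+Σ_b)/2. Gaussian
fits (sample mean, sample covariance) are used rather than kernel density
estimates because per-organ cohorts of five mice make density estimation
unstable, and the closed form is exactly testable against quadrature.

Small samples bound the achievable BC well below 1 even for identically
distributed groups: two independent 5-point samples of the *same* 2-D Gaussian
give a median BC near 0.71 from sampling noise alone, while pooled groups of
20 give ~0.94. The headline GF-vs-CVZ comparison therefore pools the four
organs per group — matching the single pooled ordination this analysis is
plotted in, and meaningful because both groups share the same organ
composition, so organ structure is common signal rather than confound.
Per-organ pairs remain available and are reported alongside, with their
small-n caveat.

The bootstrap distribution resamples members with replacement within each
group and recomputes the BC per draw (degenerate draws redrawn, at most ten
retries); the pooled summary (median, IQR, min, max) runs over all pair × draw
values and is deterministic given the seed. Bootstrap BC draws are biased
slightly low relative to the point estimate because two independent resamples
add resampling noise twice; the summary should be read as a conservative
overlap distribution, not an unbiased estimator of the population BC.

## Two-endmember mixing with turnover correction

The mixing model inverts δ_host = (1−f)·δ_diet + f·δ_microbe per EAA. Two
identifiability safeguards: the endmember separation must exceed 1‰ (below
the analytical margin the ratio is meaningless), and the GF cohort is used as
the zero-contribution baseline,

    f_raw = (mean CVZ offset − mean GF offset) / (δ_microbe − δ_diet),

so organ-specific trophic fractionation — present even without microbes —
cancels in the contrast. This is exactly the contrast the GF/CVZ design
licenses. Finite tissue turnover attenuates the equilibrium signal by the
organ's carbon replacement fraction ρ, so the reported estimate is
f = f_raw/ρ (ρ = 0 leaves the estimate uncorrected, flagged). Reported f is
clipped to [0, 1] with a flag, but the raw value is always retained: negative
raw estimates (GF more enriched than CVZ) are diagnostic evidence *against*
provisioning, not noise to discard.

Uncertainty comes from a mouse-resampling bootstrap (both cohorts resampled
independently). The default interval is Hesterberg's *expanded* percentile
bootstrap: the plain percentile interval is known to undercover at small n
(measured ~87% at nominal 95% with five mice per group), and widening the
quantiles by the t-calibration factor (df = n₁+n₂−2, scale √(n/(n−1)))
restores ~93% coverage in simulation. Plain percentile intervals remain
available via `ci_method="percentile"`.

## The synthetic-data generator

`simulate_experiment` realises the forward model the analysis inverts. Per
group, organ, mouse and EAA:

    equilibrium = (1 − f)·diet + f·microbe          (GF forced to f = 0)
    tissue      = (1 − ρ)·old_diet + ρ·equilibrium  (+ optional trophic term)
    observed    = tissue + biological shift + analytical noise

Parameter defaults are the study conditions this package targets: 5 mice per
group; liver/kidney/muscle/brain with ρ = 0.75/0.60/0.45/0.30 over the 20-day
feeding period; analytical noise σ = 0.2‰ i.i.d. per measurement (the stated
precision of the assay); two diet replicates. Biological scatter is a
per-mouse-per-organ scalar shift (σ = 0.3‰ by default) shared across that
organ's EAAs — modelling mouse-level physiology; no published estimate
separates biological from analytical variance, so 0.3‰ is a modelling choice
sized to keep the combined mouse-level spread near the conventional 1‰ margin,
exposed in the config. Note the mean-centring step removes this shared shift
entirely, so fingerprints see only analytical noise — one reason fingerprint
overlap is a more sensitive null diagnostic than raw offsets.

Diet and endmember profiles default to representative values: a C3
dairy-casein diet protein (δ¹³C-EAA between −27 and −16‰, Thr most enriched,
Leu/Phe most depleted, as casein profiles typically run), a mixed-grain
maintenance chow for the pre-switch diet (enriched ~1–3‰ with a different
fingerprint shape, so tissue memory is organ-visible), and a gut-bacterial
endmember +6–9‰ above the diet per EAA, reflecting resynthesis from
carbohydrate carbon. `study_conditions()` additionally sets the per-organ,
per-EAA trophic fractionation to the published germ-free offset patterns, so
simulated GF organs reproduce the reported organ-specific enrichment and the
pooled fingerprint space has the organ structure the real ordination shows.
The trophic term is applied to both groups identically and is documented as
distinct from microbial provisioning (it cancels in the GF-baselined
contrast).

`simulate_training` draws the three-class reference library (bacteria n = 12,
fungi n = 9, plants n = 11, the published library sizes) around zero-sum class
mean fingerprints separated by a few ‰ with i.i.d. within-class noise
(0.8‰ default), re-centring each draw.

What the generator does **not** emulate: correlated per-EAA measurement error
(chromatographic co-elution), non-Gaussian biological variation, drift between
analytical sequences, diet heterogeneity beyond two replicates, and any
taxonomic structure within classifier classes. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under a
realistic noise budget — not that real instruments or real mice satisfy these
noise assumptions.

## Problem sizes used in the checks

The statistical acceptance checks run at deliberately modest sizes chosen to
make their Monte Carlo error small relative to the asserted tolerances: 50
replicate simulated studies for the null-overlap property, 200 replicates per
contribution level (0, 0.1, 0.25) for estimator recovery and CI coverage,
2000 simulated nulls for the variance-test calibration, and bootstrap sizes of
400–1000. The full suite runs in well under a minute on one core.

## Known limitations

- The Bhattacharyya bootstrap summary is downward-biased at small n (above);
  cross-study comparisons should fix group sizes.
- The mixing estimator assumes a single, known microbial endmember profile;
  with real data this must be supplied (e.g. from the bacterial class of the
  training library) and the inference is conditional on that choice.
- Turnover correction divides by an externally supplied ρ; errors in ρ scale
  f̂ multiplicatively and are not propagated into the CI.
- The MANOVA assumes multivariate normality of offset vectors within groups;
  with five mice per group the F approximation is coarse and the test is best
  read descriptively alongside the univariate Welch results.
- No multi-source (>2 endmember) Bayesian mixing and no nitrogen-isotope
  support; non-essential amino acids pass through the offset/test machinery
  but are given no biosynthetic interpretation.
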