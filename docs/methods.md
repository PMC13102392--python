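# Methods

This note records the models, parameter choices and numerical decisions
behind `ldmorph`, and what the synthetic-data generator does and does
not emulate.

## Droplet geometry

Label masks (0 = background, positive integers = droplets) are
measured with `skimage.measure.regionprops` for labels, pixel counts
and centroids; area is pixel count × pixel_size², centroids are means
of pixel centres × pixel_size. The Feret (maximum caliper) diameter is
computed in-package as the largest pairwise distance between vertices
of the convex hull of the droplet's *pixel corner* points, scaled by
pixel size. The corner convention makes a 1-pixel object √2·pixel_size
across, matching mainstream image-analysis tools, and is validated in
the tests against an O(n²) all-pairs brute force. Objects below a
configurable minimum (default 4 px) are discarded and counted —
stereomicroscope imaging cannot resolve the small secondary droplets of
multilocular adipocytes, so a floor is unavoidable; the exact value is
a free choice. Touching droplets are assumed already separated by the
upstream segmenter.

## Strata

Strata are half-open 200 µm bins `[a + (i−1)w, a + iw)` along the
anterior–posterior axis, anchored at the most anterior droplet
*centroid* (the measured coordinate; anchoring on a droplet edge would
need boundary tracing and changes assignments by at most one stratum).
Half-open intervals with floor indexing make boundary behaviour
deterministic. Raster orientation does not encode anatomy, so the
anterior direction is a configuration choice (`anterior-at-min-x` by
default, matching right-flank imaging with the head on the left).

## The size-scaling smoother and morphology value

Mean LD Feret diameter is regressed on log total SAT area with a
penalized cubic B-spline (P-spline): 10 basis functions on equally
spaced knots, second-order difference penalty, smoothing parameter by
generalized cross-validation over a 31-point log-spaced grid. The
penalty null space contains straight lines, so the fit degrades
gracefully to linear regression under heavy smoothing and reproduces
exactly linear data to machine precision. Natural logarithms are used
throughout (the (exp(β) − 1)×100 back-transform presumes them).
Predictions outside the fitted range extrapolate linearly from the
boundary slope and are flagged. Minimum fit sizes are 8 control fish
for pooled fits and 5 per experiment for experiment-specific fits
(splines need more points than penalty constraints; experiments below
the minimum are dropped with a logged warning). Morphology values are
reported in µm (additive residuals), the scale on which the phenotype
plots live.

Control morphology values are in-sample residuals while mutant values
are out-of-sample deviations. This asymmetry is part of the method
being implemented; it is benign at balanced screen sample sizes (the
null simulations show nominal type-I error) but inflates the KS test
when a batch contributes very few controls, which is why per-experiment
minima are enforced and why severely unbalanced allocations should be
read with care (see the error-control tests).

## Screen statistics

* **KS tests** use scipy's two-sample implementation with the exact
  small-sample null and asymptotic otherwise. Morphology values are
  continuous, so ties have measure zero.
* **Fisher combination**: χ² = −2 Σ ln pᵢ on 2k df, upper tail.
* **Mixed models** are REML fits of statsmodels `MixedLM` with
  experiment as random intercept; fixed-effect p-values are two-sided
  Wald z. Satterthwaite degrees of freedom would differ negligibly at
  screen sample sizes (≥ ~50 fish, ≥ 2 batches); the z approximation
  keeps the dependency surface small. Optimizer fallbacks
  (lbfgs → powell → cg) handle boundary-variance data.
* **FDR** is Benjamini–Hochberg step-up, applied separately to the
  four families (pooled KS, stratified KS, LMM intercept, LMM slope)
  across the multi-experiment genes of a run. Lethal and
  single-experiment genes are excluded from all families; the latter
  are analysed by OLS + KS and flagged preliminary.
* **Classification**: robust = stratified-KS and LMM-intercept adjusted
  p < 0.05; distributional-only = stratified KS only; suggestive = raw
  pooled KS p < 0.05 only; otherwise ns.
* **Power** uses the noncentral t distribution with
  ncp = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2, two-sided α = 0.05 — this
  reproduces the published screen table's power column exactly, row by
  row. The negligible wrong-tail term is clamped to zero where scipy's
  `nct.cdf` underflows. Sample-size search is the smallest integer n
  meeting the target power, with the control group either growing with
  n (equal allocation) or held fixed; published "n fish for 80% power"
  numbers depend on an allocation and sidedness the calculation must
  make explicit, so both are parameters.
* **Replicate consistency** (no canonical formula exists) is defined as
  (fraction of experiment-effect pairs agreeing in sign) × 1/(1 + CV)
  with CV = SD/|mean| of the per-experiment effects: 1 for identical
  replicate effects, 0 for sign-discordant ones, deterministic.
* **Total adiposity** for trait models is total lipid area normalized
  by standard length to a configurable power (default 2, a
  dimensionless relative adiposity).

## Robustness suite

The F-test compares morphology-value variances (mutant/control) with a
two-sided p = 2·min(tail, 1−tail). Skewness and excess kurtosis use the
plain moment (biased) definitions g₁ = m₃/m₂^1.5, g₂ = m₄/m₂² − 3,
matching the usual "moments" convention; tail percentage counts points
beyond 2 sample SDs. The heteroscedastic mixed model keeps the
random-intercept structure but gives each genotype its own residual
variance; it is fit by profiled maximum likelihood (fixed effects
solved by GLS inside the likelihood, Woodbury identities per
experiment, Nelder–Mead over the three log-SDs). With one experiment
the batch SD is fixed at zero — unidentifiable against the intercept —
and the fit reduces to WLS, which the tests verify against the closed
form. The permutation test shuffles genotype labels independently
within each experiment; the statistic is the genotype coefficient with
variance components frozen at the observed-data REML fit (only the GLS
solve is repeated per permutation — a score-type permutation; a full
refit mode exists and agrees on strong effects). The reported p is the
add-one estimator (1 + exceedances)/(B + 1), which cannot be zero; the
raw proportion is also returned. Permutations are two-sided (absolute
effects). Consensus is ALL SIG / ALL NS / MIXED over the
heteroscedastic-LMM, permutation and Welch p-values at α = 0.05.

## Diet response

The paired design images the same fish before and after 14 days of
diet, so the per-fish, per-stratum change Δ = post − baseline removes
fish-level baselines. The per-stratum diet effect is the
difference-in-differences mean Δ(HFD) − mean Δ(control diet); each fish
contributes one Δ per stratum, so the per-stratum test is Welch's t
with the fish as the unit, BH-corrected across strata within genotype.
Strata with fewer than 3 fish per diet arm are reported untestable
(posterior strata thin out). Strata present at only one timepoint
(new posterior growth) are flagged emergent and excluded from paired
contrasts. The overall genotype contrast is the unweighted mean of
per-stratum effects, and blunting is 100×(effect_wt −
effect_mut)/effect_wt rounded to an integer — the arithmetic that turns
stratum-average effects of +24.4 and +7.7 µm into a 68% reduction.

## Synthetic data

The generator is the package's ground-truth source. Wild-type structure:
standard length uniform on 7–12 mm; log depot area = 6.9 + 3·ln(SL) +
N(0, 0.25) (≈2×10⁵–2×10⁶ µm²); expected mean diameter follows the
saturating curve D = 65·(1 − exp(−0.55·(ln A − 11))) µm, floored at
5 µm — a functional form chosen to reproduce the observed curvilinear
rise towards a ~65 µm plateau (the real allometry is not parameterised
anywhere, so the constants target the qualitative regime: the default
194-fish population fits with R² ≈ 0.85). Noise is log-normal on
diameters at every level: per-fish SD 0.04, per-droplet SD 0.35, batch
intercept SD 0.05 — log-scale noise makes the log-linear analysis
models exactly correctly specified, and genotype effects multiplicative
as the mixed model assumes. Genotype effects are a log-scale intercept
shift β (mutant/control diameter ratio exp(β) at fixed area, exact in
expectation), an allometric slope change γ (applied around a reference
log-area of 13.5), and a residual-SD inflation factor. Droplet count is
depot lipid area (60% of SAT area) divided by mean droplet area, so
hypertrophic genes conserve depot area by reducing count — reproducing
the observed inverse count–size relation by construction rather than
assuming independence. Droplets are placed uniformly along the depot
(length √(8·area), aspect 8), with a 3%-per-stratum posterior diameter
deficit; droplet diameters are rescaled so their mean equals the fish's
target exactly, keeping fish-level noise attributable to σ_fish alone.
Default screen design is 2 experiments × (30 controls + 30 mutants) per
gene, the typical replicate structure of such screens.

Diet experiments use 8 fish per genotype per diet arm over 15 strata,
wild-type baseline declining 45 → 24 µm anteriorly to posteriorly,
control-diet growth +4 µm, a wild-type HFD profile linear from 20.7 to
28.1 µm (stratum average +24.4 µm), mutant blunting factor 0.32 (a 68%
true reduction), mutant baseline hypertrophy +22.2 µm declining
1.1 µm/stratum, and Gaussian noise of 5 µm (baseline) and 6 µm (Δ).

Mask rendering draws droplets as non-overlapping filled discs of radius
Feret/2 with a 1-pixel clearance halo, re-jittering collisions; the
ground truth records placed centres and radii. Rendering round trips
(counts exact, Feret within 2 pixel widths) use a reduced lipid
fraction (0.2) because discs at the full 60% area fraction cannot pack
without overlap — real droplets tile the depot without circular
packing constraints.

What the generator does **not** emulate: pigment artefacts and
segmentation errors (masks are perfect by construction), sub-resolution
multilocular droplets, dorsoventral structure, tank/pair effects in the
diet design, and any real count-vs-area allometry beyond the inverse
relation. Passing tests therefore demonstrate correctness of the
statistics under the stated model, and the platform's error-control
properties under batch effects — not robustness to segmentation
failure modes.

## Problem sizes in tests and the acceptance script

Simulation-based checks use 200 replicates for parameter recovery and
error control, 100 for diet blunting, and 50–100 fish for image round
trips; these sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the whole suite around half a
minute. All simulations are seeded and reproducible.

## Known limitations

* The stratified KS test compares in-sample control residuals with
  out-of-sample mutant deviations; with very few controls in a batch
  this asymmetry inflates rejection (documented above, guarded by
  minimum-n rules).
* Wald z inference for mixed models is slightly anticonservative with
  2 batches; the permutation test is the backstop.
* The heteroscedastic model assumes a common batch intercept SD across
  genotypes.
* Figure-style plotting is out of scope; outputs are tables.
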