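# Methods

`camophylo` implements a comparative analysis of cryptic coloration in
sexually dichromatic insects: image-derived color and pattern metrics
for an animal and its local background, phylogenetic regressions
linking animal coloration to background coloration and precipitation,
and a major-axis analysis of sex-specific divergence rates. Because no
raw field data are distributable, every input is emulated by a
first-class synthetic generator, and the statistical machinery is
validated by simulation against the generator's known parameters.

## Image metrics

**Calibration.** Raw RGB rasters are mapped to linear reflectance
per channel by a least-squares straight line through the origin fitted
to the gray patches of a color checker (measured mean vs. known
reflectance). The model assumes a linear sensor with no dark offset;
`calibration.intercept` is deliberately absent rather than configurable
off. Reflectance lives on [0, 1] with pure white at (1, 1, 1); values
pushed out of gamut by calibration are clipped and counted
(`n_clipped`). 8/16-bit PNG/TIFF are read as linear by default; an
`--assume-srgb` flag undoes the sRGB transfer first. RAW demosaicing
and camera spectral mapping are out of scope.

**Color.** Four region-level metrics are computed on the *mean* RGB of
a masked region (stable under mask noise, and matching region-level
measurement of a dorsal surface): brightness (R+G+B)/3; saturation, the
Euclidean distance from white, bounded by √3 on this scale; and the
opponent-channel ratios hue1 = R/G (red vs. green) and hue2 = (R+G)/B
(yellow vs. blue). The absolute saturation values depend on the [0, 1]
normalization convention; this is harmless for the ln-scale regressions
downstream, which only see affine shifts.

**Pattern (granularity).** The pattern channel is the per-pixel mean of
R and G, taken over the mask's bounding box with out-of-mask pixels set
to the in-mask mean (which adds no spurious band energy). The channel
is mean-centered, zero-padded to the next power of two per axis, and
Fourier-transformed; the energy of an annular wavelength band is the
sum of squared spectral amplitudes with wavelength (px/cycle, from the
radial frequency √((u/W)² + (v/H)²)) inside the band, normalized by
(padded × original) pixel count. That normalization makes the Parseval
identity exact: band energies plus out-of-bank residual equal the
mean-centered raster variance to machine precision, padded or not. The
default bank has 15 band centers from 2 to 256 px in √2 steps, edges at
geometric midpoints. Descriptors: overall pattern contrast (total
energy), dominant marking size (band center with maximal energy; ties
break toward the smallest scale), and pattern diversity (dominant
band's share of the total; `diversity="of_rest"` gives the
max/(total−max) variant, and `energy="sd"` the per-band standard
deviation variant used by some granularity implementations). A constant
region has zero total energy; its descriptors are NaN with an
`undefined` flag and the record is excluded downstream. Images coarser
than 15 px/mm cannot resolve the smallest bands and are excluded from
pattern (not color) analysis, with a logged reason.

## Phylogenetic machinery

Trees are rooted, with branch lengths required; Newick IO is backed by
dendropy with added validation (unique tips, finite non-negative
lengths). The Brownian-motion covariance V has V[i,j] equal to the
depth of the most recent common ancestor of tips i and j. Pagel's λ
multiplies the off-diagonal of V, interpolating between a star
phylogeny (λ=0) and the full Brownian expectation (λ=1); the search is
bounded to [0, 1]. Polytomies are rejected in contrasts rather than
silently resolved. Felsenstein's pruning computes standardized
contrasts (x_i − x_j)/√(b_i + b_j), ancestral values as
branch-length-weighted means, and parent-branch extension
b_i·b_j/(b_i+b_j); a cherry whose branch lengths sum to zero is an
error. Contrasts use the branch lengths of the input tree as given.

## PGLS with estimated λ

The model is y = Xβ + ε, ε ~ N(0, σ²V(λ)), fitted by whitening with
the Cholesky factor of V. For each sex and each of the seven traits the
design is the trait's own background counterpart plus ln PDT and ln PWT
(precipitation of driest/wettest trimester, mm), all variables
ln-transformed (non-positive values fail early, naming taxon and
column). With 17 taxa and 3 predictors every model reports df (3, 13).

λ is estimated by maximizing the profile likelihood over [0, 1]: a
21-point grid locates the best cell, then bounded scalar optimization
refines within it; endpoints are admissible, and a flat profile
resolves to the boundary with the grid value retained whenever the
optimizer does not beat it. **The default profile is restricted
(REML), with `method="ML"` available.** The choice is driven by
calibration at the study's sample size: under the null (response
independent of predictors, Brownian residuals, λ=1, n=17, 2,000
replicates) the per-term t-test rejects at 0.068 with REML but 0.098
with ML, because the ML λ̂ is biased low (mean 0.77 vs. 0.93) and
under-corrects the phylogenetic correlation. At fixed true λ the test
is exact (0.046 measured), so the inflation is purely plug-in noise in
λ̂.

*Known limitation — small-sample anticonservatism.* Even with REML,
plugging a noisy λ̂ into the t-test leaves the type-I error above
nominal at 17 taxa, worst at intermediate true λ (measured rejection at
α=0.05: ≈0.05 at λ=0, ≈0.09 at λ=0.5, ≈0.08 at λ=1). Users should read
borderline p-values (0.01–0.10) from 17-taxon models with caution; the
effect vanishes as trees grow (λ̂ is consistent: median recovery within
0.01 at 200 tips in our checks).

Per-term statistics: Wald t = β̂/SE with df = n − p and a type-II F
(the model with and without the term at the same λ̂). The two are
reported separately and are not forced to satisfy F = t² against any
external table. R² is computed from GLS residual sums of squares
against the intercept-only model in the same metric. BH (step-up)
adjustment pools all term-level p-values of the model family run in one
invocation; the pooling scope is recorded in the run metadata.

## Major-axis divergence

Independent contrasts of each ln trait are computed per sex, each pair
sign-flipped so the female contrast is non-negative (contrast signs are
arbitrary; linked flips change nothing), screened once for outliers by
internally studentized residuals of the through-origin OLS fit of male
on female contrasts (|r| > 3 removed; studentized residuals are a
least-squares notion, so the screen uses OLS rather than the MA fit),
and then fitted by major-axis regression through the origin (contrasts
have zero expectation, so no intercept; df = n − 1). The MA slope
minimizes summed squared perpendicular distances; with uncentered sums
it is β = (Svv − Suu + √((Svv−Suu)² + 4Suv²))/(2Suv), and r² is the
squared through-origin correlation. A slope above 1 means faster male
divergence.

The slope-b₀ test uses the correlation r_w between residual-axis scores
(v − b₀u) and fitted-axis scores (u + b₀v), which is zero under the MA
model at b₀, with t = r_w√(df/(1−r_w²)). The 95% interval inverts this
test exactly (Creasy-type): the acceptance region is the root set of a
quartic in b₀, solved in closed form, so test and interval agree by
construction on every dataset, and coverage is exact under the
equal-error-variance MA model (measured 0.95 at n=16 over 1,000
replicates). Two honesty flags replace silent behavior: when the
observed r² does not exceed the critical correlation, *no* slope
magnitude can be excluded and the interval is reported unbounded (NaN
limits) rather than as a misleading bracket; when Suv = 0 the slope's
sign is undefined and the row carries an `independent_evolution` flag —
the expected outcome when a trait evolves independently in the two
sexes. Exactly collinear data yield a zero-width interval and p = 1 at
the true slope.

## Synthetic generator

The generator defines the study conditions; all defaults were fixed
once, from the study design or from what a practitioner would call
realistic, and are not adjusted per experiment.

* **Trees**: pure-birth with n = 17 extant tips by default (the study
  genus has 17 species), completed with the Exp(n·λ_birth) waiting time
  on pendant edges (the simulator otherwise stops at the n-th split,
  leaving a zero-length cherry), rescaled to unit depth.
* **Traits**: generated multiplicatively — exponentials of Gaussian
  phylogenetic fields — so the ln analysis scale is exactly
  linear-Gaussian and every column is positive. Per trait k: ln Bg_k =
  μ_k + B_k with B_k ~ BM(σ_bm², default sd 0.5); ln A_sex,k = μ_k +
  slope_bg·(ln Bg_k − μ_k) + s_sex·D_k + η_sex,k, with D_k a
  BM-λ(σ_resid², sd 0.15) field *shared* between sexes, s_female = 1,
  s_male = √(rate ratio), and η small independent per-sex fields
  (sd 0.05). The residual signal λ_true defaults to 0.5 (moderate).
  Backgrounds are shared between sexes — the two sexes are photographed
  in the same localities.
* Under this linkage with slope_bg = 0, the male-on-female MA slope has
  expectation √(rate_ratio_male_female); a fourfold male rate gives
  slope 2. A nonzero common background term with coefficient 1 on both
  sexes would pull the slope back toward 1, which is why the divergence
  experiments set slope_bg = 0.
* **Climate**: PDT and PWT are log-normal (medians 40 and 600 mm)
  loading on background fields with weight `climate_effect` (0.5) plus
  lognormal noise (sd 0.3 on the ln scale).
* **Textures**: white noise filtered to a ±10% annulus at the target
  spatial frequency, peak-normalized to the requested amplitude, added
  to mean R and G with B constant; out-of-gamut configurations error.

What the generator does *not* emulate: real reflectance distributions,
anisotropic markings, mask segmentation error, unequal per-species
sample sizes, spatial autocorrelation of localities, and climate-trait
confounding beyond a single linear loading. Passing tests therefore
demonstrate correctness of the machinery under the stated model, not
robustness of the biological conclusions to violations of it.

## Numerical choices and problem sizes

Whitening uses Cholesky factors throughout; collinearity is diagnosed
on the raw design matrix, so an ill-conditioned V at λ=1 (near-zero
terminal branches) does not masquerade as predictor collinearity.
Dominant-scale ties break toward the smallest scale; the λ profile ties
at a boundary resolve to the boundary. Simulation-based checks use
fixed seed streams and sizes chosen for tight Monte-Carlo bounds at
interactive runtimes: 100 replicates per λ level on 200-tip trees for
recovery, 2,000 null replicates for t-test calibration, 1,000 for MA
coverage, 500 for power, null-rate, duality, and divergence checks;
`scripts/acceptance.py` re-runs scaled versions of the same
computations (50–1,000 replicates) from a single `--seed`.

## Aggregation and orchestration

Individual photographs reduce to taxon × sex values by the arithmetic
mean (`aggregate="median"` available); weighting by per-species sample
size is not attempted. The response/predictor pairing is always
like-on-like (brightness on background brightness, never
cross-metric). Stages serialize to CSV/JSON and re-running any stage
from its serialized intermediate reproduces downstream outputs exactly;
a fixed seed gives byte-identical outputs.
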