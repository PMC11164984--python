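# Methods

## Overview

`bayescoloc` quantifies the colocalization of two fluorescence channels
across a set of microscopy images and compares it against a control
condition with a Bayes factor. The pipeline is:

1. **Background gating.** Each analyzed channel of each image gets an
   Otsu threshold; only pixels strictly above threshold in *both*
   channels enter the analysis.
2. **Patch correlations.** The image is tiled into an n x n grid of
   equal-area patches; each patch with at least 15 gated pixels
   contributes one correlation coefficient (Pearson by default,
   Spearman or Kendall tau-b optionally) computed over the gated pixels
   only.
3. **Hierarchical model.** The patch correlations of both conditions
   are modelled jointly by a two-level Student-t hierarchy; inference
   is variational (ADVI) with an exact MCMC fallback.
4. **Hypothesis test.** A Bayes factor on the group-level difference
   Δρ = ρ̄_S − ρ̄_C against a practical-relevance threshold Δρ₀
   (default 0.1).

## Background gating

The Otsu threshold maximizes the between-class variance
w₀w₁(μ₀ − μ₁)² over an intensity histogram (256 bins by default,
matching byte-image convention). Candidate thresholds are interior bin
edges. Two conventions are pinned deliberately:

- **Ties take the lowest maximizing edge.** The between-class variance
  curve is exactly flat across an empty-bin gap between two intensity
  modes; a relative tolerance (1e-9) absorbs float jitter along the
  plateau so the choice is deterministic and conservative (more pixels
  kept as signal).
- **Pixels equal to the threshold are background** (strict `>`).

A constant channel raises a degenerate-image error: no threshold
separates two classes, and silently passing everything (or nothing)
would corrupt the downstream correlation.

Intensities are normalized to [0, 1] by the container's dtype maximum
(255, 65535), *not* by the observed maximum, so thresholds are
comparable across images captured with identical settings.

## Patch correlations

Correlations are computed **only over gated pixels**, not over all
pixels of a qualifying patch: background pixels would deflate the
observed colocalization, which is the stated reason for gating in the
first place. A patch needs >= 15 gated pixels (`min_valid`); below
that, the cell is missing, never zero. Remainder rows/columns from the
floor-division tiling are dropped rather than merged into edge patches,
keeping patches equal-area so their correlations are exchangeable, as
the likelihood assumes.

If fewer than 2 patches qualify at the requested grid size, the patch
number per side is halved (n, n/2, n/4, ... down to 2) until a usable
configuration appears; an image with no usable configuration is
excluded with a warning rather than an error. Halving terminates
quickly and is reproducible; the grid actually used is recorded.

The local correlation map is the sliding-window (stride 1) analogue,
with a 7 px window by default (49 px², inside the 10–100 px² band that
is fine enough to resolve subcellular structure but large enough for a
stable coefficient). The Pearson map is computed exactly via windowed
sums (2-D cumulative sums); rank methods fall back to a direct loop.

## Shuffle controls

When no experimental control images exist, a null condition is built
by shuffling the sample images: pixel-wise (destroys everything except
the intensity histogram) or block-wise with 3 x 3 blocks (default),
which preserves short-range autocorrelation inside each block so the
null does not understate the variance of correlation estimates on
spatially smooth images. Choices pinned here:

- The two analyzed channels receive **independent** permutations; a
  shared permutation would preserve the cross-channel association the
  control must destroy.
- Remainder margins not divisible by the block side are left in place
  (logged), preserving the image shape for the mask/patch machinery.
- One shuffled control per sample image (N vs N paired design).

## The hierarchical model

For condition c ∈ {S, C} (sample, control):

    ρ̄_c ~ Cauchy(0, 0.3)  truncated to (−1, 1)
    σ_c ~ Cauchy(0, 0.3)  truncated to (0, 1)
    τ_c ~ Cauchy(0, 0.3)  truncated to (0, 1)
    ν_c ~ Exponential(1)

and for each image I of condition c:

    ρ̄_I ~ Normal(ρ̄_c, σ_c)  truncated to (−1, 1)
    σ_I ~ Normal(σ_c, τ_c)  truncated to (0, 1)
    ν_I ~ Exponential(mean ν_c)
    r_patch ~ StudentT(ν_I, ρ̄_I, σ_I)       for every patch of I

ρ̄_c is the group-level mean correlation (the colocalization
estimand), σ_c the between-image spread of image means, τ_c the spread
of the within-image dispersions, and ν the Student-t degrees of
freedom; the heavy tails make the fit robust to outlier patches. The
ν_I prior is parameterized by its **mean** ν_c (density
(1/ν_c)·e^(−x/ν_c)). The Student-t likelihood is *not* truncated to
[−1, 1] although correlations are bounded: the tails absorb boundary
effects and truncation would buy little at significant cost.

Images contributing fewer than two valid patch correlations are
dropped from the fit with a warning.

### Inference

The default engine is mean-field ADVI: a fully factorized Gaussian in
unconstrained coordinates (logit-type bijections for interval supports,
log for positive), optimized by Adam (learning rate 0.02, 4 Monte-Carlo
samples per step, 10,000 iterations by default) using exact
reparameterized gradients. The gradients of the log joint — including
the parameter-dependent truncation normalizers of the image-level
truncated normals — are derived analytically and verified against
finite differences in the test suite. Optimization starts at the
empirical moments of the per-image correlation lists, which removes
most of the burn-in.

`engine="mcmc"` runs an affine-invariant ensemble sampler (emcee) on
the same unconstrained log density (2D+2 walkers, >= 48; 1,500 burn-in
steps and thinning 3 by default) and is asymptotically exact. It is
the validation fallback and the instrument used for calibration
measurements; it is bit-reproducible for a fixed seed.

Posterior draws (default 100,000) are taken from the fitted
variational distribution or the thinned chains; all draws are checked
against the support constraints after transformation.

### Bayes factor

With posterior and prior draws of Δρ = ρ̄_S − ρ̄_C,

    BF[H1 : Δρ > Δρ₀ : H0 : Δρ ≤ Δρ₀]
      = [P(Δρ > Δρ₀ | data) / P(Δρ ≤ Δρ₀ | data)]
      · [P(Δρ ≤ Δρ₀) / P(Δρ > Δρ₀)]

Both tails are Monte-Carlo proportions. The prior for Δρ is sampled
(10⁵ draws by default) from the two independent truncated Cauchys by
inverse-CDF — the difference of truncated Cauchy variates has no
closed form. A tail with zero sampled mass is replaced by 1/(M+1) and
the BF is flagged as a one-sided bound. Δρ₀ defaults to 0.1 because a
smaller group difference in correlation is rarely biologically
interpretable; the BF-vs-threshold curve (default grid −0.8 … 0.8,
step 0.02) shows the sensitivity to this choice. Evidence labels use
the Lee–Wagenmakers 1/3/10/30/100 bands in both directions.

Summaries are posterior means with equal-tailed 95% credible
intervals (quantile-based, matching the symmetric intervals users
expect), not HDIs.

### Seeding

One master seed drives named substreams (shuffles, inference
initialization and noise, posterior sampling, prior draws) via
`numpy.random.SeedSequence`. Runs with `engine="mcmc"` reproduce
bit-for-bit; `engine="vi"` is run-for-run stable for a fixed seed and
stable across seeds within the Monte-Carlo tolerance documented by the
tests.

## Synthetic data

Two generators make every stage testable without external downloads.

**Correlation level** (`generate_correlations`): draws per-image means
from the truncated normal and patch values from the Student-t exactly
as the model specifies, clipped to [−1, 1] — the natural fixture for
inference tests (parameter recovery, engine cross-checks).

**Pixel level** (`generate_image_pair`): places random disks
("cells") on a dark noisy background (default 256 x 256 px, 12 cells,
radius 12–28 px, background level 0.06, noise sd 0.02). Inside disks,
the two channels are monotone sigmoid maps of bivariate standard
Gaussians correlated via the 2 x 2 Cholesky factor, scaled into the
bright band (0.45, 1]; the monotone map approximately preserves the
latent correlation (checked empirically to ±0.05). Foreground and
background are bimodally separated by construction, so Otsu gating
recovers >= 95% of true foreground pixels at the defaults. An optional
radial intensity gradient per cell introduces within-cell
autocorrelation for block-shuffle tests.

The pixel-level generator deliberately does **not** emulate PSF
convolution, photon (Poisson) noise, saturation, chromatic shift, or
realistic nuclear/cytoplasmic morphology. Passing tests therefore show
that the statistical machinery recovers a known intensity-correlation
signal under idealized imaging, not that the method is robust to those
acquisition artifacts on real data.

## Numerical choices

- ν is floored at 0.01 inside the likelihood (Student-t is undefined
  at ν ≤ 0 after float underflow); negligible prior mass is affected.
- Truncated Cauchy/normal sampling is inverse-CDF on the truncated
  interval: exact, rejection-free, seed-stable.
- Truncation normalizers use `scipy.special.ndtr` with a floor of
  1e-300 to avoid log(0) in extreme tails.
- Patch correlations are clipped to [−1, 1] against rounding excursions
  from the underlying library routines.
- Test and validation runs use reduced problem sizes (e.g. 96–256 px
  images, 1,000–4,000 ADVI iterations, 10⁴ posterior draws) chosen so
  the documented tolerances are still met; the defaults above are the
  recommended analysis settings.

## Known limitations

- **Mean-field variance underestimation.** The factorized Gaussian
  family ignores posterior correlation between the group mean and the
  image-level means, so its credible intervals tend to be somewhat
  narrower than the exact-sampler intervals. For publication numbers,
  confirm the interval with `engine="mcmc"`.
- **Frequentist coverage at few images.** With 6 images per condition,
  the 95% credible interval of ρ̄_c can cover a fixed true value less
  often than nominally: when the few image means happen to cluster
  tightly, the hierarchy infers a small σ_c and produces a
  correspondingly tight interval. This is a property of the model at
  small n (and of variance-adaptive intervals generally), not of the
  samplers. More images per condition is the only real cure.
- Patch correlations are treated as exchangeable within an image; the
  model does not represent spatial dependence between neighbouring
  patches beyond the image-level random effects.
- Single 2-D plane per channel: z-stacks and time series are out of
  scope, as are object-based colocalization measures (Manders,
  Costes) beyond the correlation framework implemented here.
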