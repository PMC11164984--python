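# bayescoloc

Bayesian colocalization analysis of two-channel fluorescence microscopy
images.

Colocalization — the spatial overlap of two fluorescently labelled
molecules — is commonly quantified by correlating pixel intensities
between channels. Doing that well requires (a) removing background
pixels without manual annotation, (b) respecting the spatial
autocorrelation of microscopy images, which makes naive per-pixel
t-tests overconfident, and (c) comparing against a proper control
condition. `bayescoloc` addresses all three for people analyzing
immunocytochemistry or similar two-channel data in batch: background
is gated automatically per channel by Otsu's method, correlations are
computed patch-wise (each n x n grid cell contributes one coefficient,
so the effective sample size is patches, not pixels), and a
hierarchical Bayesian model compares the sample condition against
control images or against pixel-/block-shuffled null images.

## Model

Patch correlations r of image I in condition c ∈ {S, C} follow a
two-level Student-t hierarchy:

    ρ̄_c ~ Cauchy(0, 0.3) on (−1, 1)     σ_c, τ_c ~ Cauchy(0, 0.3) on (0, 1)
    ν_c ~ Exponential(1)
    ρ̄_I ~ Normal(ρ̄_c, σ_c) on (−1, 1)   σ_I ~ Normal(σ_c, τ_c) on (0, 1)
    ν_I ~ Exponential(mean ν_c)
    r ~ StudentT(ν_I, ρ̄_I, σ_I)

The estimand is the group difference Δρ = ρ̄_S − ρ̄_C, tested by the
Bayes factor

    BF[H1 : Δρ > Δρ₀ : H0 : Δρ ≤ Δρ₀]
      = P(Δρ > Δρ₀ | data) / P(Δρ ≤ Δρ₀ | data) · P(Δρ ≤ Δρ₀) / P(Δρ > Δρ₀)

with Δρ₀ = 0.1 by default. Inference is mean-field ADVI with exact
analytic gradients (an exact ensemble-MCMC engine is available as
`--engine mcmc`). See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic dataset with known ground truth (six sample
images with true foreground correlation 0.7, six uncorrelated control
images), then analyze it:

```sh
coloc synth --rho 0.7 --rho-control 0.0 --n-images 6 --out demo/fixtures
coloc run --sample-dir demo/fixtures/sample \
          --control-dir demo/fixtures/control \
          --patches 16 --iterations 10000 --samples 100000 \
          --seed 42 --out demo/out
```

which prints

```
BF = 136172 (extreme evidence for H1); summary: demo/out/summary.json
```

and `demo/out/summary.json` contains (abridged):

```
"posterior": {
  "rho_S":     {"mean": 0.704, "lo": 0.669, "hi": 0.736},
  "rho_C":     {"mean": 0.009, "lo": -0.058, "hi": 0.075},
  "delta_rho": {"mean": 0.695, "lo": 0.621, "hi": 0.769}
},
"bf": 136172.12, "evidence": "extreme evidence for H1", "delta_rho0": 0.1
```

Reading: the sample condition's group-level correlation is estimated
at 0.70 (95% credible interval [0.67, 0.74], recovering the simulated
truth of 0.7), the control sits at 0.01, and the data favour a group
difference larger than 0.1 by a factor of ~10⁵ — decisive evidence of
colocalization. The output folder also holds, per image, a patched
correlation map, a local (sliding-window) correlation map and the
background mask, plus the posterior, Bayes-factor and BF-vs-threshold
plots — 3n + 3 plot artifacts for n sample images, each backed by a
CSV/JSON sidecar with the underlying numbers.

Real data follow the same layout: one folder per condition, one file
per channel named `[image name]_c[channel ID].tiff` (also
tif/png/jpg/jpeg). Without control images, use
`--control-mode block` (3 x 3 block shuffling, preserving short-range
autocorrelation) or `--control-mode pixel` instead of
`--control-dir`.

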