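# Methods

## The model

`mregle` implements joint ("M-style") representation learning for genetic
discovery on multimodal physiological waveforms, with the unimodal
("U-style") alternative as the built-in baseline. The pipeline has three
stages:

1. **Representation.** The modalities are fused *before* learning — equal-length
   leads stacked as channels (12-lead ECG: 600 samples x 12 channels) or
   unequal-length waveforms concatenated into one channel (lead I ECG + PPG:
   600 + 100 = 700 samples) — and a variational autoencoder compresses the
   fused record into d latent coordinates. The U-style baseline trains one
   autoencoder per modality at a matched total budget (8 + 4 vs 12 for
   ECG + PPG; 12 x 8 = 96 for the 12 leads) and concatenates the embeddings.
2. **Orthogonalization and association.** The embeddings are projected onto
   all of their principal components (no dimension loss), making the
   coordinates exactly sample-uncorrelated. Each coordinate is regressed on
   each variant by OLS adjusted for age, sex, BMI, smoking status,
   genotyping array and 15 genetic PCs; the per-coordinate Wald chi-squared
   statistics are summed per variant and referred to chi-squared(m). Because
   the coordinates are uncorrelated this is a valid test, asymptotically
   equivalent to a MANOVA of the m-variate embedding on the variant.
   Genome-wide significant hits are greedy clump leads (p < 5e-8, mutually
   independent at r^2 < 0.1 in a reference panel); loci are the LD spans
   (r^2 >= 0.1) of the hits, merged when separated by fewer than 250 kb.
3. **Risk scores.** Hit dosages feed an elastic net (l1_ratio searched over
   [0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0] with 5-fold CV) fit on the training
   split; models are compared by paired bootstrap (100 replicates) of AUROC
   and AUPRC.

## Preprocessing

ECG waveforms are band-pass filtered (0.05–40 Hz) with a windowed-sinc
(Hamming) FIR kernel, default 255 taps at an assumed 500 Hz sampling rate,
applied forward-backward for zero phase. The sampling rate is an assumption
surfaced as a required parameter — the 600-point median complex spans about
1.2 s at 500 Hz. Two numerical choices matter:

* At 255 taps the 0.05 Hz corner lies far below the kernel's frequency
  resolution, so the kernel is re-centered to have exactly zero DC gain;
  constant offsets (baseline wander in the limit) are removed exactly while
  the pass band is perturbed only by the removed residue (|sum(h)| ~ 1e-2
  spread over 255 taps).
* PPG median beats are already clean and are not filtered by default; a flag
  enables filtering any modality.

Quality control computes four statistics per waveform (minimum, maximum,
mean, median) and drops a record when any statistic falls outside the
inclusive [0.1, 99.9] percentile interval of that statistic within its
modality. The cutoffs are the outer order statistics bracketing the
requested percentiles (low bound rounds down, high bound rounds up), so the
bounds are always attainable: constant datasets and two-record inputs
survive. The per-modality scale factor is the 90th percentile (linear
interpolation) of per-waveform max |value| over the *training split only*;
every waveform of the modality, in every split, is divided by it, which puts
roughly 90% of training waveforms inside [-1, 1] while ignoring outliers.

Splits are a pure function of the sample id: the first 8 bytes of its
SHA-256 digest, modulo 1000, allot buckets 0–699/700–899/900–999 to
train/val/test (70/20/10). The assignment is identical across runs,
machines and languages.

## The autoencoder

The representation model is a dense encoder/decoder beta-VAE written on
numpy with reverse-mode gradients and Adam, chosen to train deterministically
in seconds on one CPU at the package's problem sizes (n ~ 2000–3000,
700-dimensional inputs). The encoder applies fully connected layers (default
widths 128, 32, tanh) and emits the posterior mean and log-variance; the
decoder mirrors the encoder with a linear output layer. The loss is the
per-sample sum of squared reconstruction errors plus beta times the KL
divergence to the standard-normal prior (beta default 1e-3; beta and the
input scaling interact, so they are exposed together). With beta = 0 and
latent sampling disabled the model *is* the plain convolutional-autoencoder
baseline's dense analog, and on linear data it converges to the principal
subspace — both facts are exploited as test oracles. Embeddings are always
the posterior means, never samples, so downstream association phenotypes are
deterministic; checkpoint selection keeps the parameters with the lowest
validation loss, which makes generous epoch budgets benign. Model selection
across hyper-parameter candidates first filters at max |off-diagonal
correlation| <= 0.1 on validation embeddings, then takes the lowest
validation reconstruction loss, falling back to the least-correlated
candidate (with a warning) when none pass.

PCA baselines use exact SVD with a deterministic sign convention (the
largest-|loading| element of each component is positive), which pins down
the sign indeterminacy that would otherwise break reproducibility.

## Synthetic data

The generator produces the statistical structure the pipeline assumes, not
physiological realism:

* **Waveforms.** waveform_m = B_m [u, v_m] + noise, with u shared across
  modalities and v_m modality-specific. Each modality's loading basis B_m is
  a random rotation of a smooth dictionary (8 Gaussian bumps + 4 harmonic
  pairs), QR-orthonormalized so the configured factor variances are exactly
  the waveforms' principal variances — without this, random loading
  correlations concentrate variance and the nominal spectrum is not the
  realized one. Defaults: 6 shared factors (variances 5·0.8^j), 4/3
  modality-specific factors for ECG/PPG, per-point noise SD 0.05. The
  reconstruction benchmark uses a richer setting (8 shared + 4 specific per
  modality) so that no per-modality budget below 12 captures everything.
* **Genetics.** Dosages are Binomial(2, maf) per variant (Hardy-Weinberg),
  with an optional Gaussian-copula AR(1) mode that induces decaying LD for
  the clumping tests. Variant metadata (realized maf, info = 1, missingness
  = 0, exact HWE test p) is filled consistently. Genetic shared factors are
  u_j = sqrt(h2)·(standardized score of 3 causal variants) + sqrt(1-h2)·noise
  with h2 = 0.35 — about 12% of factor variance per causal variant, sized so
  a faithful embedding coordinate reaches genome-wide significance at
  n = 2000 while a degraded one may not.
* **Calibration model.** Ten factors F_j = X b_j + e with equicorrelated
  noise ((1-rho)I + rho J), only b_1 nonzero. The documented reference
  effect is b_1 = 0.001; at desk-scale n that is indistinguishable from the
  null (non-centrality n b^2 var(X) ~ 0.002 at n = 5000), so the study
  applies an effect-scale multiplier, default 90, chosen from the
  non-centrality (~17) needed for roughly one-half MANOVA power at n = 5000.
* **Toy two-modality model.** M1 ~ MVN([F, 0.1 s], I),
  M2 ~ MVN([F, 0.2 s], I), Y = 0.05 s + sum(F) + 0.8 e, all of F, s, e
  independent standard normal. The model does not pin down how the
  two-column F enters scalar Y; the package uses the column sum, with the
  combiner exposed. The M-style embedding is the joint PCA truncated to
  (number of true factors + 1) = 3 coordinates by default (configurable);
  the U-style takes two PCs per modality.

What passing tests on these generators do **not** show: robustness to real
waveform morphology, missing modalities, population structure or relatedness
(the association engine is plain OLS, appropriate for the unrelated
synthetic cohorts), LD beyond AR(1), or covariate confounding of the
embeddings (covariates are generated independent of waveforms by default).

## Numerical choices

* Association scans residualize phenotypes and dosages against the covariate
  design once (Frisch–Waugh) and then vectorize the per-variant simple
  regressions; dof = n − q − 1 with q the design rank. Monomorphic variants
  yield NA rows; collinear covariates raise.
* p-values are computed in log space and floored at the smallest positive
  normal double; log10 p is reported alongside.
* The MANOVA oracle uses the rank-one identity Lambda = 1/(1 + T²/v_e) and
  refers T² to chi-squared(m), which reduces exactly to the univariate Wald
  test at m = 1.
* Zero-variance embedding components are dropped during orthogonalization
  with a loud warning, because the retained count m is the combined test's
  degrees of freedom.
* The clumping window is 500 kb each side (the r² and 250 kb merge rules are
  fixed; the window is not specified by the method and is exposed as
  configuration). Panel r² uses mean-imputed dosages. Locus gaps compare
  start − previous end, so a gap of exactly 250 000 bp stays unmerged.
* Elastic-net selection applies a parsimony rule on paired fold differences:
  among all (l1_ratio, alpha) whose mean CV error is within two paired SEs
  of the minimum, the largest alpha wins. Pure-noise fits collapse to the
  null model while effects of a few percent variance survive; the plain CV
  minimum leaves small nonzero weights on noise, and a marginal-SE 1-SE rule
  occasionally zeroes genuine effects.
* Binary phenotypes are fit as 0/1 linear targets by default (the same
  estimator as continuous traits); an elastic-net logistic option exists
  behind `method="logistic"`.

## Problem sizes

The shipped studies are sized for a single CPU: calibration uses 1000
replicates at n = 5000 (about half a minute), the toy study 200 replicates
at n = 50 000, the reconstruction benchmark n = 3000 with budgets
{1, 2, 4, 8} per modality and 120 training epochs, and the end-to-end
benchmark 20 seeds at n = 2000 with 500 variants and 60 epochs. These sizes
are the package's defaults; every study accepts larger values.

## Known limitations

* The autoencoder is dense, not convolutional; it has no translation
  equivariance and would need more capacity for raw (non-median) waveforms.
* Whole-genome-regression association (mixed models) is out of scope; OLS
  is only appropriate for unrelated cohorts.
* The VAE latent space is identifiable only up to permutation and sign; all
  downstream steps are invariant to this because of the PCA
  orthogonalization.
* U-style and M-style comparisons assume complete cases; samples missing a
  registered modality are excluded.
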