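# Methods

## Model

`vbcca` estimates effective (directed) connectivity among N brain regions
from fMRI time series. Neuronal activity is a latent vector autoregressive
process of order P,

    s(t) = Σ_{p=1}^{P} A^(p) s(t−p) + η(t),        η(t) ~ N(0, Λ⁻¹),

and the observed BOLD signal of region i is a causal convolution of that
activity with a region-specific hemodynamic response function (HRF) plus
white noise,

    y_i(t) = Σ_{k=1}^{L} h_i(k) z_i(t−k+1) + ε_i(t),   ε_i(t) ~ N(0, β_i⁻¹),

where z(t) = B x(t) + κ(t), κ(t) ~ N(0, ϑ⁻¹ I), is a Gaussian proxy of the
neuronal series: x(t) is the P-lag embedding of s(t), B = [I_N 0] extracts
the current sample, and the proxy node decouples the hemodynamic
deconvolution from the state-space estimation, keeping the Kalman state at
dimension PN instead of NL.

A nonzero coefficient a_ij^(p) means region j's past helps predict region
i, i.e. influence j → i. Sparsity is imposed through zero-mean Gaussian
priors on the coefficients whose precision γ_ij is *shared across lags*
(one precision per connection — automatic relevance determination with
group structure, the Bayesian analogue of ℓ1ℓ2 regularization). A Jeffreys
hyperprior on γ_ij lets precisions of unsupported connections grow without
bound, pruning them. Λ gets a Wishart prior (ν₀, W₀), β_i a gamma prior.

## Inference

The posterior is approximated by mean-field variational Bayes with factors
q(x) q(z) q(A) q(Γ) q(Λ) q(β), updated cyclically:

1. **q(z), per region** — a ridge deconvolution with a circulant structure:
   on a zero-padded embedding of length M (next power of two ≥ T + L) the
   convolution matrix is circulant, so the posterior mean and covariance
   are diagonal in the Fourier domain; only the first covariance row is
   ever represented. Cost O(M log M) per region.
2. **q(x)** — a variational Kalman (Rauch–Tung–Striebel) smoother on the
   PN-dimensional embedding with ⟨z(t)⟩ as observations, observation
   covariance ϑ⁻¹I, transition ⟨Ã⟩ (companion form) and process covariance
   with top-left block ⟨Λ⟩⁻¹. Cross-time covariances Σ_{t,t−1} are
   propagated alongside the smoothed marginals; the recursion runs down to
   t = 0 so the smoothed prior state is available to the sums below.
3. **q(A)** — Gaussian; the N²P-dimensional mean solves a linear system
   whose matrix is P₁ ⊗ ⟨Λ⟩ plus the diagonal ARD term. The system is
   solved by preconditioned conjugate gradients using the Kronecker
   structure (matrix-vector products cost O(N²P·NP)); a Jacobi
   preconditioner absorbs the enormous dynamic range of the ARD precisions,
   and the solve warm-starts from the previous cycle. Posterior variances
   are approximated by the inverse diagonal of the precision.
4. **q(Λ)** — Wishart with ν = T + ν₀ and W⁻¹ = ⟨P₂⟩ + W₀⁻¹, where ⟨P₂⟩ is
   the expected sum of squared one-step prediction residuals.
5. **q(γ_ij)** — gamma with shape P/2 and inverse scale
   ½ Σ_p (⟨a_ij^(p)⟩² + var a_ij^(p)); the shared-across-lags grouping.
6. **q(β_i)** — gamma with shape T/2 + a⁰_β; the inverse scale includes the
   trace term tr(HᵀH Σ^z) evaluated from the circulant spectrum.

Iteration stops when the max-norm relative change of ⟨A⟩ falls below
`tol` (default 1e−4) or after `max_iter` (default 200) cycles. The fit is
deterministic: no randomness enters after the data are generated.

### Deterministic parameters

Given a user-supplied noise-variance estimate σ² (required), and after
rescaling the observation so its mean squared amplitude is `rms_target`
(default 6.0; σ² is co-scaled, making all outputs invariant to the data's
absolute scale):

| parameter | default | meaning |
|---|---|---|
| ϑ | 10/σ² | proxy precision; acts as the deconvolution ridge |
| a⁰_β, b⁰_β | c, c·σ² with c = 1e9 | pins the noise precision near 1/σ² |
| ν₀, W₀ | 1, 1e−3·I | keeps ⟨Λ⟩ from diverging when the HRF hides the high-frequency innovations |
| γ cap/floor | 1e12 / 1e−12 | overflow guard that preserves effective pruning |
| CG | rtol 1e−8, ≤10·N²P iters | relative-residual stopping |

### Treatment of the latent second moments

The coefficient and innovation updates consume Σ_t ⟨x(t−1)x(t−1)ᵀ⟩ and
Σ_t ⟨s(t)x(t−1)ᵀ⟩. Two treatments are implemented:

* `state_moments="full"`: the complete mean-field expectation — smoothed
  means plus smoothed covariances and cross-time covariances.
* `state_moments="means"` (default): the smoothed trajectory is used as a
  point estimate, in the same spirit as the ⟨AᵀA⟩ = ⟨A⟩ᵀ⟨A⟩ simplification
  applied to the coefficients.

The default is "means", for a substantive reason. The HRF destroys the
neuronal signal's content above a fraction of a hertz, so the smoothed
covariances at those frequencies are filled in by the *current model* — a
self-consistent-field feedback. Summed over time, that imputed mass acts as
a strong ridge on the coefficient solve. The directional information in
heavily downsampled two-region data lives in a weak contrast between two
almost collinear deconvolved series, exactly the subspace such a ridge
crushes: with "full" moments the two-node benchmark (delay 100 ms, TR
150 ms, SNR 0 dB) yields d-Accuracy ≈ 0 — a systematic causality
*inversion* — while "means" yields ≈ 1 and also reproduces the known
inversion behaviour of Granger causality on the same data. The "full" path
remains available and is the form the dense-oracle equality tests exercise.

### Steady-state covariance freezing

For a time-invariant system the filter covariance recursion is a Riccati
iteration that converges geometrically; the backward covariance recursions
reach their own steady state likewise. Once the step-to-step change falls
below `freeze_tol` (default 1e−9, max-abs) the covariance-dependent
quantities are held fixed, covariance sums over the frozen stretch are
accumulated in closed form, and only the cheap mean recursions continue.
This is what makes N = 200, T = 500 fits take under a minute per cycle
batch; with `freeze_tol=0` the full recursion runs and the unit tests
verify both paths agree.

## Synthetic data

Two generator families define the benchmark conditions:

* **Random sparse networks** — ⌈N/2⌉ unidirectional connections drawn
  without replacement over unordered region pairs and oriented at random
  (a pair is never activated in both directions); all P lag coefficients
  of an active connection are N(0, 0.05) — read as *variance* 0.05, the
  (mean, variance) Gaussian notation used for every other distribution in
  this codebase; inactive cross coefficients and all self-coefficients are
  exactly zero; innovations are unit variance. Draws whose companion
  spectral radius reaches 0.999 are rejected and resampled (the attempt
  count is recorded). The neuronal series (T = 500 by default) is convolved
  per region with the canonical HRF on a 1 Hz grid (L = 30) and i.i.d.
  Gaussian noise is added at the requested SNR, defined as
  10·log₁₀(Σ_t‖y(t)−ȳ‖² / (NTσ²)) with ȳ the per-region temporal mean.
  The σ² that solves this identity is returned with the data and handed to
  the estimator as the "known" noise level.
* **Two-node delay/TR sweeps** — a two-region process at 1 kHz for 240 s
  with self-coefficients 0.95 at lag 1 and one cross coefficient of
  magnitude Uniform[0.4, 0.9] at lag d = delay in milliseconds, direction
  chosen at random; per-region HRF convolution at 1 kHz (canonical, or
  randomized time-to-peak uniform on [2.5, 6.5] s with the undershoot-delay
  parameter fixed at 16 s); pure decimation to the target TR (no anti-alias
  filter — aliasing is part of the phenomenon under study); then noise at
  the requested SNR. Three HRF modes control what the estimator is told:
  `fixed` (canonical everywhere), `random` (randomized generation, the
  estimator wrongly assumes the canonical kernel), `return_true_hrf`
  (randomized generation, true kernels supplied).

HRF kernels are amplitude-normalized double-gamma shapes (difference of two
unit-rate gamma densities, undershoot ratio 6:1, positive peak scaled to
one). The canonical kernel peaks at 5 s with its post-peak minimum at
15.75 s.

What the generators deliberately do **not** emulate: slow scanner drifts,
physiological (cardiac/respiratory) noise, motion, spatially correlated
noise, nonlinear (Balloon-type) hemodynamics, and modulatory non-stationary
coupling. Passing benchmarks here therefore shows that the inference
recovers the model's own structure under realistic sampling and noise — not
that it survives every artifact of real scanner data.

## Evaluation metrics

* **Undirected AUC** — each unordered pair is scored by
  max(c_ij, c_ji) where c_ij = Σ_p |⟨a_ij^(p)⟩| (absolute values: the
  coefficients are signed, the connectivity scores must be nonnegative);
  the ROC is swept over all distinct score values with midrank tie
  handling, so the AUC equals the normalized Mann–Whitney statistic.
  Diagonals are excluded.
* **d-Accuracy** — the fraction of true connections with the larger score
  in the true direction; exact ties earn half credit (our convention; an
  unbiased choice under random ties).
* **Normalized MSE** — Σ‖s−ŝ‖² / Σ‖s‖² for the latent-series estimate.

The conditional Granger baseline fits the full least-squares VAR on all
regions and, per candidate source, the reduced VAR excluding that region's
lags; gc(j→i) = ln(RSS_reduced/RSS_full) for region i, floored at zero.
Regions are demeaned first (whether the reference toolbox also detrends is
not documented; demeaning alone is used here). Order selection, when
requested, minimizes the multivariate BIC over orders 1..20.

## Problem sizes used in the shipped checks

The acceptance-level tests and `scripts/acceptance.py` run scaled-down
replicate counts chosen as desk-scale versions of the original designs: 10
replicates (instead of 50) for the 200-region contrast, with the VB fit
capped at 60 cycles at that size; 50 replicates for the two-node regimes;
20 seeds for the small-network recovery and order-mismatch checks; 500
replicates for the random-detector calibration. Full-scale presets
(50 replicates, 40×40 TR/delay grids) ship in `vbcca.benchmark.PRESETS`.

## Known limitations

* The mean-field proxy caps the information the coefficient update can see
  about unrecoverable frequency content (the proxy posterior variance is at
  most ϑ⁻¹ per sample), so latent-state uncertainty is understated; the
  "means"/"full" dichotomy above is the visible consequence. Neither
  treatment reaches the detection ceiling of an estimator with direct
  access to the neuronal series: on the random-network benchmark at N=200
  the VB fit on the *observed* BOLD attains AUC ≈ 0.6 where the same
  ARD machinery on the noise-free neuronal series attains ≈ 0.96.
* Both this method and Granger causality can invert the estimated direction
  under downsampling; the two-node sweeps map out exactly where.
* The evidence (ELBO) is not computed; convergence is declared on
  coefficient stability.
* The HRF is assumed known per region; it is not estimated.
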