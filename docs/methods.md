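# Methods

## The model

`phenocae` implements a *compositional autoencoder* (CAE) that factorizes
hyperspectral plant phenotypes into genotype, macro-environment
(field/year) and micro-environment (plot/replicate) latent components, and
compares the resulting representations against a vanilla autoencoder, PCA
and raw spectra on downstream trait prediction.

The unit of computation is the *genotype group*: the P = E·N plots of one
genotype across E environments with N replicates each, ordered
environment-major (all replicates of environment 1, then environment 2).
One forward pass is

1. **Encode** — a shared MLP maps each plot's spectrum (input width W,
   values in [0, 1]) to a per-plant latent of width d = zg + ze + zp.
   Hidden layers use SELU; the encoder output layer is linear.
2. **Fuse** — a single linear layer (with bias, no activation) maps the
   concatenation of the P per-plant latents (length P·d) to a group-level
   *fused* latent of length D = zg + E·ze + P·zp.  Its slot map is fixed:
   one genotype block Zg, then E macro-environment blocks Ze(e), then P
   micro-environment blocks Zp(p).
3. **Compose** — plant p's latent is reassembled as
   [Zg | Ze(env(p)) | Zp(p)], env(p) = ⌊p/N⌋.  By construction all plants
   of a group share Zg bit-exactly and plants in the same environment
   share Ze.
4. **Decode** — a shared MLP mirroring the encoder (sigmoid output)
   reconstructs each plant's spectrum from its composed latent.

The vanilla autoencoder is the identical encoder/decoder pair without
fusion or composition, one sample at a time.

### Loss

Training minimizes `MSE + λ · CorrLoss`, where the correlation loss is the
sum of |r_ij| over the off-diagonal upper triangle of the D×D Pearson
matrix of fused-latent dimensions, computed across the groups of the
(full) batch.  The penalty discourages information about one factor from
leaking into another block's dimensions.

Two numerical points matter:

- **Zero-variance guard.** Pearson denominators carry +1e-8 so dead latent
  units early in training cannot produce NaNs; a zero-variance column
  contributes r = 0.
- **Scale of λ.** The penalty is an *unnormalized sum* over D(D−1)/2
  pairs with a sampling floor of about D(D−1)/2 · √(2/π)/√B (the expected
  |r| of independent dimensions estimated from B groups) — roughly 40–90
  for D = 36 and B ≈ 100–200, versus reconstruction MSEs of order 1e-3 to
  1e-2.  The default λ = 3e-5 (≈ 0.02 in mean-|r| units at D = 36) keeps
  the penalty a fraction of the reconstruction term; larger values
  visibly stall reconstruction and degrade downstream accuracy.  λ = 0
  recovers pure-reconstruction training.

Analytic gradients (backprop through encoder, fusion, composition,
decoder, and the |r|-sum penalty) are verified against central finite
differences at 1e-4 relative tolerance in the test suite.

### Training protocol

- **Split**: 85/15 train/validation at the *group* level, so no genotype
  straddles the split (a plot-level split would be ill-typed for a model
  that consumes whole groups).  Training size is ⌊0.85·G⌋.
- **Masking**: each epoch, every encoder input entry is independently
  zeroed with probability 0.20 (fresh mask per epoch); reconstruction
  targets stay unmasked, and validation is computed unmasked.  Masking is
  not merely a regularizer here: full-batch quasi-Newton optimization on a
  fixed objective converges to a poor stationary point within one epoch,
  while the per-epoch mask refresh supplies the stochasticity that keeps
  optimization moving and forces the network to reconstruct a plot from
  its group's shared information.
- **Optimizer**: full-batch L-BFGS (scipy L-BFGS-B; history 10,
  strong-Wolfe line search) with up to 400 inner iterations per epoch,
  warm-started across epochs.  Desk-scale problems need on the order of
  2000 quasi-Newton iterations; with a much smaller per-epoch budget,
  patience-based stopping fires long before convergence.  Adam and SGD
  are available as config options.
- **Early stopping**: patience 15 on the validation *reconstruction* MSE.
  The validation correlation term is dominated by sampling noise at
  typical validation sizes (B ≈ 30 groups) and, if monitored, stops
  training almost immediately; both components are logged per epoch and
  monitoring the total remains a config option.  The returned checkpoint
  is the best-validation one, not the last.
- **Reproducibility**: one integer seed drives initialization
  (fan-in-scaled uniform, encoder and decoder drawn before fusion so CAE
  and vanilla runs share starting weights), the split, and the masks;
  identical seeds give bit-identical runs up to BLAS accumulation order.

### Architecture defaults

For 2151-band field spectra the default hidden stack is 2150/1024/512
(the first hidden width is one less than the input width; both are
configurable) with latent layout (zg, ze, zp) =
(12, 4, 4), E = N = 2, i.e. d = 20 and D = 36.  All widths, depths and
layouts are configurable; the depth and layout grids
(1–4 hidden layers; layouts (6,2,2) through (48,16,16)) are available
through the sweep harness.  Tests and the acceptance script use smaller
panels (G = 150–200 genotypes, W = 150–500 wavelengths) and narrower
hidden stacks (48–64 units), which train in minutes on one CPU while
preserving every structural property of the full-size model.

## Evaluation

**Factor-specific reflectance.** Keeping only one factor's latent blocks
and replacing the others by averages isolates that factor's spectral
signature: genotype-specific spectra replace each group's Ze and Zp blocks
by their within-group means (making all P reconstructions of a group
identical); environment-specific spectra replace Zg and Zp by their means
over the whole evaluation set and retain each Ze(e); micro-specific
spectra retain each Zp(p).  Averages are computed over the evaluation set
passed in, not the training set.

**KL environment separation.** At each evaluated wavelength (default:
every 50th), the reflectance distributions of the two environments are
estimated by histograms on 50 shared equal-width bins spanning the pooled
range, smoothed with 0.5 pseudo-counts per bin, and compared by
symmetrized KL, ½[KL(P‖Q) + KL(Q‖P)]; the per-wavelength values are
averaged.  The pseudo-count choice matters: with vanishing smoothing,
near-empty tail bins dominate and the estimator overshoots the Gaussian
closed form by ~75%; at 0.5 pseudo-counts it lands within ~15% for
N(0,1) vs N(1,1) at n = 2000 (the calibration check in the test suite).
Estimator settings are recorded in every report.  Computing the report on
raw spectra and on environment-specific reconstructions quantifies the
separation gained by disentanglement.

**Trait prediction.** Feature sources are the per-plant composed CAE
latent (width d — one vector per plot, which the fused group vector cannot
provide), the vanilla latent of equal width, PCA scores (component count
= d for parity; deterministic full-SVD solver with a largest-|loading|
sign convention), and raw spectra.  Scoring is R² = 1 − SS_res/SS_tot
under 5-fold cross-validation with folds grouped by genotype — replicates
of a genotype never straddle folds, so the score measures generalization
to unseen genotypes.  Regressors: ridge (penalty chosen by internal CV
over 1e-3…1e3), PLSR, random forest, and gradient boosting, all with
fixed seeds.  As an operational probe of disentanglement, a logistic
classifier predicts the environment id from single latent blocks:
environment information should be recoverable from the Ze slice and
absent from the Zg slice (on balanced panels Zg is constant within a
group whose environment labels are balanced, so any classifier on Zg is
pinned at chance).

## Synthetic panels

The generator produces the replicated-panel structure the model assumes:
spectrum(g, e, p) = logistic(baseline(λ) + genotype + macro-env +
micro-env + white noise), laid out genotype-major as G × E × N with
metadata.  Components are low-rank expansions over smooth Gaussian-bump
bases (bump width = the `smoothness` correlation length, default 25
wavelength indices), emulating the broad absorption features of leaf
reflectance.  Each component is rescaled so the realized per-wavelength
variance shares match the configured (v_g, v_e, v_p) — default
(0.4, 0.3, 0.1), remainder white sensor noise — and the total pre-squash
signal sd (default 0.22 logit units) keeps the logistic squash in its
near-linear range so the shares survive into the observed spectra.

Two identifiability choices define the default data-generating world:

- **Stratified, orthonormalized bases.** Bump centers are stratified
  across the grid and the bases are orthonormalized (QR); i.i.d. random
  centers can nearly coincide, leaving some factors spectrally invisible
  and the ground truth unrecoverable by any method.
- **Micro-environment overlaps genotype.** By default the k_p = 5 micro
  factors reuse the genotype factors' spectral directions (plot-level
  stress and genotype modulate the same absorption features), while the
  macro-environment factors are orthogonal to both.  This makes a single
  plot a *noisy* readout of its genotype — per-plot ridge prediction of a
  genotype-driven trait caps near R² ≈ 0.78 while pooling a group's four
  replicates raises the ceiling to ≈ 0.93 — which is precisely the regime
  in which replicated measurements, and a model that pools them
  structurally, pay off.  With fully orthogonal micro bases
  (`micro_shares_genotype_bases=False`) a single plot is almost
  noiseless, a per-plot encoder is already near the ceiling, and no
  pooling method can show an advantage.

Traits are linear in the genotype factors (seeded random weights unless
given), optionally plus a per-environment offset, with Gaussian noise at
a configurable fraction (default 10%) of the noiseless trait sd.

A balanced two-way ANOVA oracle (`variance_decomposition`) recovers the
realized shares from a generated panel: expected-mean-square estimates
for the genotype and environment components (shrunk by (levels−1)/levels
because the generator calibrates realized, finite-population shares), and
a lag-1 wavelength-difference estimator to split the plot-level residual
into smooth micro signal and white noise.

### What the synthetic world does and does not show

It reproduces the structure the method needs — additive G/E/plot effects
on smooth spectra, replicated panel layout, genotype-driven traits — so
tests on it validate the machinery: slot bookkeeping, loss behavior,
optimization, pooling advantage, environment separation.  It does not
emulate real leaf reflectance physics (no radiative-transfer model),
genotype-by-environment interactions (effects are additive on the logit
scale), heteroscedastic sensor noise, or traits with nonlinear genetic
architecture.  Passing tests therefore demonstrate correctness of the
implementation and the qualitative behavior of the method under its own
assumptions, not field-data performance.

## Known limitations

- Full-batch training materializes the whole panel; fine for thousands of
  plots, not for millions.
- The correlation penalty's sampling floor grows as D²/√B; for very wide
  fused latents with few groups, decorrelation pressure is mostly noise.
- The 85/15 split leaves small validation sets at desk scale, so early
  stopping is coarse.
- Normalization constants are dataset-wide (computed before the split),
  faithful to the reference procedure but technically a mild leakage
  between train and validation reconstruction losses.
- The replicate-permutation symmetry of factor-specific reconstructions
  holds only approximately for trained fusion weights; exact invariants
  are the within-group identities guaranteed by composition.
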