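# Methods

This note records the modelling choices, parameter meanings and numerical
details behind `diffdecon`, and what the synthetic studies do and do not
demonstrate.

## Model

Deconvolution is treated as conditional generation on the K-simplex. A
proportion vector `x0` is progressively noised by the forward chain
`q(x_t | x_{t-1}) = N(sqrt(1-beta_t) x_{t-1}, beta_t I)` over `T`
timesteps (1-based, `t in [1, T]`); `beta_t` is linear from `1e-4` to
`0.02` inclusive of both endpoints. The closed-form marginal
`x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps` is used for training; the
cumulative products `abar_t` are exact `cumprod` outputs and are
regression-tested against an explicit product loop.

A denoiser `eps_theta(x_t, t, c)` is trained to predict the injected
standard-normal noise by plain MSE, with timesteps drawn uniformly on
`[1, T]` per batch element (the standard DDPM recipe). Inference is
ancestral sampling:
`x_{t-1} = (x_t - beta_t/sqrt(1-abar_t) eps_theta) / sqrt(alpha_t) +
sigma_t z`, with `sigma_t^2 = beta_t` by default and `z = 0` at `t = 1`.
The posterior-variance variant
`sigma_t^2 = beta_t (1-abar_{t-1})/(1-abar_t)` is available as
`variance="posterior"`; for the near-deterministic conditionals that arise
here it reduces sampling noise only marginally (measured ~0.005 RMSE), so
the simpler default stands. The final state is mapped to the simplex by
clipping negatives and renormalizing; clipping (rather than a softmax)
preserves exact zeros for absent cell types, and an all-non-positive
vector falls back to uniform. With an exact denoiser the final update
coefficient `1 - beta_1/(1-abar_1)` vanishes, so the sampler returns the
target exactly — all residual error in practice is denoiser error.

`ddpm_sample`/`infer_proportions` accept `n_draws`; draws are averaged
before projection. The default is a single draw, matching single-pass
inference; averaging is exposed purely as variance reduction. Batched
inference derives one RNG stream per row from
`SeedSequence(seed).spawn(N)`, so a sample's estimate is independent of
which other samples share the batch.

## Denoiser architectures

**DiffFormer.** Three affine embeddings map the noisy proportions
(K -> 128), the scaled timestep (`t/T`, 1 -> 128) and the bulk profile
(G -> 128) into a common space; the raw step index destabilizes training,
hence the `t/T` scaling. The three tokens, ordered
`[proportion, time, bulk]`, receive learnable positional embeddings
(initialized N(0, 0.02^2)) and pass through a 3-layer pre-norm Transformer
encoder: 4 softmax-attention heads, feed-forward width 256 with GELU,
dropout 0.1 on attention weights and on the feed-forward hidden layer, and
a final layer normalization after the last block (standard pre-norm
practice). The first token's output is projected 128 -> K with no
activation so the full real line is available for noise prediction. The
default-architecture parameter count (K=7, G=5000) is 1,040,391 and is
regression-tested.

**DiffMLP** (ablation) keeps the identical per-modality embeddings,
concatenates them and applies GELU hidden layers of width [256, 256] with
dropout 0.1. It shares every training hyperparameter with DiffFormer.

**Bulk-token standardization.** Log-normalized expression values span an
order of magnitude across genes; feeding them raw, the denoiser largely
ignores the conditioning token at small training budgets (per-type
correlations near zero). The bulk profile is therefore standardized per
gene with training-set statistics before its embedding. The statistics are
non-trainable model buffers, computed from the training portion only and
stored in checkpoints, so inference applies the identical transform.
Input scaling of this kind is standard for expression-conditioned
networks.

**Initialization** is Xavier-uniform for weights, zero biases, all from a
seed-controlled generator; forward passes and every layer's parameter
gradients are verified against central finite differences.

## Training

AdamW with decoupled weight decay (lr 1e-4, wd 0.01, betas (0.9, 0.999),
eps 1e-8), batch 64, cosine annealing of the learning rate from `lr` to
`eta_min = 1e-6` over `t_max = 150` epochs — `t_max` is the scheduler's
clock and deliberately independent of the epoch budget, so shortened runs
anneal on the same schedule rather than crash-cooling. Early stopping
monitors a 10% held-out validation split whose noise realization (t, eps
per sample) is frozen at split time: the validation loss is then a
low-variance function of the parameters, which makes best-epoch selection
stable. The best checkpoint is the lowest validation loss, ties to the
earlier epoch. All randomness — split, init, batch order, timesteps,
noise, dropout masks — descends from the single training seed via
`SeedSequence` spawning. No gradient clipping or accumulation.

## Reference preprocessing

Cells are kept when their detected-gene count lies in
`[min_genes, max_genes]` (defaults 200/5000) and their mitochondrial count
fraction (genes with an `MT-` name prefix) is at most 20%; genes expressed
in fewer than 3 retained cells are dropped afterwards, so prevalence is
computed on retained cells. Counts are scaled to 10,000 per cell and
log1p-transformed; every cell's expm1 row sum is 10,000 to 1e-6 relative
tolerance. HVG selection delegates to scanpy's dispersion method (seurat
flavor: per-gene mean and variance/mean dispersion on the expm1 scale,
dispersions z-scored within mean bins; window `min_mean=0.0125`,
`max_mean=3`, `min_disp=0.5`, 20 bins), then orders the passing genes by
normalized dispersion with lexicographic gene-id tie-breaks, making the
selected list deterministic. If fewer genes pass the window than
requested, all passers are returned with a warning. Cell types are indexed
in lexicographic order so proportion-vector positions are reproducible.
A QC pass that removes every cell of some annotated type is an error
unless `allow_type_loss` is set.

## Pseudo-bulk simulation

Each sample: draw `p ~ Dirichlet(alpha=1)` (uniform on the simplex), draw
per-type cell counts as one multinomial over a fixed total of 2000 cells,
sample that many cells with replacement per type, and average their
log-normalized profiles. The recorded ground truth is the *realized*
fraction (multinomial counts / 2000): the bulk profile is built from the
realized cells, so the realized composition is the recoverable quantity.
The latent Dirichlet draw is available via `truth="latent"` for
sensitivity analyses. Averaging happens on the log-normalized scale
because normalization precedes simulation in the pipeline; raw-count
mixing is not the default. One seeded stream drives proportions and cell
sampling in a fixed documented order (proportion, multinomial, per-type
index draws in type order), so a seed fixes the dataset. Default dataset
sizes are 5000 training and 500 test samples.

## Synthetic reference generator

The generator emulates an annotated droplet-style counts matrix. Per-gene
baseline abundances are lognormal around `base_mean` (sigma 1.5), so a
minority of highly expressed genes absorbs most counts — the library
composition real data shows, and the reason typical informative genes land
inside the HVG mean window after CP10K. Each of K types over-expresses a
disjoint block of `n_markers_per_type` markers by `marker_fold`; markers
start from a low off-state baseline (4% of `base_mean`), as cell-type
markers are specific rather than housekeeping-level genes. Counts are
negative-binomial via gamma-Poisson mixing (`Var = mu + phi mu^2`,
`phi = 0.5`), with lognormal per-cell library-size multipliers (CV 0.2).
A `marker_overlap_frac` knob shares part of each block with the next type
to emulate overlapping signatures. Draw order (baseline abundances,
library sizes, counts) is fixed; a config plus seed is bit-reproducible.

Defaults: 5 types, 300 genes, 100 cells per type, 20 markers at fold 20.
At this scale cells detect ~110 of 300 genes, so the reduced studies use
QC thresholds `min_genes=50`/`max_genes=300`; the 200/5000 defaults are
for real-scale data.

What the generator does **not** model: ambient RNA, doublets, batch
effects, dropout beyond NB sampling zeros, and technical bulk noise
(library preparation, platform effects). Passing the synthetic studies
therefore demonstrates the pipeline's correctness and the architectures'
relative merits under a clean linear-mixture ground truth — not
performance on real tissue.

## Evaluation

- Per-sample RMSE: root mean square over the K proportion entries.
- Per-type PCC: Pearson correlation of one type's true vs predicted
  fractions across samples; a constant column (model collapse) yields an
  explicit NaN, reported in `failed_types` and excluded from averages.
- Overall PCC: Pearson correlation of the two row-major flattened N x K
  matrices.
- Paired comparison: two-tailed paired t-test on per-sample RMSE;
  Cohen's d for paired data is `mean(d)/sd(d)` with the sample (N-1)
  standard deviation; negative d means the first method has lower error.
  Differences that are constant to float precision have undefined t and
  are reported as such.
- Stability: median, quartiles and IQR of per-sample RMSE using
  linear-interpolation quantiles (numpy's default convention).
- NNLS baseline: non-negative least squares of the bulk against type
  centroids, renormalized to sum one; uniform fallback for an all-zero
  solution.

## Reduced-study sizing and observed behaviour

The in-repo end-to-end study uses 1000 training / 100 test samples, a
T=200 schedule and 50 training epochs so that the whole suite runs on one
CPU in minutes (`scripts/acceptance.py` recomputes it). Under these
conditions the measured results are: NNLS mean RMSE ~0.003 (the data are
cleanly separable), DiffFormer mean RMSE ~0.067-0.074 with per-type PCC
0.84-0.91, DiffMLP ~0.18, and the paired t-test separates the two at
p ~ 1e-26 with |d| > 1.4. The Transformer's advantage over concatenation
fusion is thus large and significant at desk scale. The absolute accuracy
of the diffusion models at this budget is optimizer-step-limited: 50
epochs x ~15 batches is ~750 AdamW steps at learning rate 1e-4, and the
validation loss is still falling when the epoch budget ends. The full
5000-sample / 150-epoch configuration is the intended operating point.

## Known limitations

- The evaluation reports "Overall RMSE" as the mean of per-sample RMSE;
  RMSE over the flattened matrix is a near-identical alternative not
  currently exposed.
- Accelerated samplers (fewer-step schedules) are out of scope; inference
  cost is T forward passes per draw.
- The trainer is CPU-oriented numpy; it is adequate for the reduced
  studies and small references, not for atlas-scale training.
- Real-data batch effects between reference and bulk are not addressed
  beyond enlarging the HVG set; the pipeline assumes a compatible
  reference.
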