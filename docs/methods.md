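# Methods

## Model

A cohort is a pair (X, y): a samples × taxa matrix of relative abundances
(each row closed to sum 1) and binary disease labels. The classifier is a
variational information bottleneck with two views per sample:

1. **Abundance view** — the relative-abundance vector itself. Counts are
   accepted and closed to proportions unconditionally; closure is
   idempotent, so relative input passes through unchanged. No further
   transform (log, CLR, …) is applied.
2. **Distance view** — the vector of Euclidean distances from the sample
   to every training sample. Distances are true Euclidean (with the square
   root); a `squared_distance` flag switches to the sum of squared
   differences for users who want that variant. The full distance vector
   is used rather than a k-nearest truncation, and the reference set is
   always the *training* samples of the current fit: a held-out sample's
   view has training-set dimension, and held-out samples never see one
   another, which keeps the encoder input dimension split-independent and
   rules out test-set leakage. During training the self-distance zero on
   the diagonal is included.

Each view has a stochastic encoder emitting a diagonal Gaussian posterior
over a shared latent code U of dimension K. The abundance encoder
zero-pads its d-vector to the smallest square s×s (s = ⌈√d⌉, row-major
reshape), applies one 2-D convolution (8 channels, 3×3 kernel, stride 1,
size-preserving zero padding), SiLU, and 2×2 max-pooling (floor
semantics), then flattens. Both encoders continue with three fully
connected SiLU layers (widths 512, 256, 256, tapering toward the 2K
output) with dropout p = 0.2 in training mode; the final layer emits 2K
numbers read as (μ, log σ²), so unconstrained outputs give valid
variances and zero weights give exactly the prior N(0, I). The distance
view skips the convolutional front end: its dimension is the training-set
size, and a distance vector has no spatial structure for a convolution to
exploit.

Per-view posteriors are fused with the standard-normal prior by a product
of experts. For diagonal Gaussians the product is Gaussian with
per-dimension precision T = 1 + Σᵢ σᵢ⁻², mean (Σᵢ μᵢσᵢ⁻²)/T and variance
1/T; an absent view simply drops out of the product, and the empty product
is the prior. A single reparameterized draw u = μ + σ ⊙ ε per sample per
step feeds a logistic decoder σ(wᵀu + b). The objective is the mean
binary cross-entropy plus β times the mean closed-form KL of the *joint*
(product-of-experts) posterior to N(0, I) — the joint, not a sum of
per-view KLs. At evaluation time ε = 0 (posterior mean) and dropout is
off, making prediction a deterministic function of the parameters.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `latent_dim` (K) | 256 | latent code dimension |
| `beta` | 1e-5 | bottleneck trade-off multiplier (≥ 0) |
| `dropout_p` | 0.2 | dropout on fully connected layers, training only |
| `conv_channels` / `conv_kernel` / `pool_size` | 8 / 3 / 2 | convolutional front end |
| `hidden_sizes` | (512, 256, 256) | the three fully connected widths |
| `learning_rate` | 1e-3 | Adam step size, full-batch |
| `max_epochs` / `patience` | 200 / 20 | epoch budget and early-stopping patience |
| `multi_view` / `use_conv` | true / true | ablation switches |
| `seed` | 42 | root seed for init, noise draws and dropout |

K, β, the dropout rate and the SiLU activation, and the layer inventory
(three fully connected layers, one 2-D convolution, one max-pooling, PoE,
decoder) follow the published setting of the method. The remaining
choices — hidden widths tapering toward 2K, 8×3×3 convolution with 2×2
pooling, Adam at 1e-3 full batch (cohorts are tiny), 200-epoch budget
with patience 20 — are this package's defaults where the original leaves
them open, and all are configurable.

## Protocol

Cohorts are split 8:2 with per-class allocation round(count × 0.2),
bounded to [1, count−1] (round half up, the ratio being the only stated
constraint). Stratified 5-fold cross-validation assigns training samples
to folds by per-class round-robin after a seeded within-class shuffle; a
single fold pointer continues across classes so overall fold sizes differ
by at most one. Every fold trains with early stopping on its validation
AUC; because folds stop at different epochs, each stopped fold's curve is
frozen at its last recorded value before averaging, and the epoch with
the best mean validation AUC (earliest on ties) sets the training length
for a fresh full-training-set refit. The held-out test AUC uses the rank
formula with midranks, i.e. the normalized Mann–Whitney statistic, so
tied scores count half. A validation fold that degenerates to one class
contributes an uninformative 0.5.

All randomness (initialization, the per-epoch ε draws, dropout masks,
splits) derives from the configuration seed through independent
`numpy` generators, so a fixed configuration reproduces results
bit-for-bit; determinism is the contract, the particular integer is not.

## Synthetic cohorts

The generator emulates the output of an amplicon pipeline: compositional,
sparse, with a controlled class signal. One base composition is drawn
from a symmetric Dirichlet(concentration); class 1's composition is the
same vector with its informative taxa multiplied by `effect_size` and
re-closed, so `effect_size = 1` makes the classes exactly exchangeable (a
null cohort). Each sample is drawn from a Dirichlet centered on its class
composition with total concentration n_taxa × concentration — chosen so
the symmetric case matches the base draw's spread — then a `sparsity`
fraction of taxa is structurally zeroed uniformly at random and the row
re-closed (resampling, bounded, in the measure-zero event of an all-zero
row). The `separable` preset (40 samples/class, 100 taxa, 10 informative,
effect 8, concentration 0.5, sparsity 0.3) carries a signal strong enough
that a nearest-centroid baseline already exceeds AUC 0.8, establishing
separability independently of the model.

What the generator does *not* emulate: phylogenetic correlation between
taxa, sequencing-depth (count) noise, batch effects, or the
heavy-tailed taxon-prevalence structure of real stool profiles. Passing
tests on these cohorts therefore demonstrate that the implementation
learns and is calibrated under controlled compositional signal — not that
the method attains any particular AUC on real cohorts.

## Numerical choices

- All arithmetic is float64. The network, reverse-mode gradients and Adam
  are implemented in numpy; a gradient check against central finite
  differences (1e-4 relative on a toy batch) guards the backward pass.
- Binary cross-entropy is computed from logits via a stable softplus,
  never by taking `log` of a saturated sigmoid.
- Max-pooling uses floor semantics (trailing rows/cols dropped) and
  routes gradients to the first maximum on exact ties.
- Sigmoids are evaluated in the numerically safe branch form; posterior
  σ = exp(logvar/2) keeps σ strictly positive.
- Row closure tolerates only strictly positive row sums; a zero-sum
  sample is an error naming the sample.

## Scope and limitations

- Abundance input is TSV (either orientation); BIOM files are not read —
  convert upstream. The packaged reference tables are the 16-sample
  metastatic/non-metastatic colorectal cohort metadata and the
  three-cohort CRC registry.
- Binary labels only; the group→label mapping must be given explicitly.
- The acceptance script runs the full protocol at the preset's scale
  (80-sample cohorts, 5 repetitions per condition), the package's chosen
  benchmark size for routine verification.
- Real-cohort AUCs depend on upstream 16S processing (denoising,
  feature-table construction) that is out of scope here; this package
  starts from the feature table.
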