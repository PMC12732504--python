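# Methods

## Model

The base model is a variational autoencoder for UMI counts.  The encoder
maps mean-scaled, log1p-transformed expression through two ReLU layers to a
diagonal Gaussian posterior q(z|x) over a d-dimensional latent; the decoder
mirrors the encoder and outputs a strictly positive per-gene mean through a
softplus link with a small floor (1e-8), multiplied by the cell's mean count
so the normalized decoder output is library-size free.  Each gene has one
negative-binomial dispersion r, optimized as log r (initialized at r = 1) so
positivity is unconstrained.  The objective is the β-VAE bound with the NB
reconstruction term

    log NB(k; m, r) = lgamma(k+r) − lgamma(k+1) − lgamma(r)
                      + k·log m + r·log r − (k+r)·log(r+m),

computed via log-gamma throughout.  β is annealed linearly from 0 to
`beta_final` (default 1e-3) over `beta_anneal_epochs` (default 10–20)
epochs; with such a small terminal β the converged model behaves almost as
an autoencoder, which is the intended regime — the latent geometry, not
sampling fidelity, is what the probe consumes.  Optimization is Adam with
early stopping on validation total loss (default patience 20, best weights
restored).  One posterior sample is drawn per cell during training;
evaluation uses the posterior mean.

Auxiliary outputs are linear read-outs of z: a binary head with
sigmoid/BCE-with-logits and a continuous head with L1 loss, each scaled by a
weight α and averaged over the cells whose labels are observed (missing
labels contribute exactly zero, and averaging over observed cells only makes
the gradient scale invariant to the labeled fraction).  Defaults are α = 10
for binary and α = 1 for continuous heads: with 10% labeling the binary
head's gradient would otherwise be an order of magnitude smaller than the
reconstruction signal.

Everything — forward passes, training, and the probe's gradients — is
implemented in numpy with analytic reverse-mode differentiation written for
this fixed architecture.  Gradients of any scalar output with respect to z
are therefore exact (they agree with central finite differences to ~1e-9
relative wherever the ReLU network is smooth across the stencil), and
training is bit-for-bit reproducible for a fixed seed.

## Preprocessing

Cells are kept with ≥ 200 non-zero genes, ≥ 500 total counts and < 5000
non-zero genes; genes expressed in < 5 cells are dropped (cells first, then
genes).  Counts are scaled by the cell's mean count across genes and
log1p-transformed; the inverse transform recovers the raw counts exactly
(integer equality), which remain the reconstruction targets.  "Mean count
per cell" is read as the cell's own mean across genes; the alternative
reading (dataset mean total) is a one-line change of the scale-factor
function.  Highly variable genes are ranked by a binned normalized
dispersion (var/mean of the de-logged values, z-scored within 20 mean bins).
This statistic is implemented in the package with explicit degenerate
handling — single-gene bins get normalized dispersion 0 and zero-variance
genes always rank last — and is cross-checked against scanpy's
seurat-flavor selection on smooth data in the test suite.  Forced genes
(e.g. a knockout target that must stay in the model) displace the
lowest-ranked selections so the output size is exact.  Cells are split
82/9/9 into train/validation/test by a seeded permutation, floor-rounding
the validation and test sizes.

## Perturbation probe

The flow map of output y_i is the exact gradient field ∇_z y_i(z) of the
normalized decoder mean (cell scale 1; library scaling is a positive
per-cell constant and cannot change gradient direction).  Trajectories use
plain forward Euler, z_{t+1} = z_t + δ·∇y_i(z_t), with defaults δ = ±0.001
and 400 steps; no adaptive stepping.  Evaluation points are subsampled from
the embedded cells (seeded, without replacement) or a regular 2-D lattice.
Low-density regions are masked by the k-NN criterion: a point survives iff
its distance to the k-th nearest training embedding is at most the
`quantile` (default 0.99) of that statistic over the training embeddings
themselves (k = 15).  PCA projection applies the fitted component map
affinely to points and linearly (uncentered) to vectors, with a
deterministic sign convention; vector fields can be interpolated onto a
lattice by barycentric interpolation, NaN outside the convex hull.  The
UMAP projection embeds data, field origins and perturbed endpoints
(z + δ_display·∇, default δ_display = δ·n_steps since per-step displacements
vanish visually) jointly; the displayed vector is the difference of embedded
endpoint and origin, and pairs with zero latent displacement display an
exactly zero vector.  Multi-gene fields are means of per-gene gradients over
a user-supplied list.

## Scoring

The perturbation axis is the exact difference of group means of the
embedded, labeled populations.  The cosine score skips zero-norm gradients
and renormalizes (warning past 50% skipped, error when all are skipped),
since treating them as cosine 0 would bias toward orthogonality.  The
magnitude-weighted variant keeps zero gradients as genuine zero
contributions.  The baseline decodes NB means at each condition's
coordinate-wise median latent; b_i is defined as 0 when both means vanish.
The default evaluation set Z is all embedded cells of both conditions —
restriction to one condition or cluster is an explicit argument, and the
tests demonstrate that restriction changes scores for genes with
location-dependent gradients.  Ranking is by |s_i| with lexicographic
gene-id tie-breaks; top-k defaults to 200.

## Enrichment and the prompt pipeline

Overrepresentation uses the one-sided hypergeometric tail P(X ≥ overlap)
with the scored genes as the default background universe, set-size filters
5–500 after universe intersection, and Benjamini–Hochberg step-up FDR.
The pathway-relevance pipeline renders a fixed relevance question per
pathway three times, then a final-verdict prompt over the three answers;
verdicts parse the leading Yes/No token case- and punctuation-insensitively
with a standalone-token fallback, else "undetermined".  The backend is any
callable prompt→text; the shipped deterministic mock makes the pipeline
fully testable offline, and failures are retried three times before a
pathway is marked undetermined.

## Synthetic data

The generator emulates overdispersed UMI counts from a known
low-dimensional latent model: a mixture of spherical Gaussian clusters
(default 3 clusters, separation 4), a random half of cells displaced by a
known condition axis (default norm 3–4), gene means m = lib·exp(Wz+b)
clipped to a finite exponent range, and NB sampling via a gamma–Poisson
mixture (default r = 2, ~2,000 counts/cell over 300 genes so defaults
survive the standard filters).  A designated block of effect genes (default
20) has loadings aligned (or anti-aligned, for the knockdown preset) with
the condition axis up to a 5% orthogonal jitter; remaining loadings are
random with |cosine| to the axis kept below 0.6, so the effect set is
exactly the set above the 0.9 cosine threshold.  The exponential mean link
deliberately differs from the model's softplus link, so recovery results do
not depend on matching the generator's functional form.  Binary condition
and continuous pseudo-time (a noisy latent projection) labels are emitted
with exactly round(fraction·n) observed (default 10%).  The generator does
not emulate batch effects, zero inflation beyond NB, doublets or gene–gene
regulatory structure, so passing tests demonstrate recovery of planted
low-rank perturbation structure under NB noise — not robustness to those
real-data artifacts.

The default study conditions used by the tests and the acceptance script
are 3,000 cells × 300 genes, latent dimension 8 for the data and the model,
encoder 128/64, 30 epochs, batch 256 — chosen so a full train/probe/score
cycle completes in well under a minute on one CPU while leaving clear
margins on the recovery properties.

## Numerical notes and limitations

- The NB log-pmf is exact for all valid (k, m, r); its distance to the
  Poisson log-pmf decays as ((k−m)² − k)/(2r), so "Poisson-likeness" at
  r = 1e6 is ~1e-3 for k up to 50 and vanishes by r = 1e8.
- Finite-difference checks of decoder gradients are valid only where the
  ReLU activation pattern is constant across the stencil; the suite detects
  and excludes stencil-straddling points (a fraction of a percent at
  h = 1e-4) rather than loosening the tolerance.
- PCA projections fix sign by making each axis's largest-magnitude loading
  positive; UMAP projections take an explicit seed.  UMAP does not preserve
  global geometry, so displayed UMAP vectors are trustworthy locally (e.g.
  endpoints landing inside another cluster), not as global directions.
- Scores compare gradient *directions* only; they are invariant to library
  scaling but, like the underlying model, sensitive to how well the latent
  space is fit.  Training is single-threaded deterministic; BLAS threading
  does not change results beyond floating-point association at this scale.
- Alternative likelihoods (ZINB, Poisson), encoder-free decoder training,
  optimal-transport comparisons and integrated-gradient scoring are out of
  scope.
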