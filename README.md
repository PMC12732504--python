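# perturbflow

Probing single-cell generative decoders for perturbation structure.

Trained generative models of single-cell RNA-seq already encode how gene
expression changes along directions in their latent space.  `perturbflow`
reads that structure out directly: it trains a negative-binomial β-VAE on UMI
counts and differentiates decoder outputs with respect to the latent
variables, turning the decoder into a simulator of infinitesimal knockdown
and overexpression — no perturbation labels or bespoke architecture needed.
It is aimed at computational biologists who want in-silico perturbation
hypotheses (which genes drive an observed healthy→disease or
control→treatment shift) from data they already have.

## Method

**Base model.** A β-VAE with a negative-binomial likelihood per gene,

&nbsp;&nbsp;NB(k; m, r) = Γ(k+r)/(k!·Γ(r)) · (m/(r+m))ᵏ · (r/(r+m))ʳ,

where the decoder outputs the mean m(z) (softplus link, scaled by the cell's
mean count) and one dispersion r per gene is a free parameter.  Training
minimizes E[−log p(x|z)] + β·KL(q(z|x)‖N(0,I)) with β annealed linearly to a
small value, so the fitted model is almost an autoencoder.  Auxiliary linear
heads (a binary condition with weighted BCE, a continuous covariate with L1)
can be trained from as little as 10% of labels.

**Perturbation flows.**  For any scalar output y_i (a gene's decoded mean or
an auxiliary head), the gradient field ∇_z y_i(z) is a perturbation flow
map.  Forward-Euler steps z_{t+1} = z_t + δ·∇y_i(z_t) simulate gradual
knockdown (δ<0) or overexpression (δ>0).  Fields are evaluated at points
subsampled from the embedded cells, masked away from low-density regions,
and projected to 2-D by PCA (vectors map linearly) or a joint UMAP of
origins and perturbed endpoints.

**Gene scoring.**  Given two labeled populations, the perturbation axis is
a = z̄₁ − z̄₀ and each gene is scored by

&nbsp;&nbsp;s_i = avg_{z∈Z} cos∠(∇y_i(z), a) ∈ [−1, 1],

optionally magnitude-weighted (s̃_i = avg ∇y_iᵀa/‖a‖) and compared against a
decoded-mean baseline b_i = (m_i(1)−m_i(0)) / ½(m_i(1)+m_i(0)) evaluated at
each condition's median latent.  The top-|s| genes feed a one-sided
hypergeometric overrepresentation analysis (BH-FDR) over GMT gene sets, and
pathway hits can be screened by a two-stage relevance-prompt pipeline with a
pluggable language-model backend (a deterministic mock ships for offline
use).

The whole stack is implemented in numpy with exact analytic reverse-mode
differentiation, so probe gradients are exact, not approximated.

## Worked example

```python
import numpy as np
import perturbflow as pf
from perturbflow import probe, scoring

cfg = pf.preset_config("knockdown", seed=1)       # 3,000 cells × 300 genes
cm, labels, truth = pf.generate(cfg)

split = pf.split_data(cm, seed=1)                 # 82% / 9% / 9%
mc = pf.ModelConfig(latent_dim=8, encoder_hidden=(128, 64),
                    max_epochs=30, batch_size=256, patience=10, seed=1)
model, history = pf.train(mc, cm, split)

emb, _ = model.encode(pf.normalize_log1p(cm).values)
axis = scoring.perturbation_axis(emb, truth.condition)
scores = scoring.score_genes(model, emb, axis, weighted=False)

from sklearn.metrics import roc_auc_score
y = np.zeros(cfg.n_genes); y[truth.effect_genes] = 1
print("effect-gene AUROC:", round(roc_auc_score(y, np.abs(scores.s)), 3))

g = int(truth.effect_genes[0])
traj = probe.integrate_flow(model, emb[truth.condition == 0][0], g,
                            delta=-0.001, n_steps=400)
c1 = emb[truth.condition == 1].mean(axis=0)
print("start→centroid:", round(float(np.linalg.norm(traj.points[0] - c1)), 2),
      " end→centroid:", round(float(np.linalg.norm(traj.points[-1] - c1)), 2))
```

prints

```
effect-gene AUROC: 0.998
start→centroid: 3.1  end→centroid: 3.03
```

i.e. alignment scores rank the planted effect genes essentially perfectly
(AUROC 0.998), and an in-silico knockdown trajectory of an effect gene moves
an unperturbed cell measurably closer to the perturbed population's
centroid.

The same pipeline is available from the shell:

```bash
perturbflow run --seed 1 --out out/demo \
    --stages simulate,preprocess,train,probe,score,enrich
```

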