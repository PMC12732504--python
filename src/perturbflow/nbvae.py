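"""Negative-binomial β-VAE with gene-wise dispersions and auxiliary heads.

The model is a standard single-cell VAE backbone: an encoder maps mean-scaled
log1p expression to a diagonal-Gaussian posterior over a low-dimensional
latent z; a mirrored decoder maps z to strictly positive per-gene negative
binomial means m(z) (softplus link), scaled by the cell's mean count; one
dispersion r per gene is learned as a free parameter shared across cells.
Training minimizes the β-VAE objective

    L_β = E_q[-log NB(x; m, r)] + β · KL(q(z|x) ‖ N(0, I)),

with β annealed linearly from 0 to a small final value, so the converged
model is almost an autoencoder.  Optional auxiliary heads (a binary
condition, a continuous covariate such as developmental time) are linear
read-outs of z trained with weighted BCE / L1 losses over the subset of
cells whose labels are observed.

Everything is implemented in numpy with exact analytic reverse-mode
gradients for this fixed architecture, which also gives the perturbation
probe exact derivatives of any model output with respect to z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np
from scipy.special import digamma, gammaln

from .data_io import (
    CountMatrix,
    LabelTable,
    SplitAssignment,
    cell_scale_factors,
    normalize_log1p,
)

_MEAN_EPS = 1e-8
CHECKPOINT_SCHEMA = 1


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Negative binomial likelihood
# ---------------------------------------------------------------------------


def nb_log_pmf(k, m, r):
    """Log pmf of NB(k; m, r) with mean m and dispersion r.

    log NB = lgamma(k+r) − lgamma(k+1) − lgamma(r)
             + k·log m + r·log r − (k+r)·log(r+m),

    computed via log-gamma for stability; finite for all k ≥ 0, m > 0, r > 0.
    """
    k = np.asarray(k, dtype=np.float64)
    m = np.asarray(m, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.any(m <= 0) or np.any(r <= 0):
        raise ModelError("nb_log_pmf requires m > 0 and r > 0")
    if np.any(k < 0) or np.any(k != np.floor(k)):
        raise ModelError("nb_log_pmf requires non-negative integer k")
    return (
        gammaln(k + r)
        - gammaln(k + 1.0)
        - gammaln(r)
        + k * np.log(m)
        + r * np.log(r)
        - (k + r) * np.log(r + m)
    )


def _nb_dlogpmf_dm(k, m, r):
    return k / m - (k + r) / (r + m)


def _nb_dlogpmf_dr(k, m, r):
    return digamma(k + r) - digamma(r) + np.log(r) + 1.0 - np.log(r + m) - (k + r) / (r + m)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class AuxHeadSpec:
    """An auxiliary model output: binary condition or continuous covariate."""

    name: str
    kind: Literal["binary", "continuous"]
    loss_weight: float = 1.0
    label_fraction: float = 1.0


@dataclass
class ModelConfig:
    latent_dim: int = 32
    encoder_hidden: tuple[int, ...] = (512, 256)
    beta_final: float = 1e-3
    beta_anneal_epochs: int = 20
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    aux_heads: list[AuxHeadSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ModelError("latent_dim must be ≥ 1")
        if any(h < 1 for h in self.encoder_hidden):
            raise ModelError("hidden sizes must be ≥ 1")
        if self.beta_final < 0:
            raise ModelError("beta_final must be ≥ 0")
        self.aux_heads = [
            h if isinstance(h, AuxHeadSpec) else AuxHeadSpec(**h) for h in self.aux_heads
        ]


# ---------------------------------------------------------------------------
# MLP with manual reverse mode
# ---------------------------------------------------------------------------


class _MLP:
    """Fully connected net, ReLU on hidden layers, linear final layer."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    def forward(self, x: np.ndarray):
        """Returns (output, cache); hidden layers ReLU, last layer linear."""
        acts = [x]
        h = x
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def backward(self, dout: np.ndarray, acts: list[np.ndarray]):
        """Backprop a cotangent through the net.

        Returns (dW list, db list, dx)."""
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        g = dout
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                g = g * (acts[i + 1] > 0)  # ReLU mask
            dW[i] = acts[i].T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return dW, db, g

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"{prefix}_W{i}"] = W
            out[f"{prefix}_b{i}"] = b
        return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class NBVAEModel:
    """Encoder + NB decoder + gene-wise dispersions + auxiliary linear heads."""

    def __init__(self, config: ModelConfig, gene_ids: Sequence[str]):
        self.config = config
        self.gene_ids = list(gene_ids)
        n_genes = len(self.gene_ids)
        d = config.latent_dim
        rng = np.random.default_rng(config.seed)
        hid = list(config.encoder_hidden)
        self.encoder = _MLP([n_genes] + hid, rng) if hid else None
        enc_out = hid[-1] if hid else n_genes
        self.W_mu = rng.normal(0, np.sqrt(1.0 / enc_out), (enc_out, d))
        self.b_mu = np.zeros(d)
        self.W_lv = rng.normal(0, np.sqrt(1.0 / enc_out), (enc_out, d))
        self.b_lv = np.zeros(d)
        self.decoder = _MLP([d] + hid[::-1] + [n_genes], rng)
        self.log_r = np.zeros(n_genes)  # init r = 1
        self.aux_W: dict[str, np.ndarray] = {}
        self.aux_b: dict[str, np.ndarray] = {}
        for head in config.aux_heads:
            self.aux_W[head.name] = rng.normal(0, np.sqrt(1.0 / d), d)
            self.aux_b[head.name] = np.zeros(1)
        self._rng = rng
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic properties ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def dispersions(self) -> np.ndarray:
        return np.exp(self.log_r)

    def gene_index(self, gene: str | int) -> int:
        if isinstance(gene, (int, np.integer)):
            if not 0 <= gene < self.n_genes:
                raise ModelError(f"gene index {gene} out of range")
            return int(gene)
        if gene not in self._gene_index:
            raise ModelError(f"unknown gene: {gene}")
        return self._gene_index[gene]

    # -- forward passes -----------------------------------------------------

    def encode(self, x_norm: np.ndarray, sample: bool = False):
        """Posterior mean (default) or a reparameterized sample.

        ``x_norm`` is mean-scaled log1p expression over the training genes.
        Returns ``(mu, logvar)`` plus the sample when requested.
        """
        x_norm = np.atleast_2d(np.asarray(x_norm, dtype=np.float64))
        if x_norm.shape[1] != self.n_genes:
            raise ModelError(
                f"input has {x_norm.shape[1]} genes, model expects {self.n_genes}"
            )
        h, _ = self.encoder.forward(x_norm)
        mu = h @ self.W_mu + self.b_mu
        logvar = h @ self.W_lv + self.b_lv
        if sample:
            eps = self._rng.standard_normal(mu.shape)
            return mu, logvar, mu + np.exp(0.5 * logvar) * eps
        return mu, logvar

    def decode_mean(self, z: np.ndarray, cell_scale=1.0) -> np.ndarray:
        """Per-gene NB means m(z) · cell_scale; strictly positive, smooth in z."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if not np.all(np.isfinite(z)):
            raise ModelError("non-finite latent input")
        cell_scale = np.asarray(cell_scale, dtype=np.float64)
        if np.any(cell_scale <= 0):
            raise ModelError("cell_scale must be positive")
        pre, _ = self.decoder.forward(z)
        mean_norm = _softplus(pre) + _MEAN_EPS
        if cell_scale.ndim == 1:
            return mean_norm * cell_scale[:, None]
        return mean_norm * cell_scale

    def aux_forward(self, z: np.ndarray, name: str) -> np.ndarray:
        """Auxiliary head output: probability for binary, raw value for continuous."""
        head = self._aux_spec(name)
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        u = z @ self.aux_W[name] + self.aux_b[name]
        return _sigmoid(u) if head.kind == "binary" else u

    def _aux_spec(self, name: str) -> AuxHeadSpec:
        for head in self.config.aux_heads:
            if head.name == name:
                return head
        raise ModelError(f"unknown auxiliary head: {name}")

    # -- exact gradients w.r.t. z (used by the probe) -----------------------

    def output_gradient(self, z: np.ndarray, output: str | int) -> np.ndarray:
        """∇_z y(z) for a scalar model output: a gene's normalized decoder
        mean, or an auxiliary head.  Exact reverse-mode; batched over rows."""
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if isinstance(output, str) and output in self.aux_W:
            head = self._aux_spec(output)
            w = self.aux_W[output]
            if head.kind == "binary":
                u = z @ w + self.aux_b[output]
                s = _sigmoid(u)
                return (s * (1.0 - s))[:, None] * w[None, :]
            return np.broadcast_to(w, z.shape).copy()
        gi = self.gene_index(output)
        pre, acts = self.decoder.forward(z)
        dout = np.zeros_like(pre)
        dout[:, gi] = _sigmoid(pre[:, gi])  # d softplus / d pre
        _, _, dz = self.decoder.backward(dout, acts)
        return dz

    # -- parameter plumbing -------------------------------------------------

    def _param_dict(self) -> dict[str, np.ndarray]:
        params = self.encoder.params("enc")
        params.update(self.decoder.params("dec"))
        params.update(W_mu=self.W_mu, b_mu=self.b_mu, W_lv=self.W_lv, b_lv=self.b_lv)
        params["log_r"] = self.log_r
        for name in self.aux_W:
            params[f"aux_{name}_W"] = self.aux_W[name]
            params[f"aux_{name}_b"] = self.aux_b[name]
        return params

    def _set_params(self, params: dict[str, np.ndarray]) -> None:
        for i in range(len(self.encoder.W)):
            self.encoder.W[i] = params[f"enc_W{i}"]
            self.encoder.b[i] = params[f"enc_b{i}"]
        for i in range(len(self.decoder.W)):
            self.decoder.W[i] = params[f"dec_W{i}"]
            self.decoder.b[i] = params[f"dec_b{i}"]
        self.W_mu, self.b_mu = params["W_mu"], params["b_mu"]
        self.W_lv, self.b_lv = params["W_lv"], params["b_lv"]
        self.log_r = params["log_r"]
        for name in self.aux_W:
            self.aux_W[name] = params[f"aux_{name}_W"]
            self.aux_b[name] = params[f"aux_{name}_b"]

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-file checkpoint: config JSON, all parameters, gene list."""
        meta = {
            "schema": CHECKPOINT_SCHEMA,
            "config": asdict(self.config),
            "gene_ids": self.gene_ids,
        }
        arrays = {k: np.asarray(v) for k, v in self._param_dict().items()}
        with open(path, "wb") as f:  # explicit handle: keep the exact filename
            np.savez(f, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "NBVAEModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(bytes(data["_meta"].tobytes()).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ModelError(f"unsupported checkpoint schema: {meta.get('schema')}")
            cfg_raw = meta["config"]
            cfg_raw["encoder_hidden"] = tuple(cfg_raw["encoder_hidden"])
            config = ModelConfig(**cfg_raw)
            model = cls(config, meta["gene_ids"])
            params = {k: data[k] for k in data.files if k != "_meta"}
        model._set_params(params)
        return model


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def elbo_loss(x_raw: np.ndarray, model: NBVAEModel, beta: float):
    """Evaluate (total, reconstruction, KL) at the posterior mean.

    Reconstruction is the mean over cells of the per-cell NB negative
    log-likelihood, with decoder means scaled by each cell's mean count.
    """
    x_raw = np.atleast_2d(np.asarray(x_raw))
    if x_raw.shape[0] == 0:
        raise ModelError("empty batch")
    scale = cell_scale_factors(x_raw)
    x_norm = np.log1p(x_raw / scale[:, None])
    mu, logvar = model.encode(x_norm)
    m = model.decode_mean(mu, cell_scale=scale)
    recon = float(-nb_log_pmf(x_raw, m, model.dispersions[None, :]).sum(axis=1).mean())
    kl = float(
        0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1).mean()
    )
    total = recon + beta * kl
    if not np.isfinite(total):
        raise ModelError("non-finite loss")
    return total, recon, kl


def aux_loss(head: AuxHeadSpec, predictions: np.ndarray, labels: LabelTable) -> float:
    """Weighted auxiliary loss over observed labels only.

    Binary heads use mean binary cross-entropy of predicted probabilities;
    continuous heads use mean absolute error.  Missing labels contribute
    exactly zero; an all-missing table yields 0.
    """
    if head.kind != labels.kind:
        raise ModelError(f"head kind {head.kind} does not match labels kind {labels.kind}")
    predictions = np.asarray(predictions, dtype=np.float64).ravel()
    mask = labels.observed_mask
    if not mask.any():
        return 0.0
    y = labels.labels[mask]
    p = predictions[mask]
    if head.kind == "binary":
        p = np.clip(p, 1e-12, 1 - 1e-12)
        loss = -(y * np.log(p) + (1 - y) * np.log(1 - p)).mean()
    else:
        loss = np.abs(p - y).mean()
    return float(head.loss_weight * loss)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainingHistory:
    train_total: list[float] = field(default_factory=list)
    train_recon: list[float] = field(default_factory=list)
    train_kl: list[float] = field(default_factory=list)
    train_aux: dict[str, list[float]] = field(default_factory=dict)
    val_total: list[float] = field(default_factory=list)
    val_recon: list[float] = field(default_factory=list)
    val_kl: list[float] = field(default_factory=list)
    val_aux: dict[str, list[float]] = field(default_factory=dict)
    betas: list[float] = field(default_factory=list)
    stopped_epoch: int = -1


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _aux_eval(model: NBVAEModel, mu: np.ndarray, labels: dict[str, LabelTable], idx):
    out = {}
    for head in model.config.aux_heads:
        lt = labels[head.name]
        sub = LabelTable(
            [lt.cell_ids[i] for i in idx], lt.labels[idx], lt.kind
        )
        preds = model.aux_forward(mu, head.name)
        out[head.name] = aux_loss(head, preds, sub)
    return out


def train(
    config: ModelConfig,
    cm: CountMatrix,
    split: SplitAssignment,
    label_tables: dict[str, LabelTable] | None = None,
    verbose: bool = False,
):
    """Train the NB β-VAE; returns (best model, history).

    β is annealed linearly from 0 to ``beta_final`` over
    ``beta_anneal_epochs`` epochs and held constant after.  Early stopping
    monitors the validation total loss with the configured patience and
    restores the best parameters.  Fully deterministic for a fixed seed.
    """
    label_tables = label_tables or {}
    for head in config.aux_heads:
        if head.name not in label_tables:
            raise ModelError(f"no label table for auxiliary head {head.name!r}")
        if label_tables[head.name].kind != head.kind:
            raise ModelError(f"label kind mismatch for head {head.name!r}")
    tr_idx = split.indices("train")
    va_idx = split.indices("val")
    if tr_idx.size == 0 or va_idx.size == 0:
        raise ModelError("train and val partitions must be non-empty")

    nm = normalize_log1p(cm)
    X_raw = cm.counts.astype(np.float64)
    X_norm = nm.values
    scales = nm.scale_factors
    labels_arr = {
        name: lt.align_to(cm.cell_ids).labels for name, lt in label_tables.items()
    }

    model = NBVAEModel(config, cm.gene_ids)
    params = model._param_dict()
    opt = _Adam(params, config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = TrainingHistory(
        train_aux={h.name: [] for h in config.aux_heads},
        val_aux={h.name: [] for h in config.aux_heads},
    )

    best_val = np.inf
    best_params = None
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        if config.beta_anneal_epochs > 0:
            beta = config.beta_final * min(1.0, epoch / config.beta_anneal_epochs)
        else:
            beta = config.beta_final
        order = rng.permutation(tr_idx)
        ep_tot = ep_rec = ep_kl = 0.0
        ep_aux = {h.name: 0.0 for h in config.aux_heads}
        n_seen = 0
        for start in range(0, order.size, config.batch_size):
            batch = order[start : start + config.batch_size]
            losses = _train_step(model, params, opt, X_raw, X_norm, scales, labels_arr, batch, beta, rng)
            B = batch.size
            ep_tot += losses["total"] * B
            ep_rec += losses["recon"] * B
            ep_kl += losses["kl"] * B
            for h in config.aux_heads:
                ep_aux[h.name] += losses[f"aux_{h.name}"] * B
            n_seen += B
        history.train_total.append(ep_tot / n_seen)
        history.train_recon.append(ep_rec / n_seen)
        history.train_kl.append(ep_kl / n_seen)
        for h in config.aux_heads:
            history.train_aux[h.name].append(ep_aux[h.name] / n_seen)
        history.betas.append(beta)

        # validation at the posterior mean
        v_tot, v_rec, v_kl = elbo_loss(X_raw[va_idx], model, beta)
        mu_va, _ = model.encode(X_norm[va_idx])
        v_aux = {}
        for h in config.aux_heads:
            preds = model.aux_forward(mu_va, h.name)
            sub = LabelTable(
                [cm.cell_ids[i] for i in va_idx], labels_arr[h.name][va_idx], h.kind
            )
            v_aux[h.name] = aux_loss(h, preds, sub)
            v_tot += v_aux[h.name]
            history.val_aux[h.name].append(v_aux[h.name])
        history.val_total.append(v_tot)
        history.val_recon.append(v_rec)
        history.val_kl.append(v_kl)
        if verbose:
            print(f"epoch {epoch}: train {history.train_total[-1]:.3f} val {v_tot:.3f}")

        if v_tot < best_val - 1e-9:
            best_val = v_tot
            best_params = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                history.stopped_epoch = epoch
                break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.val_total) - 1
    if best_params is not None:
        model._set_params(best_params)
    return model, history


def _train_step(model, params, opt, X_raw, X_norm, scales, labels_arr, batch, beta, rng):
    """One Adam step on a minibatch; exact analytic gradients."""
    cfg = model.config
    B = batch.size
    x = X_raw[batch]
    xn = X_norm[batch]
    s = scales[batch]

    # ---- forward
    h_enc, enc_acts = model.encoder.forward(xn)
    mu = h_enc @ params["W_mu"] + params["b_mu"]
    logvar = h_enc @ params["W_lv"] + params["b_lv"]
    eps = rng.standard_normal(mu.shape)
    sigma = np.exp(0.5 * logvar)
    z = mu + sigma * eps
    pre, dec_acts = model.decoder.forward(z)
    mean_norm = _softplus(pre) + _MEAN_EPS
    m = mean_norm * s[:, None]
    r = np.exp(params["log_r"])[None, :]

    logpmf = nb_log_pmf(x, m, r)
    recon = float(-logpmf.sum(axis=1).mean())
    kl = float(0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1).mean())
    total = recon + beta * kl
    if not np.isfinite(total):
        raise ModelError("non-finite training loss; aborting")

    grads = {}

    # ---- reconstruction backward
    dL_dm = -_nb_dlogpmf_dm(x, m, r) / B
    dL_dpre = dL_dm * s[:, None] * _sigmoid(pre)
    grads["log_r"] = (-_nb_dlogpmf_dr(x, m, r) / B).sum(axis=0) * r.ravel()
    dW_dec, db_dec, dz = model.decoder.backward(dL_dpre, dec_acts)
    for i in range(len(model.decoder.W)):
        grads[f"dec_W{i}"] = dW_dec[i]
        grads[f"dec_b{i}"] = db_dec[i]

    # ---- auxiliary heads (linear read-outs of z)
    aux_losses = {}
    for head in cfg.aux_heads:
        y = labels_arr[head.name][batch]
        obs = ~np.isnan(y)
        w = params[f"aux_{head.name}_W"]
        u = z @ w + model.aux_b[head.name]
        if not obs.any():
            aux_losses[head.name] = 0.0
            grads[f"aux_{head.name}_W"] = np.zeros_like(w)
            grads[f"aux_{head.name}_b"] = np.zeros(1)
            continue
        n_obs = obs.sum()
        if head.kind == "binary":
            # BCE with logits, averaged over observed labels
            lvec = _softplus(u[obs]) - y[obs] * u[obs]
            aux_l = head.loss_weight * float(lvec.mean())
            du = np.zeros_like(u)
            du[obs] = head.loss_weight * (_sigmoid(u[obs]) - y[obs]) / n_obs
        else:
            resid = u[obs] - y[obs]
            aux_l = head.loss_weight * float(np.abs(resid).mean())
            du = np.zeros_like(u)
            du[obs] = head.loss_weight * np.sign(resid) / n_obs
        aux_losses[head.name] = aux_l
        grads[f"aux_{head.name}_W"] = z.T @ du
        grads[f"aux_{head.name}_b"] = np.array([du.sum()])
        dz += du[:, None] * w[None, :]
        total += aux_l

    # ---- KL backward and reparameterization
    dmu = dz + beta * mu / B
    dlogvar = dz * (0.5 * sigma * eps) + beta * 0.5 * (np.exp(logvar) - 1.0) / B

    grads["W_mu"] = h_enc.T @ dmu
    grads["b_mu"] = dmu.sum(axis=0)
    grads["W_lv"] = h_enc.T @ dlogvar
    grads["b_lv"] = dlogvar.sum(axis=0)
    dh = dmu @ params["W_mu"].T + dlogvar @ params["W_lv"].T
    dW_enc, db_enc, _ = model.encoder.backward(dh, enc_acts)
    for i in range(len(model.encoder.W)):
        grads[f"enc_W{i}"] = dW_enc[i]
        grads[f"enc_b{i}"] = db_enc[i]

    opt.step(params, grads)
    model._set_params(params)
    out = {"total": total, "recon": recon, "kl": kl}
    for name, v in aux_losses.items():
        out[f"aux_{name}"] = v
    return out
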