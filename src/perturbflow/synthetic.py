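"""Synthetic overdispersed single-cell counts from a known latent model.

Cells live in a low-dimensional latent space as a mixture of spherical
Gaussian clusters.  A random half of cells carries a binary condition and is
displaced by a known axis ``a_true``; per-gene NB means follow an
exponential (or optionally softplus) link ``m = lib · exp(W z + b)`` with a
known loading matrix W, and counts are drawn NB(m, r).  A designated block
of "effect" genes has loadings aligned (or anti-aligned) with ``a_true``, so
the ground-truth gradient direction and the true alignment score of every
gene are available in closed form.  Binary condition labels and a continuous
pseudo-time (a noisy latent projection) are emitted with only a configured
fraction observed, emulating sparsely labeled auxiliary targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_io import CountMatrix, LabelTable


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    n_cells: int = 3000
    n_genes: int = 300
    latent_dim: int = 8
    n_clusters: int = 3
    cluster_separation: float = 4.0
    loading_scale: float = 0.35
    dispersion_r: float = 2.0
    library_size_mean: float = 2000.0
    condition_axis_norm: float = 3.0
    n_effect_genes: int = 20
    effect_sign: Literal[1, -1] = 1  # +1: effect genes up in condition 1; -1: down
    label_fraction: float = 0.10
    time_noise_sd: float = 0.25
    mean_link: Literal["exp", "softplus"] = "exp"
    effect_cos_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_effect_genes > self.n_genes:
            raise SyntheticError("n_effect_genes exceeds n_genes")
        if not (0 < self.label_fraction <= 1):
            raise SyntheticError("label_fraction must be in (0, 1]")
        if min(self.n_cells, self.n_genes, self.latent_dim, self.n_clusters) < 1:
            raise SyntheticError("counts and dimensions must be positive")
        if self.dispersion_r <= 0 or self.library_size_mean <= 0:
            raise SyntheticError("dispersion_r and library_size_mean must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for downstream tests."""

    latents: np.ndarray  # (n_cells, latent_dim)
    clusters: np.ndarray  # (n_cells,) int
    condition: np.ndarray  # (n_cells,) {0,1}
    W: np.ndarray  # (n_genes, latent_dim) loadings
    b: np.ndarray  # (n_genes,) intercepts
    a_true: np.ndarray  # (latent_dim,) condition displacement
    effect_genes: np.ndarray  # indices of effect genes
    time: np.ndarray  # (n_cells,) continuous pseudo-time
    time_axis: np.ndarray  # unit vector defining pseudo-time
    lib_scale: np.ndarray  # (n_cells,) per-cell library scaling
    config: SyntheticConfig = field(repr=False, default=None)

    def true_alignment_score(self, gene: int) -> float:
        """cos(w_g, a_true): the analytic alignment score of a gene, since
        the generative gradient direction is w_g at every z (exp link)."""
        w = self.W[gene]
        na = np.linalg.norm(self.a_true)
        nw = np.linalg.norm(w)
        if na == 0 or nw == 0:
            return 0.0
        return float(w @ self.a_true / (nw * na))


def truth_gradient(gt: GroundTruth, gene: int, z: np.ndarray) -> np.ndarray:
    """Analytic ∇_z of the generative mean exp(w_g·z + b_g) (unit library).

    Direction is w_g/‖w_g‖ at every z; magnitude scales with the mean.
    """
    if not 0 <= gene < gt.W.shape[0]:
        raise SyntheticError(f"gene index {gene} out of range")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    w = gt.W[gene]
    if gt.config is not None and gt.config.mean_link == "softplus":
        u = z @ w + gt.b[gene]
        s = 0.5 * (1.0 + np.tanh(0.5 * u))
        grad = s[:, None] * w[None, :]
    else:
        m = np.exp(np.clip(z @ w + gt.b[gene], -30.0, 30.0))
        grad = m[:, None] * w[None, :]
    return grad if grad.shape[0] > 1 else grad[0]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def generate(config: SyntheticConfig):
    """Draw a synthetic dataset.

    Returns ``(CountMatrix, labels, GroundTruth)`` where ``labels`` is a dict
    with ``"condition"`` (binary) and ``"time"`` (continuous) LabelTables,
    each observed for ``label_fraction`` of cells.  Seed-deterministic.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = cfg.latent_dim

    # latent structure: clusters, condition displacement
    centers = rng.standard_normal((cfg.n_clusters, d))
    centers = cfg.cluster_separation * centers / np.maximum(
        np.linalg.norm(centers, axis=1, keepdims=True), 1e-12
    )
    clusters = rng.integers(0, cfg.n_clusters, cfg.n_cells)
    z = centers[clusters] + rng.standard_normal((cfg.n_cells, d))
    condition = rng.integers(0, 2, cfg.n_cells).astype(float)
    a_dir = _unit(rng.standard_normal(d))
    a_true = cfg.condition_axis_norm * a_dir
    z = z + condition[:, None] * a_true[None, :]

    # loadings: effect genes aligned with ±a_true, rest nearly orthogonal
    W = rng.standard_normal((cfg.n_genes, d)) * (cfg.loading_scale / np.sqrt(d))
    effect = np.arange(cfg.n_effect_genes)
    if cfg.condition_axis_norm != 0:
        for g in effect:
            # small orthogonal jitter keeps effect loadings distinct
            perp = rng.standard_normal(d)
            perp -= (perp @ a_dir) * a_dir
            w = cfg.effect_sign * a_dir + 0.05 * _unit(perp)
            W[g] = cfg.loading_scale * _unit(w)
        # guarantee the non-effect block stays below the effect threshold
        for g in range(cfg.n_effect_genes, cfg.n_genes):
            while abs(_unit(W[g]) @ a_dir) >= 0.6:
                W[g] = rng.standard_normal(d) * (cfg.loading_scale / np.sqrt(d))

    b = rng.normal(0.0, 0.3, cfg.n_genes)

    # per-cell library scaling so expected totals sit near library_size_mean
    eta = np.clip(z @ W.T + b[None, :], -12.0, 12.0)
    if cfg.mean_link == "softplus":
        base = np.logaddexp(0.0, eta)
    else:
        base = np.exp(eta)
    lib_scale = cfg.library_size_mean / base.sum(axis=1)
    m = base * lib_scale[:, None]

    # NB sampling via gamma-Poisson mixture
    lam = rng.gamma(shape=cfg.dispersion_r, scale=m / cfg.dispersion_r)
    counts = rng.poisson(lam)

    # pseudo-time: projection of z on a fixed unit vector plus noise
    time_axis = _unit(rng.standard_normal(d))
    time = z @ time_axis + rng.normal(0.0, cfg.time_noise_sd, cfg.n_cells)

    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    gene_ids = [f"g{j:04d}" for j in range(cfg.n_genes)]
    cm = CountMatrix(counts, gene_ids, cell_ids)

    # partial observation mask: exactly round(fraction * n) observed
    n_obs = int(round(cfg.label_fraction * cfg.n_cells))
    obs_idx = rng.choice(cfg.n_cells, size=n_obs, replace=False)
    mask = np.zeros(cfg.n_cells, dtype=bool)
    mask[obs_idx] = True
    cond_labels = np.where(mask, condition, np.nan)
    time_labels = np.where(mask, time, np.nan)
    labels = {
        "condition": LabelTable(cell_ids, cond_labels, "binary"),
        "time": LabelTable(cell_ids, time_labels, "continuous"),
        "condition_full": LabelTable(cell_ids, condition, "binary"),
        "time_full": LabelTable(cell_ids, time, "continuous"),
    }

    gt = GroundTruth(
        latents=z,
        clusters=clusters,
        condition=condition,
        W=W,
        b=b,
        a_true=a_true,
        effect_genes=effect,
        time=time,
        time_axis=time_axis,
        lib_scale=lib_scale,
        config=cfg,
    )
    return cm, labels, gt


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # knockdown: effect genes high in the wild type (condition 0) and low in
    # the perturbed population, so a negative-stepsize flow on an effect gene
    # walks condition-0 cells toward the condition-1 cluster.
    "knockdown": dict(effect_sign=-1),
    # treatment: separable binary condition with sparse labels, for the
    # auxiliary-classification setting.
    "treatment": dict(effect_sign=1, condition_axis_norm=4.0),
    # time: continuous developmental-time labels dominate.
    "time": dict(effect_sign=1, condition_axis_norm=2.0, time_noise_sd=0.25),
}


def preset_config(name: str, **overrides) -> SyntheticConfig:
    if name not in PRESETS:
        raise SyntheticError(f"unknown preset: {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)
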