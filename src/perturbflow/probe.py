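"""Perturbation probing: latent gradients, flow integration, projections.

A trained decoder defines, for every scalar output y_i (a gene's normalized
NB mean or an auxiliary head), a vector field ∇_z y_i(z) over latent space —
the perturbation flow map.  Following the field with a signed stepsize δ
simulates gradual knockdown (δ < 0) or overexpression (δ > 0):

    z_{t+1} = z_t + δ · ∇y_i(z_t).

Gradients are evaluated at points subsampled from observed cell embeddings
(or a 2-D grid), masked away from low-density regions, and projected to 2-D
either linearly (PCA, which maps the gradient vectors directly) or through a
joint UMAP of origins and perturbed endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.interpolate import griddata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .nbvae import NBVAEModel


class ProbeError(ValueError):
    pass


@dataclass
class GradientField:
    """Latent points with one gradient vector per point for one output."""

    points: np.ndarray  # (n, d)
    vectors: np.ndarray  # (n, d)
    output_name: str
    mask: np.ndarray | None = None  # boolean per point

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.points.shape != self.vectors.shape:
            raise ProbeError("points and vectors must share shape")
        if not (np.all(np.isfinite(self.points)) and np.all(np.isfinite(self.vectors))):
            raise ProbeError("non-finite entries in gradient field")


@dataclass
class FlowTrajectory:
    """Forward-Euler trajectory of a perturbation flow."""

    points: np.ndarray  # (n_steps+1, d)
    stepsize: float
    output_name: str
    output_values: np.ndarray  # (n_steps+1,)
    truncated: bool = False


@dataclass
class Projection2D:
    method: Literal["pca", "umap_endpoint"]
    points: np.ndarray  # (n, 2)
    vectors: np.ndarray  # (n, 2)
    projector: object | None = None


# ---------------------------------------------------------------------------
# Gradients and flows
# ---------------------------------------------------------------------------


def output_gradient(model: NBVAEModel, z: np.ndarray, output: str | int) -> np.ndarray:
    """Exact reverse-mode gradient of the chosen scalar output at z.

    ``output`` is a gene id / index (gradient of the normalized decoder
    mean, cell_scale = 1) or an auxiliary head name.
    """
    return model.output_gradient(z, output)


def gradient_field(
    model: NBVAEModel,
    points: np.ndarray,
    output: str | int,
    mask: np.ndarray | None = None,
) -> GradientField:
    vecs = model.output_gradient(points, output)
    name = output if isinstance(output, str) else model.gene_ids[model.gene_index(output)]
    return GradientField(points, vecs, name, mask)


def mean_gradient_field(
    model: NBVAEModel, points: np.ndarray, genes: list, mask: np.ndarray | None = None
) -> GradientField:
    """Mean of per-gene gradient fields over a user-supplied gene list."""
    if not genes:
        raise ProbeError("gene list is empty")
    vecs = np.mean([model.output_gradient(points, g) for g in genes], axis=0)
    return GradientField(points, vecs, f"mean({len(genes)} genes)", mask)


def integrate_flow(
    model: NBVAEModel,
    z0: np.ndarray,
    output: str | int,
    delta: float = -0.001,
    n_steps: int = 400,
) -> FlowTrajectory:
    """Forward-Euler integration z_{t+1} = z_t + δ∇y(z_t) from one point.

    Records the output value at every step.  A non-finite state truncates
    the trajectory and sets the ``truncated`` flag.
    """
    if n_steps < 0:
        raise ProbeError("n_steps must be ≥ 0")
    z = np.asarray(z0, dtype=float).ravel()[None, :]
    name = output if isinstance(output, str) else model.gene_ids[model.gene_index(output)]
    pts = [z[0].copy()]
    vals = [_output_value(model, z, output)]
    truncated = False
    for _ in range(n_steps):
        g = model.output_gradient(z, output)
        z_next = z + delta * g
        if not np.all(np.isfinite(z_next)):
            truncated = True
            break
        z = z_next
        pts.append(z[0].copy())
        vals.append(_output_value(model, z, output))
    return FlowTrajectory(np.array(pts), delta, name, np.array(vals), truncated)


def _output_value(model: NBVAEModel, z: np.ndarray, output) -> float:
    if isinstance(output, str) and output in model.aux_W:
        return float(model.aux_forward(z, output)[0])
    gi = model.gene_index(output)
    return float(model.decode_mean(z)[0, gi])


# ---------------------------------------------------------------------------
# Evaluation points and density masking
# ---------------------------------------------------------------------------


def sample_eval_points(
    latents: np.ndarray,
    n: int,
    strategy: Literal["subsample", "grid2d"] = "subsample",
    seed: int = 0,
) -> np.ndarray:
    """Seeded subsample of observed embeddings, or a regular 2-D lattice
    over their bounding box (2-D latents only)."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    if strategy == "subsample":
        if n > latents.shape[0]:
            raise ProbeError("n exceeds the number of available points")
        rng = np.random.default_rng(seed)
        idx = rng.choice(latents.shape[0], size=n, replace=False)
        return latents[np.sort(idx)]
    if strategy == "grid2d":
        if latents.shape[1] != 2:
            raise ProbeError("grid2d requires a 2-D latent space")
        side = int(np.round(np.sqrt(n)))
        xs = np.linspace(latents[:, 0].min(), latents[:, 0].max(), side)
        ys = np.linspace(latents[:, 1].min(), latents[:, 1].max(), side)
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])
    raise ProbeError(f"unknown strategy: {strategy}")


def density_mask(
    points: np.ndarray,
    train_latents: np.ndarray,
    k: int = 15,
    quantile: float = 0.99,
) -> np.ndarray:
    """Keep points whose k-NN distance to the training embeddings does not
    exceed the ``quantile`` of the same statistic over the training set."""
    points = np.atleast_2d(points)
    train_latents = np.atleast_2d(train_latents)
    if k < 1 or k > train_latents.shape[0]:
        raise ProbeError("k must be in [1, n_train]")
    if not (0 < quantile <= 1):
        raise ProbeError("quantile must be in (0, 1]")
    nn = NearestNeighbors(n_neighbors=k).fit(train_latents)
    # reference: each training point's distance to its k-th neighbor,
    # excluding itself
    nn_self = NearestNeighbors(n_neighbors=k + 1).fit(train_latents)
    ref = nn_self.kneighbors(train_latents)[0][:, -1]
    cutoff = np.quantile(ref, quantile)
    d = nn.kneighbors(points)[0][:, -1]
    return d <= cutoff


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------


def project_gradients_pca(field: GradientField, fit_on: np.ndarray) -> Projection2D:
    """Project points affinely and vectors linearly onto the top-2 PCs.

    Sign convention: the largest-magnitude component of each axis is
    positive, so the projection is deterministic.
    """
    fit_on = np.atleast_2d(fit_on)
    if fit_on.shape[0] < 2:
        raise ProbeError("need at least 2 points to fit a PCA")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(fit_on)
    if np.linalg.matrix_rank(np.cov(fit_on.T)) < 2:
        raise ProbeError("degenerate covariance: rank < 2")
    comps = pca.components_.copy()
    for i in range(2):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    pca.components_ = comps
    pts = (field.points - pca.mean_) @ comps.T
    vecs = field.vectors @ comps.T  # linear map, no centering for vectors
    return Projection2D("pca", pts, vecs, pca)


def grid_interpolate(proj: Projection2D, resolution: int = 50):
    """Interpolate each projected vector component onto a regular lattice.

    Linear barycentric interpolation; nodes outside the convex hull are NaN.
    Returns ``(grid_x, grid_y, grid_u, grid_v)``.
    """
    pts = proj.points
    if pts.shape[0] < 3:
        raise ProbeError("need ≥ 3 points to interpolate")
    span = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(span, tol=1e-10) < 2:
        raise ProbeError("all points are collinear")
    xs = np.linspace(pts[:, 0].min(), pts[:, 0].max(), resolution)
    ys = np.linspace(pts[:, 1].min(), pts[:, 1].max(), resolution)
    gx, gy = np.meshgrid(xs, ys)
    gu = griddata(pts, proj.vectors[:, 0], (gx, gy), method="linear")
    gv = griddata(pts, proj.vectors[:, 1], (gx, gy), method="linear")
    return gx, gy, gu, gv


def project_gradients_umap(
    model: NBVAEModel,
    latents: np.ndarray,
    field: GradientField,
    delta_display: float,
    seed: int = 0,
    **umap_kwargs,
) -> Projection2D:
    """Joint UMAP of data, field origins and perturbed endpoints.

    Endpoints z + δ_display·∇ are concatenated to the embedding set before
    fitting; the displayed vector is embedded(endpoint) − embedded(origin).
    """
    import warnings

    import umap

    latents = np.atleast_2d(latents)
    origins = field.points
    endpoints = origins + delta_display * field.vectors
    if delta_display == 0:
        warnings.warn("delta_display is 0: all displayed vectors will be zero")
    stack = np.vstack([latents, origins, endpoints])
    reducer = umap.UMAP(n_components=2, random_state=seed, **umap_kwargs)
    emb = reducer.fit_transform(stack)
    n, m = latents.shape[0], origins.shape[0]
    emb_orig = emb[n : n + m]
    emb_end = emb[n + m :]
    vectors = emb_end - emb_orig
    # identical origin/endpoint pairs are the same latent point; any embedded
    # offset is optimizer jitter, so their displayed vector is exactly zero
    same = np.all(endpoints == origins, axis=1)
    vectors[same] = 0.0
    return Projection2D("umap_endpoint", emb_orig, vectors, reducer)


# ---------------------------------------------------------------------------
# Export and plotting conveniences
# ---------------------------------------------------------------------------


def export_field_tsv(field: GradientField, path: str) -> None:
    import pandas as pd

    d = field.points.shape[1]
    cols = {f"z{i}": field.points[:, i] for i in range(d)}
    cols.update({f"grad{i}": field.vectors[:, i] for i in range(d)})
    cols["mask"] = (
        field.mask.astype(int) if field.mask is not None else np.ones(len(field.points), int)
    )
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def export_trajectory_tsv(traj: FlowTrajectory, path: str) -> None:
    import pandas as pd

    d = traj.points.shape[1]
    cols = {"step": np.arange(traj.points.shape[0])}
    cols.update({f"z{i}": traj.points[:, i] for i in range(d)})
    cols["output_value"] = traj.output_values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def streamplot(proj: Projection2D, resolution: int = 40, ax=None, **kwargs):
    """Convenience streamplot of a projected field (untested cosmetic wrapper)."""
    import matplotlib.pyplot as plt

    gx, gy, gu, gv = grid_interpolate(proj, resolution)
    if ax is None:
        _, ax = plt.subplots()
    ax.streamplot(gx, gy, np.nan_to_num(gu), np.nan_to_num(gv), **kwargs)
    return ax
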