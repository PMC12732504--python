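"""Gene scoring by alignment of gradient fields with an empirical axis.

Given two labeled populations in latent space (e.g. healthy vs. disease),
the perturbation axis is the mean displacement a = z̄₁ − z̄₀.  Gene i is
scored by the average cosine similarity between its gradient field and a
over a set of evaluation points Z:

    s_i = avg_{z∈Z} cos∠(∇y_i(z), a) ∈ [−1, 1],

with a magnitude-weighted variant s̃_i = avg_z ∇y_i(z)ᵀa / ‖a‖₂ that couples
direction with local effect size.  A decoded-mean baseline scores genes by
the symmetric change b_i between the two conditions' median latents.  The
choice of Z controls locality: restricting it to one condition or cell type
yields cell-state-conditioned rankings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import LabelTable
from .nbvae import NBVAEModel


class ScoringError(ValueError):
    pass


@dataclass
class PerturbationAxis:
    a: np.ndarray
    mean_perturbed: np.ndarray
    mean_unperturbed: np.ndarray
    n_perturbed: int
    n_unperturbed: int

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.a))


@dataclass
class GeneScores:
    gene_ids: list[str]
    s: np.ndarray  # cosine alignment, in [-1, 1]
    s_weighted: np.ndarray | None = None
    baseline: np.ndarray | None = None
    n_eval_points: int = 0
    n_skipped: np.ndarray | None = None  # zero-gradient points skipped per gene
    eval_set: str = "all"

    def ranking(self, signed: bool = False) -> np.ndarray:
        """Gene indices sorted by |s| (default) or signed s, descending;
        ties broken by gene id ascending."""
        key = self.s if signed else np.abs(self.s)
        order = sorted(range(len(self.gene_ids)), key=lambda i: (-key[i], self.gene_ids[i]))
        return np.array(order)

    def to_frame(self) -> pd.DataFrame:
        rank_of = np.empty(len(self.gene_ids), dtype=int)
        rank_of[self.ranking()] = np.arange(1, len(self.gene_ids) + 1)
        df = pd.DataFrame({"gene_id": self.gene_ids, "s": self.s, "rank": rank_of})
        if self.s_weighted is not None:
            df["s_weighted"] = self.s_weighted
        if self.baseline is not None:
            df["baseline"] = self.baseline
        df["n_eval_points"] = self.n_eval_points
        if self.n_skipped is not None:
            df["n_skipped"] = self.n_skipped
        return df


# ---------------------------------------------------------------------------
# Axis
# ---------------------------------------------------------------------------


def perturbation_axis(latents: np.ndarray, labels: LabelTable | np.ndarray) -> PerturbationAxis:
    """a = z̄_perturbed − z̄_unperturbed over the observed binary labels."""
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    y = labels.labels if isinstance(labels, LabelTable) else np.asarray(labels, dtype=float)
    if len(y) != latents.shape[0]:
        raise ScoringError("labels and latents length mismatch")
    obs = ~np.isnan(y)
    g1 = latents[obs & (y == 1)]
    g0 = latents[obs & (y == 0)]
    if g1.shape[0] == 0 or g0.shape[0] == 0:
        raise ScoringError("both condition groups must be non-empty")
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    return PerturbationAxis(m1 - m0, m1, m0, g1.shape[0], g0.shape[0])


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


def _gradients(model_or_fn, Z: np.ndarray, gene) -> np.ndarray:
    if isinstance(model_or_fn, NBVAEModel):
        return model_or_fn.output_gradient(Z, gene)
    return np.atleast_2d(model_or_fn(gene, Z))


def alignment_score(model, gene, Z: np.ndarray, axis: PerturbationAxis) -> tuple[float, int]:
    """Mean cosine between gene's gradients and the axis over Z.

    Zero-norm gradients are undefined under the cosine and are skipped,
    renormalizing the average; returns ``(s_i, n_skipped)``.  All-zero
    gradients raise; skipping more than half of Z emits a warning.
    """
    Z = np.atleast_2d(Z)
    if Z.shape[0] == 0:
        raise ScoringError("empty evaluation set")
    if axis.norm == 0:
        raise ScoringError("zero-norm perturbation axis")
    G = _gradients(model, Z, gene)
    norms = np.linalg.norm(G, axis=1)
    valid = norms > 0
    n_skipped = int((~valid).sum())
    if not valid.any():
        raise ScoringError("all gradients have zero norm; score undefined")
    if n_skipped > Z.shape[0] / 2:
        warnings.warn(f"skipped {n_skipped}/{Z.shape[0]} zero-gradient points")
    cos = (G[valid] @ axis.a) / (norms[valid] * axis.norm)
    return float(cos.mean()), n_skipped


def magnitude_weighted_score(model, gene, Z: np.ndarray, axis: PerturbationAxis) -> float:
    """s̃_i = avg_z ∇y_i(z)ᵀ a / ‖a‖₂ — unbounded, couples direction and
    local effect size; zero gradients legitimately contribute 0."""
    Z = np.atleast_2d(Z)
    if Z.shape[0] == 0:
        raise ScoringError("empty evaluation set")
    if axis.norm == 0:
        raise ScoringError("zero-norm perturbation axis")
    G = _gradients(model, Z, gene)
    return float((G @ axis.a).mean() / axis.norm)


def baseline_symmetric_change(
    model: NBVAEModel, latents: np.ndarray, labels: LabelTable | np.ndarray
) -> np.ndarray:
    """Decode NB means at each condition's coordinate-wise median latent and
    score genes by the symmetric change

        b_i = (m_i(1) − m_i(0)) / (½ (m_i(1) + m_i(0))) ∈ [−2, 2];

    genes with both means zero get b_i = 0."""
    latents = np.atleast_2d(latents)
    y = labels.labels if isinstance(labels, LabelTable) else np.asarray(labels, dtype=float)
    obs = ~np.isnan(y)
    z1 = latents[obs & (y == 1)]
    z0 = latents[obs & (y == 0)]
    if z1.shape[0] == 0 or z0.shape[0] == 0:
        raise ScoringError("both condition groups must be non-empty")
    med1 = np.median(z1, axis=0)
    med0 = np.median(z0, axis=0)
    m1 = model.decode_mean(med1)[0]
    m0 = model.decode_mean(med0)[0]
    denom = 0.5 * (m1 + m0)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(denom > 0, (m1 - m0) / denom, 0.0)
    return b


def score_genes(
    model: NBVAEModel,
    Z: np.ndarray,
    axis: PerturbationAxis,
    genes: list | None = None,
    weighted: bool = True,
    baseline: np.ndarray | None = None,
    eval_set: str = "all",
) -> GeneScores:
    """Score every gene (or a subset) over the evaluation points Z."""
    genes = list(range(model.n_genes)) if genes is None else genes
    idx = [model.gene_index(g) for g in genes]
    s = np.empty(len(idx))
    sw = np.empty(len(idx)) if weighted else None
    skipped = np.zeros(len(idx), dtype=int)
    for j, gi in enumerate(idx):
        s[j], skipped[j] = alignment_score(model, gi, Z, axis)
        if weighted:
            sw[j] = magnitude_weighted_score(model, gi, Z, axis)
    return GeneScores(
        gene_ids=[model.gene_ids[i] for i in idx],
        s=s,
        s_weighted=sw,
        baseline=baseline[idx] if baseline is not None else None,
        n_eval_points=Z.shape[0],
        n_skipped=skipped,
        eval_set=eval_set,
    )


def top_k_genes(scores: GeneScores, k: int = 200, signed: bool = False) -> list[str]:
    """The k genes with largest |score| (ties: gene id ascending)."""
    if k > len(scores.gene_ids):
        raise ScoringError("k exceeds the number of scored genes")
    order = scores.ranking(signed=signed)
    return [scores.gene_ids[i] for i in order[:k]]
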