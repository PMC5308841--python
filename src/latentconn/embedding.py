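"""Visualization of the latent space: posterior-expected distances,
classical multidimensional scaling, rigid Procrustes alignment to an
anatomical reference, and cortical-vs-latent distance correlation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from . import model as _m
from .errors import ValidationError
from .inference import PosteriorSamples, standardize_positions
from .io import AnatomicalPositions


@dataclass
class EmbeddingResult:
    """Posterior-mean distance matrix, 2D display coordinates (MDS,
    optionally Procrustes-aligned), and -- when an anatomical reference
    exists -- the per-draw correlation between cortical and latent
    distances."""

    node_labels: list[str]
    mean_distances: np.ndarray
    coords: np.ndarray
    reference: AnatomicalPositions | None = None
    distance_corr_mean: float | None = None
    distance_corr_sd: float | None = None
    distance_corr_posterior_mean: float | None = None


def expected_distances(samples: PosteriorSamples) -> np.ndarray:
    """Posterior-mean latent distances l-hat (symmetric, nonnegative,
    zero diagonal).  Only metric variants qualify: the eigenmodel's
    generalized distance is not a metric and is rejected."""
    if samples.variant == "eigenmodel":
        raise ValidationError(
            "expected_distances requires a metric variant; the "
            "eigenmodel's bilinear form is not a distance"
        )
    return samples.distance_draws().mean(axis=0)


def classical_mds(distances: np.ndarray, out_dim: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared-distance matrix and takes the top
    ``out_dim`` nonnegative eigenpairs of the resulting Gram matrix.
    Axes are ordered by eigenvalue and each is oriented so its
    largest-magnitude loading is positive, making the output
    deterministic.
    """
    D = np.asarray(distances, dtype=float)
    p = D.shape[0]
    if D.shape != (p, p) or not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be square symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValidationError("distance matrix must have zero diagonal")
    if not np.any(D > 0):
        warnings.warn("all distances are zero; all points coincide",
                      stacklevel=2)
        return np.zeros((p, out_dim))
    J = np.eye(p) - np.ones((p, p)) / p
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:out_dim]
    vals_top = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals_top)
    for d in range(coords.shape[1]):  # deterministic sign convention
        k = np.argmax(np.abs(coords[:, d]))
        if coords[k, d] < 0:
            coords[:, d] = -coords[:, d]
    return coords


def procrustes_align(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigid Procrustes superposition (rotation/reflection +
    translation, NO scaling) of ``coords`` onto ``reference``: pairwise
    distances are preserved exactly while the summed squared
    point-to-reference distance is minimized among rigid transforms."""
    X = np.asarray(coords, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape:
        raise ValidationError(
            f"shape mismatch: coords {X.shape} vs reference {Y.shape}"
        )
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    R, _ = orthogonal_procrustes(X - xm, Y - ym)
    return (X - xm) @ R + ym


def distance_correlation(
    samples: PosteriorSamples, positions: AnatomicalPositions
) -> tuple[float, float]:
    """Pearson correlation between anatomical (cortical) distances and
    latent distances: computed per draw over the off-diagonal upper
    triangle, then summarized as (mean, SD) across draws."""
    pos = positions.reorder(samples.node_labels)
    ref_d = _m.latent_distance(standardize_positions(pos.coords))
    iu = np.triu_indices(samples.p, 1)
    x = ref_d[iu]
    if np.ptp(x) == 0:
        raise ValidationError(
            "anatomical distances are constant; correlation undefined"
        )
    dists = samples.distance_draws()
    rs = np.empty(samples.n_draws)
    for t in range(samples.n_draws):
        y = dists[t][iu]
        if np.ptp(y) == 0:
            raise ValidationError(
                f"latent distances constant in draw {t}; correlation "
                "undefined"
            )
        rs[t] = np.corrcoef(x, y)[0, 1]
    return float(rs.mean()), float(rs.std(ddof=1))


def embed(
    samples: PosteriorSamples,
    reference: AnatomicalPositions | None = None,
    out_dim: int = 2,
) -> EmbeddingResult:
    """Full visualization pipeline: posterior-mean distances, classical
    MDS to ``out_dim`` dimensions and -- when a reference is supplied --
    rigid alignment to the (MDS-projected, standardized) anatomical
    configuration plus the distance correlation summary."""
    L = expected_distances(samples)
    coords = classical_mds(L, out_dim=out_dim)
    result = EmbeddingResult(
        node_labels=list(samples.node_labels),
        mean_distances=L,
        coords=coords,
        reference=reference,
    )
    if reference is not None:
        pos = reference.reorder(samples.node_labels)
        ref_std = standardize_positions(pos.coords)
        ref_2d = (
            ref_std if ref_std.shape[1] == out_dim
            else classical_mds(_m.latent_distance(ref_std), out_dim=out_dim)
        )
        result.coords = procrustes_align(coords, ref_2d)
        r_mean, r_sd = distance_correlation(samples, reference)
        result.distance_corr_mean = r_mean
        result.distance_corr_sd = r_sd
        iu = np.triu_indices(samples.p, 1)
        ref_d = _m.latent_distance(ref_std)
        result.distance_corr_posterior_mean = float(
            np.corrcoef(ref_d[iu], L[iu])[0, 1]
        )
    return result


def coords_table(result: EmbeddingResult) -> pd.DataFrame:
    dims = [f"dim{d + 1}" for d in range(result.coords.shape[1])]
    return pd.DataFrame(
        {"label": result.node_labels,
         **{d: result.coords[:, k] for k, d in enumerate(dims)}}
    )


def plot_embedding(
    result: EmbeddingResult,
    expected_connectome: np.ndarray | None = None,
    edge_threshold: float = 0.5,
    ax=None,
):
    """Scatter of the 2D embedding; optional edges where the expected
    weight exceeds ``edge_threshold``."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xy = result.coords
    if expected_connectome is not None:
        p = len(result.node_labels)
        for i in range(p):
            for j in range(p):
                if i != j and expected_connectome[i, j] > edge_threshold:
                    ax.plot(xy[[i, j], 0], xy[[i, j], 1],
                            color="0.8", lw=0.5, zorder=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=25, zorder=2)
    for lab, (x, y) in zip(result.node_labels, xy[:, :2]):
        ax.annotate(str(lab), (x, y), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_aspect("equal")
    return ax
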