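"""Representational-geometry metrics.

First order: a per-object 12x12 color RSM (Pearson or Euclidean) over the
activation patterns of the 12 hues, vectorized to a length-66 "color space"
vector. Second order: Pearson correlations among color-space vectors --
between objects within a layer, within an object across layers, and between
a layer's color-space-similarity structure and its achromatic form
similarity -- plus a normalized within-object color distance and metric
MDS for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import ActivationMatrix
from .errors import DataIntegrityError, DegenerateInputError, InputDomainError

__all__ = [
    "color_rsm",
    "rsm_offdiag_vector",
    "pairwise_vector_correlation_matrix",
    "PairwiseSimilarityMatrix",
    "within_object_color_distance",
    "cross_layer_profile",
    "colorspace_similarity_vector",
    "form_similarity_vector",
    "form_vs_colorspace_correlation",
    "mds_embed",
    "object_color_space_vectors",
    "between_object_mean_correlation",
]

_VAR_GUARD = 1e-12


def _check_variance(patterns: np.ndarray, what: str = "pattern"):
    var = patterns.var(axis=1)
    bad = np.nonzero(var < _VAR_GUARD)[0]
    if bad.size:
        raise DegenerateInputError(f"zero-variance {what} at index {int(bad[0])}")


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Pearson r with a near-constant guard."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputDomainError("vectors must have equal length")
    if a.var() < _VAR_GUARD or b.var() < _VAR_GUARD:
        raise DegenerateInputError("constant vector has no defined correlation")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


def color_rsm(patterns: np.ndarray, metric: str = "pearson") -> np.ndarray:
    """Pairwise similarity matrix among color patterns.

    Parameters
    ----------
    patterns : (n_colors, n_units)
    metric : "pearson" (diagonal 1) or "euclidean" (raw distances, diagonal 0).
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise InputDomainError("patterns must be (n_colors, n_units >= 2)")
    if metric == "pearson":
        _check_variance(patterns, "color pattern")
        rsm = np.corrcoef(patterns)
        np.fill_diagonal(rsm, 1.0)
        return rsm
    if metric == "euclidean":
        diff = patterns[:, None, :] - patterns[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    raise InputDomainError(f"unknown metric {metric!r}")


def rsm_offdiag_vector(rsm: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle, row-major (each pair once);
    a 12x12 RSM yields the length-66 color-space vector."""
    rsm = np.asarray(rsm, dtype=np.float64)
    if rsm.ndim != 2 or rsm.shape[0] != rsm.shape[1]:
        raise InputDomainError("RSM must be square")
    if not np.allclose(rsm, rsm.T, atol=1e-9):
        raise DataIntegrityError("RSM is asymmetric beyond 1e-9")
    iu = np.triu_indices(rsm.shape[0], 1)
    return rsm[iu]


@dataclass
class PairwiseSimilarityMatrix:
    """Symmetric Pearson matrix over entities with its mean off-diagonal."""

    entity_ids: list
    matrix: np.ndarray

    @property
    def mean_offdiag(self) -> float:
        return float(rsm_offdiag_vector(self.matrix).mean())

    @property
    def offdiag_vector(self) -> np.ndarray:
        return rsm_offdiag_vector(self.matrix)


def pairwise_vector_correlation_matrix(
    vectors: np.ndarray, entity_ids: list | None = None
) -> PairwiseSimilarityMatrix:
    """All pairwise Pearson correlations among equal-length vectors."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise InputDomainError("need >= 2 equal-length vectors")
    _check_variance(vectors, "vector")
    mat = np.corrcoef(vectors)
    np.fill_diagonal(mat, 1.0)
    if entity_ids is None:
        entity_ids = list(range(vectors.shape[0]))
    return PairwiseSimilarityMatrix(entity_ids, mat)


def within_object_color_distance(patterns: np.ndarray) -> float:
    """Mean normalized distance among a stimulus's color patterns.

    Each pattern is z-scored across units (population variance, so
    ||z|| = sqrt(n) exactly), pairwise Euclidean distances are divided by
    2*sqrt(n_units), and the 66 pair values are averaged. Bounded in
    [0, 1]; equals 0 iff all z-scored patterns coincide.
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise InputDomainError("patterns must be (n_colors, n_units >= 2)")
    _check_variance(patterns, "color pattern")
    z = (patterns - patterns.mean(axis=1, keepdims=True)) / patterns.std(axis=1, keepdims=True)
    n = patterns.shape[1]
    iu = np.triu_indices(patterns.shape[0], 1)
    diff = z[iu[0]] - z[iu[1]]
    dists = np.linalg.norm(diff, axis=1) / (2.0 * np.sqrt(n))
    return float(dists.mean())


def cross_layer_profile(vectors_by_layer: dict, reference: str) -> dict:
    """Correlate one object's color-space vector at every layer against its
    vector at the ``reference`` layer."""
    if reference not in vectors_by_layer:
        raise InputDomainError(f"reference layer {reference!r} not present")
    ref = np.asarray(vectors_by_layer[reference], dtype=np.float64)
    return {
        label: pearson(ref, vec) for label, vec in vectors_by_layer.items()
    }


def colorspace_similarity_vector(color_space_vectors: np.ndarray) -> np.ndarray:
    """Upper triangle of the between-object color-space correlation matrix
    (length C(n_objects, 2)); order matches :func:`rsm_offdiag_vector`."""
    vectors = np.asarray(color_space_vectors, dtype=np.float64)
    if vectors.shape[0] < 3:
        raise InputDomainError("need >= 3 objects")
    return pairwise_vector_correlation_matrix(vectors).offdiag_vector


def form_similarity_vector(grayscale_rows: np.ndarray) -> np.ndarray:
    """Upper triangle of the object-by-object Pearson matrix over the layer
    outputs to the grayscale (achromatic) versions of the objects."""
    return pairwise_vector_correlation_matrix(
        np.asarray(grayscale_rows, dtype=np.float64)
    ).offdiag_vector


def form_vs_colorspace_correlation(form_vec, cs_sim_vec) -> float:
    """Single Pearson r between a layer's form-similarity and
    color-space-similarity vectors (matching pair order)."""
    return pearson(form_vec, cs_sim_vec)


def mds_embed(dissimilarities: np.ndarray, dim: int = 2, seed: int = 0):
    """Metric MDS (stress majorization) of a dissimilarity matrix.

    Returns ``(coordinates, stress)``; deterministic under a fixed seed.
    """
    d = np.asarray(dissimilarities, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise InputDomainError("dissimilarities must be square and symmetric")
    if (d < -1e-12).any():
        raise InputDomainError("dissimilarities must be non-negative")
    if np.abs(np.diag(d)).max() > 1e-9:
        raise InputDomainError("dissimilarity diagonal must be zero")
    if d.max() <= 1e-15:  # degenerate: all points coincide
        return np.zeros((d.shape[0], dim)), 0.0
    from sklearn.manifold import MDS

    model = MDS(
        n_components=dim,
        metric="precomputed",
        metric_mds=True,
        init="random",
        random_state=seed,
        n_init=8,
        max_iter=2000,
        eps=1e-14,
        normalized_stress=False,
    )
    coords = model.fit_transform(np.clip(d, 0.0, None))
    return coords, float(model.stress_)


# --------------------------------------------------------------------------
# Convenience layers over ActivationMatrix


def object_color_space_vectors(
    matrix: ActivationMatrix,
    metric: str = "pearson",
    variant: str | None = None,
) -> dict:
    """Per-object color-space vector from one layer's activations.

    Rows of each object are taken in stored order (ascending hue index per
    the manifest convention); grayscale rows (hue_index < 0) are ignored.
    """
    out = {}
    for obj in matrix.object_ids:
        idx = [
            i
            for i, (o, h, v) in enumerate(matrix.row_keys)
            if o == obj and h >= 0 and (variant is None or v == variant)
        ]
        if len(idx) < 2:
            continue
        patterns = matrix.values[idx]
        out[obj] = rsm_offdiag_vector(color_rsm(patterns, metric=metric))
    return out


def between_object_mean_correlation(
    matrix: ActivationMatrix, metric: str = "pearson", variant: str | None = None
) -> float:
    """Mean pairwise correlation among all objects' color-space vectors in
    one layer -- the between-object color-space similarity."""
    vectors = object_color_space_vectors(matrix, metric=metric, variant=variant)
    stacked = np.stack(list(vectors.values()))
    return pairwise_vector_correlation_matrix(stacked, list(vectors)).mean_offdiag
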