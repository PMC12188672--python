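"""Embedding a distance matrix into flat and constant-curvature spaces.

The latent geometry of a network is the metric space in which its nodes can
be placed so that pairwise distances reproduce a given dissimilarity
matrix.  Three candidate geometries are tried — the Euclidean plane,
the hyperbolic plane of curvature k < 0 and the sphere of curvature k > 0 —
and ranked by the embedding stress

    Stress = (1 / Xi) * sqrt( sum_{i != j} (h_ij - h*_ij)^2 )

with Xi the number of nodes and h* the realized distances.  The geometry
with the smallest stress is the latent geometry.

Curved spaces use the curvature Gram matrix C_ij = cos(sqrt(k) d_ij) for
k > 0 and cosh(sqrt(-k) d_ij) for k < 0.  The classical
Blumenthal–Schoenberg conditions decide exact embeddability from the signs
of C's eigenvalues: a hyperbolic embedding into m dimensions exists iff C
has exactly one positive eigenvalue and at most m negative ones; a
spherical embedding into the m-sphere exists iff C has no negative
eigenvalues and at most m+1 positive ones.  When the conditions fail, the
dominant eigenpairs give the least-distorted approximate embedding.

Hyperbolic coordinates are reconstructed on the hyperboloid model: the m
most negative eigenpairs give the space-like coordinates w_i, the time
coordinate is x0_i = sqrt(1 + ||w_i||^2), and realized distances follow
from the Minkowski product cosh(sqrt(-k) h*) = x0_i x0_j - <w_i, w_j>.
Because diag(C) = 1, this reconstruction is exact whenever the input is
exactly hyperbolic.  Poincaré-disk coordinates u_i = w_i / (1 + x0_i)
(always inside the unit disk) are exported for plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .cone import DistanceMatrix
from .exceptions import EmbeddingError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CurvatureGram",
    "EmbeddingResult",
    "embedding_stress",
    "cmds_embed",
    "laplacian_spectral_embed",
    "curvature_gram",
    "embeddability_check",
    "hyperbolic_embed",
    "spherical_embed",
    "select_geometry",
]

#: relative tolerance for calling an eigenvalue zero when counting signs
EIGENVALUE_ZERO_RTOL = 1e-9

#: tie-break preference when stresses are exactly equal
SPACE_PREFERENCE = {"euclidean": 0, "hyperbolic": 1, "spherical": 2}


@dataclass
class CurvatureGram:
    """Curvature Gram matrix of a distance matrix at curvature k != 0."""

    k: float
    C: np.ndarray
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns, matching eigenvalues
    n_pos: int
    n_neg: int
    n_zero: int
    within_domain: bool = True  # for k > 0: sqrt(k) * max(d) <= pi


@dataclass
class EmbeddingResult:
    """Coordinates, realized distances and stress of one embedding."""

    space: str  # euclidean | hyperbolic | spherical
    k: float
    m: int
    labels: list[str]
    coords: np.ndarray
    hstar: np.ndarray
    stress: float
    poincare: np.ndarray | None = None
    notes: dict = field(default_factory=dict)


def _check_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValidationError("distance matrix diagonal must be zero")
    return D


def _as_array(D) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Array view, labels, and the off-diagonal interacting-pair mask.

    Bare arrays treat every off-diagonal pair as interacting (a zero entry
    then means coincident nodes); a :class:`DistanceMatrix` carries its own
    no-interaction flags.
    """
    if isinstance(D, DistanceMatrix):
        mask = ~D.no_interaction.copy()
        np.fill_diagonal(mask, False)
        return _check_square(D.D), list(D.labels), mask
    D = _check_square(D)
    mask = ~np.eye(D.shape[0], dtype=bool)
    return D, [str(i) for i in range(D.shape[0])], mask


def embedding_stress(
    D: np.ndarray,
    hstar: np.ndarray,
    n_nodes: int | None = None,
    convention: str = "ordered",
) -> float:
    """Normalized root-sum-square distortion between D and realized h*.

    The default sums over all ordered pairs i != j (each unordered pair
    twice); ``convention="unordered"`` sums each pair once.  The diagonal is
    excluded and the normalizer Xi is the number of nodes.
    """
    D = np.asarray(D, dtype=float)
    hstar = np.asarray(hstar, dtype=float)
    if D.shape != hstar.shape:
        raise ValidationError("distance matrices differ in shape")
    n = n_nodes if n_nodes is not None else D.shape[0]
    sq = (D - hstar) ** 2
    if convention == "ordered":
        total = sq.sum() - np.diag(sq).sum()
    elif convention == "unordered":
        total = sq[np.triu_indices(D.shape[0], k=1)].sum()
    else:
        raise ValueError(f"unknown stress convention {convention!r}")
    return float(np.sqrt(total) / n)


def _euclidean_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    H = np.sqrt(np.maximum((diff**2).sum(-1), 0.0))
    np.fill_diagonal(H, 0.0)
    return H


def cmds_embed(
    D, m: int = 2, stress_convention: str = "ordered"
) -> EmbeddingResult:
    """Classical multidimensional scaling into m Euclidean dimensions.

    Double-centers the squared distances, keeps the top-m eigenpairs with
    negative eigenvalues truncated to zero, and scales eigenvectors by the
    square roots of the eigenvalues.
    """
    Dm, labels, _ = _as_array(D)
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dm**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:m]
    lam = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lam)
    hstar = _euclidean_distances(coords)
    stress = embedding_stress(Dm, hstar, n, convention=stress_convention)
    return EmbeddingResult(
        space="euclidean", k=0.0, m=m, labels=labels, coords=coords,
        hstar=hstar, stress=stress, notes={"method": "cmds"},
    )


def laplacian_spectral_embed(
    D,
    m: int = 2,
    sigma: float | None = None,
    stress_convention: str = "ordered",
) -> EmbeddingResult:
    """Euclidean embedding from graph-Laplacian eigenvectors.

    Interacting pairs (positive distances) are joined by Gaussian
    similarity weights w_ij = exp(-d_ij^2 / (2 sigma^2)) with sigma the
    median positive distance by default; coordinates are the eigenvectors
    of the m smallest non-trivial eigenvalues of the unnormalized
    Laplacian, arranged in ascending order of eigenvalue, scaled by the
    single least-squares factor that minimizes the stress.  A disconnected
    similarity graph is embedded per component with a warning.
    """
    Dm, labels, mask = _as_array(D)
    n = Dm.shape[0]
    if n < m + 1:
        raise ValidationError(f"need at least {m + 1} nodes for an {m}-D embedding")
    pos = Dm[mask]
    pos = pos[pos > 0]
    if sigma is None:
        sigma = float(np.median(pos)) if len(pos) else 1.0
    W = np.zeros((n, n))
    W[mask] = np.exp(-(Dm[mask] ** 2) / (2.0 * sigma**2))
    np.fill_diagonal(W, 0.0)

    n_comp, comp = connected_components(W > 0, directed=False)
    coords = np.zeros((n, m))
    if n_comp > 1:
        logger.warning(
            "similarity graph has %d components; embedding per component", n_comp
        )
    for c in range(n_comp):
        idx = np.flatnonzero(comp == c)
        if len(idx) == 1:
            continue
        Wc = W[np.ix_(idx, idx)]
        L = np.diag(Wc.sum(axis=1)) - Wc
        w, v = np.linalg.eigh(L)
        # skip the trivial constant eigenvector (eigenvalue ~0)
        take = min(m, len(idx) - 1)
        coords[idx, :take] = v[:, 1 : 1 + take]
    hstar = _euclidean_distances(coords)
    denom = (hstar**2).sum()
    scale = float((Dm * hstar).sum() / denom) if denom > 0 else 1.0
    coords = coords * scale
    hstar = hstar * scale
    stress = embedding_stress(Dm, hstar, n, convention=stress_convention)
    return EmbeddingResult(
        space="euclidean", k=0.0, m=m, labels=labels, coords=coords,
        hstar=hstar, stress=stress,
        notes={"method": "laplacian", "sigma": sigma, "scale": scale},
    )


def curvature_gram(D, k: float) -> CurvatureGram:
    """Curvature Gram matrix C and its eigenvalue sign counts.

    ``C_ij = cos(sqrt(k) d_ij)`` for spherical curvature k > 0 and
    ``cosh(sqrt(-k) d_ij)`` for hyperbolic k < 0.  For k > 0 the distances
    must satisfy sqrt(k) max(d) <= pi to lie within one hemisphere-pair;
    violations are flagged, not raised.
    """
    if k == 0:
        raise ValueError("curvature must be nonzero; use the Euclidean path")
    Dm, _, _ = _as_array(D)
    within = True
    if k > 0:
        if np.sqrt(k) * Dm.max(initial=0.0) > np.pi + 1e-12:
            within = False
        C = np.cos(np.sqrt(k) * Dm)
    else:
        C = np.cosh(np.sqrt(-k) * Dm)
    w, v = np.linalg.eigh(C)
    tol = EIGENVALUE_ZERO_RTOL * max(np.abs(w).max(), 1.0)
    n_pos = int((w > tol).sum())
    n_neg = int((w < -tol).sum())
    n_zero = len(w) - n_pos - n_neg
    return CurvatureGram(
        k=k, C=C, eigenvalues=w, eigenvectors=v,
        n_pos=n_pos, n_neg=n_neg, n_zero=n_zero, within_domain=within,
    )


def embeddability_check(gram: CurvatureGram, m: int) -> tuple[bool, int]:
    """Blumenthal–Schoenberg eigenvalue-sign verdict for isometric embedding.

    Hyperbolic (k < 0): embeddable into m dimensions iff the signs are
    (1 positive, p negative, rest zero) with p <= m.  Spherical (k > 0):
    embeddable into the m-sphere iff (p positive, 0 negative, rest zero)
    with p <= m + 1.  Returns ``(embeddable, p)``.
    """
    if gram.k < 0:
        p = gram.n_neg
        return gram.n_pos == 1 and p <= m, p
    p = gram.n_pos
    return gram.within_domain and gram.n_neg == 0 and p <= m + 1, p


def hyperbolic_embed(
    D, m: int = 2, k: float = -1.0, stress_convention: str = "ordered"
) -> EmbeddingResult:
    """Embed into the m-dimensional hyperbolic space of curvature k < 0.

    Space-like hyperboloid coordinates come from the m most negative
    eigenpairs of the curvature Gram matrix; the time coordinate is implied
    by the unit diagonal.  Distances are read off the Minkowski product and
    divided by sqrt(-k).  Fewer than m negative eigenvalues triggers a
    dimension-deficiency warning and uses the available ones.
    """
    if k >= 0:
        raise ValueError("hyperbolic embedding needs k < 0")
    Dm, labels, _ = _as_array(D)
    n = Dm.shape[0]
    gram = curvature_gram(Dm, k)
    embeddable, p = embeddability_check(gram, m)
    w, v = gram.eigenvalues, gram.eigenvectors
    neg_order = np.argsort(w)[: min(m, n)]
    neg_order = [i for i in neg_order if w[i] < 0][:m]
    if len(neg_order) < m:
        logger.warning(
            "only %d negative eigenvalues available for an %d-D hyperbolic "
            "embedding", len(neg_order), m,
        )
    if not neg_order:
        raise EmbeddingError("no negative eigenvalues: hyperbolic embedding fails")
    lam = w[neg_order]
    W = v[:, neg_order] * np.sqrt(-lam)
    x0 = np.sqrt(1.0 + (W**2).sum(axis=1))
    cosh_d = np.outer(x0, x0) - W @ W.T
    hstar = np.arccosh(np.clip(cosh_d, 1.0, None)) / np.sqrt(-k)
    np.fill_diagonal(hstar, 0.0)
    poincare = W / (1.0 + x0)[:, None]
    stress = embedding_stress(Dm, hstar, n, convention=stress_convention)
    coords = np.zeros((n, len(neg_order)))
    coords[:, : W.shape[1]] = W
    return EmbeddingResult(
        space="hyperbolic", k=k, m=m, labels=labels, coords=coords,
        hstar=hstar, stress=stress, poincare=poincare,
        notes={"embeddable": embeddable, "p": p},
    )


def spherical_embed(
    D, m: int = 2, k: float = 1.0, stress_convention: str = "ordered"
) -> EmbeddingResult:
    """Embed into the m-sphere of curvature k > 0.

    The m+1 largest positive eigenpairs of the curvature Gram matrix give
    ambient coordinates which are row-normalized onto the unit sphere;
    distances are arccos of dot products divided by sqrt(k).  Requires
    sqrt(k) max(d) <= pi.
    """
    if k <= 0:
        raise ValueError("spherical embedding needs k > 0")
    Dm, labels, _ = _as_array(D)
    n = Dm.shape[0]
    if np.sqrt(k) * Dm.max(initial=0.0) > np.pi + 1e-12:
        raise EmbeddingError(
            "distances exceed pi / sqrt(k): no spherical embedding at this k"
        )
    gram = curvature_gram(Dm, k)
    embeddable, p = embeddability_check(gram, m)
    w, v = gram.eigenvalues, gram.eigenvectors
    pos_order = np.argsort(w)[::-1][: m + 1]
    pos_order = [i for i in pos_order if w[i] > 0]
    if not pos_order:
        raise EmbeddingError("no positive eigenvalues: spherical embedding fails")
    lam = w[pos_order]
    W = v[:, pos_order] * np.sqrt(lam)
    norms = np.linalg.norm(W, axis=1)
    if np.any(norms == 0):
        raise EmbeddingError("zero-norm ambient coordinate row")
    V = W / norms[:, None]
    cos_d = np.clip(V @ V.T, -1.0, 1.0)
    hstar = np.arccos(cos_d) / np.sqrt(k)
    np.fill_diagonal(hstar, 0.0)
    stress = embedding_stress(Dm, hstar, n, convention=stress_convention)
    return EmbeddingResult(
        space="spherical", k=k, m=m, labels=labels, coords=V,
        hstar=hstar, stress=stress,
        notes={"embeddable": embeddable, "p": p},
    )


def select_geometry(results: list[EmbeddingResult]) -> EmbeddingResult:
    """The embedding with the smallest stress; exact ties prefer Euclidean,
    then hyperbolic, then spherical."""
    if not results:
        raise ValueError("no embedding results to select from")
    return min(
        results, key=lambda r: (r.stress, SPACE_PREFERENCE.get(r.space, 99))
    )
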