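"""Ordination of compositional risk profiles.

Two complementary views are provided:

* :class:`CompositionalPCA` — principal components of the ilr-transformed
  compositions, optionally with a robust (minimum covariance determinant)
  location/scatter estimate so that a handful of aberrant sites cannot
  steer the components. Loadings are back-transformed to clr space, where
  every part owns a coordinate and the biplot "rays and links" reading
  applies: the squared distance between the vertices of two rays
  approximates the variance of the log-ratio of the corresponding parts.

* :class:`AitchisonPCoA` — classical principal coordinate analysis
  (metric multidimensional scaling) of the Aitchison distance matrix,
  with eigenvectors scaled by the square roots of their eigenvalues so
  that distances among the coordinates reproduce the input distances.
  Because the Aitchison distance is Euclidean on ilr coordinates, this
  agrees with classical PCA scores up to rotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import MinCovDet

from . import coda

__all__ = [
    "CompositionalPCA",
    "AitchisonPCoA",
    "BiplotElements",
    "robust_pca_ilr",
    "biplot_elements",
    "select_representative_subcomposition",
    "pcoa_aitchison",
]


class CompositionalPCA(BaseEstimator, TransformerMixin):
    """PCA of compositions via ilr coordinates, robust by default.

    Parameters
    ----------
    n_components : int or None
        Number of components kept; ``None`` keeps all ``D - 1``.
    robust : bool
        If True, estimate location and scatter with the minimum covariance
        determinant (support fraction 0.75); otherwise use the sample mean
        and covariance.
    random_state : int
        Seed for the (deterministic) MCD subset search.

    Attributes
    ----------
    loadings_clr_ : ndarray of shape (D, k)
        Principal axes expressed in clr space (columns sum to zero).
    components_ilr_ : ndarray of shape (k, D - 1)
        The same axes in ilr coordinates (rows, sklearn convention).
    scores_ : ndarray of shape (n, k)
        Projections of the centred training data.
    explained_variance_ : ndarray
    explained_variance_ratio_ : ndarray
    center_ilr_ : ndarray of shape (D - 1,)
    """

    def __init__(self, n_components=None, robust=True, support_fraction=0.75,
                 random_state=0):
        self.n_components = n_components
        self.robust = robust
        self.support_fraction = support_fraction
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, D = X.shape
        if n <= D:
            raise ValueError(
                f"need more compositions ({n}) than parts ({D}) for a "
                "full-rank scatter estimate"
            )
        self.psi_ = coda.ilr_basis(D)
        Z = coda.ilr(X, self.psi_)
        if self.robust:
            mcd = MinCovDet(
                support_fraction=self.support_fraction,
                random_state=self.random_state,
            ).fit(Z)
            location, scatter = mcd.location_, mcd.covariance_
        else:
            location = Z.mean(axis=0)
            scatter = np.cov(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(scatter)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        if eigval[0] <= 0 or not np.all(np.isfinite(eigval)):
            raise ValueError("degenerate scatter matrix")
        eigval = np.maximum(eigval, 0.0)

        k = (D - 1) if self.n_components is None else int(self.n_components)
        if not 1 <= k <= D - 1:
            raise ValueError("n_components out of range")
        V = eigvec[:, :k]
        # sign convention: largest-magnitude clr loading entry positive
        L = self.psi_.T @ V
        signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        V, L = V * signs, L * signs

        self.n_features_in_ = D
        self.center_ilr_ = location
        self.components_ilr_ = V.T
        self.loadings_clr_ = L
        self.eigenvalues_ = eigval[:k]
        self.explained_variance_ = eigval[:k]
        self.explained_variance_ratio_ = eigval[:k] / eigval.sum()
        self.scores_ = (Z - location) @ V
        return self

    def transform(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = coda.ilr(X, self.psi_)
        return (Z - self.center_ilr_) @ self.components_ilr_.T

    @property
    def robust_flag(self) -> bool:
        return bool(self.robust)


@dataclass(frozen=True)
class BiplotElements:
    """Covariance-biplot geometry: per-part rays and implied link variances."""

    rays: np.ndarray  # (D, 2) clr rays scaled by sqrt(eigenvalue)
    scores: np.ndarray  # (n, 2) standardized scores
    link_variances: np.ndarray  # (D, D) squared link lengths

    def link_variance(self, i: int, j: int) -> float:
        return float(self.link_variances[i, j])


def biplot_elements(pca: CompositionalPCA, kind: str = "covariance") -> BiplotElements:
    """First-two-component biplot geometry from a fitted PCA.

    ``covariance``: rays carry the variance structure (loading ×
    sqrt(eigenvalue)) and scores are standardized; the squared link length
    ``|ray_i - ray_j|²`` approximates ``var(ln(x_i/x_j))``. ``form``: the
    dual scaling — scores carry the variance, rays are bare loadings.
    """
    if kind not in ("covariance", "form"):
        raise ValueError("kind must be 'covariance' or 'form'")
    if pca.loadings_clr_.shape[1] < 2:
        raise ValueError("biplot needs at least two fitted components")
    L = pca.loadings_clr_[:, :2]
    lam = pca.eigenvalues_[:2]
    if kind == "covariance":
        rays = L * np.sqrt(lam)[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = pca.scores_[:, :2] / np.sqrt(lam)[None, :]
    else:
        rays = L
        scores = pca.scores_[:, :2]
    diff0 = rays[:, None, 0] - rays[None, :, 0]
    diff1 = rays[:, None, 1] - rays[None, :, 1]
    link = diff0**2 + diff1**2
    return BiplotElements(rays=rays, scores=scores, link_variances=link)


def select_representative_subcomposition(
    pca: CompositionalPCA, labels, part_groups: dict[str, str]
) -> list[str]:
    """One representative part per group: the longest 2-D clr ray.

    ``part_groups`` maps each part label to its group name; the part whose
    covariance-biplot ray is longest within each group is returned, in
    first-appearance group order. This formalizes picking the "most
    distinctive ray" of each biplot variable cluster for a ternary view.
    """
    labels = list(labels)
    if set(part_groups) != set(labels):
        raise ValueError("part_groups must cover exactly the part labels")
    rays = biplot_elements(pca).rays
    norms = np.linalg.norm(rays, axis=1)
    order: list[str] = []
    for lab in labels:
        g = part_groups[lab]
        if g not in order:
            order.append(g)
    chosen = []
    for g in order:
        members = [i for i, lab in enumerate(labels) if part_groups[lab] == g]
        if not members:
            raise ValueError(f"empty group {g!r}")
        chosen.append(labels[members[int(np.argmax(norms[members]))]])
    return chosen


class AitchisonPCoA(BaseEstimator):
    """Principal coordinate analysis of a distance matrix, Gower-scaled.

    ``fit`` double-centres ``-D²/2``, eigendecomposes, drops negative
    eigenvalues (warning) and scales eigenvectors by sqrt(eigenvalue), so
    Euclidean distances among ``coordinates_`` reproduce the input
    distances exactly when the input metric is Euclidean-embeddable —
    which the Aitchison distance always is.
    """

    def __init__(self, n_components=None, atol=1e-9):
        self.n_components = n_components
        self.atol = atol

    def fit(self, D, y=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        n = D.shape[0]
        B = -0.5 * D**2
        B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        scale = max(1.0, float(np.abs(eigval).max()))
        neg = eigval < -self.atol * scale
        if neg.any():
            warnings.warn(
                f"dropping {int(neg.sum())} negative eigenvalue(s); input "
                "distances are not exactly Euclidean-embeddable",
                RuntimeWarning,
                stacklevel=2,
            )
        keep = eigval > self.atol * scale
        eigval, eigvec = eigval[keep], eigvec[:, keep]
        if self.n_components is not None:
            k = int(self.n_components)
            eigval, eigvec = eigval[:k], eigvec[:, :k]
        self.eigenvalues_ = eigval
        self.coordinates_ = eigvec * np.sqrt(eigval)[None, :]
        self.proportion_explained_ = eigval / eigval.sum()
        self.n_samples_ = n
        return self

    def fit_transform(self, D, y=None):
        return self.fit(D).coordinates_


# ---------------------------------------------------------------------------
# thin functional wrappers

def robust_pca_ilr(X, robust: bool = True, n_components=None,
                   random_state: int = 0) -> CompositionalPCA:
    """Fit a :class:`CompositionalPCA` on rows of compositions."""
    return CompositionalPCA(
        n_components=n_components, robust=robust, random_state=random_state
    ).fit(X)


def pcoa_aitchison(D, n_components=None) -> AitchisonPCoA:
    """Fit an :class:`AitchisonPCoA` on a precomputed distance matrix."""
    return AitchisonPCoA(n_components=n_components).fit(D)
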