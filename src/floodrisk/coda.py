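"""Aitchison-geometry primitives for compositional data.

A composition is a vector of strictly positive parts carrying only relative
information: rescaling it changes nothing. The natural sample space is the
simplex, with perturbation (closed elementwise product) as the group
operation and powering as scalar multiplication. The log-ratio transforms
map the simplex isometrically onto real space so that ordinary multivariate
statistics apply:

* clr — centred log-ratio, ``ln(x_i / g(x))`` with ``g`` the geometric mean;
  coordinates sum to zero (the image is a hyperplane).
* ilr — isometric log-ratio, an orthonormal-basis representation in
  ``D - 1`` unconstrained coordinates; Euclidean distance in ilr
  coordinates equals the Aitchison distance on the simplex.

All functions accept a single composition (1-D array) or rows of
compositions (2-D array).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Composition",
    "IlrBasis",
    "closure",
    "perturb",
    "power",
    "clr",
    "clr_inv",
    "ilr_basis",
    "ilr",
    "ilr_inv",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "variation_matrix",
    "total_variance",
    "center_data",
    "subcomposition",
    "ternary_coords",
]

_CLOSURE_TOL = 1e-10


def _as_positive(x, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr <= 0):
        raise ValueError(
            f"{name} must be strictly positive; zeros must be handled "
            "upstream (e.g. half-detection-limit substitution)"
        )
    return arr


def closure(x, kappa: float = 1.0) -> np.ndarray:
    """Rescale positive parts to sum to ``kappa`` (row-wise for matrices)."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    arr = _as_positive(x)
    total = arr.sum(axis=-1, keepdims=True)
    return kappa * arr / total


def perturb(x, y) -> np.ndarray:
    """Simplex group operation: closure of the elementwise product."""
    a, b = _as_positive(x), _as_positive(y, "y")
    if a.shape[-1] != b.shape[-1]:
        raise ValueError("compositions must have the same number of parts")
    return closure(a * b)


def power(x, a: float) -> np.ndarray:
    """Scalar powering on the simplex: closure of elementwise ``x**a``."""
    return closure(_as_positive(x) ** float(a))


def clr(x) -> np.ndarray:
    """Centred log-ratio transform; output rows sum to zero."""
    arr = _as_positive(x)
    logx = np.log(arr)
    return logx - logx.mean(axis=-1, keepdims=True)


def clr_inv(z, kappa: float = 1.0) -> np.ndarray:
    """Map clr coordinates back to closed compositions."""
    return closure(np.exp(np.asarray(z, dtype=float)), kappa)


def ilr_basis(n_parts: int) -> np.ndarray:
    """Orthonormal (D-1) x D contrast (Helmert-type balance) matrix.

    Row j encodes the balance between the first j parts and part j+1:
    ``z_j = sqrt(j/(j+1)) * ln(g(x_1..x_j) / x_{j+1})``.  Rows sum to zero
    and ``psi @ psi.T = I``.
    """
    D = int(n_parts)
    if D < 2:
        raise ValueError("need at least two parts for an ilr basis")
    psi = np.zeros((D - 1, D))
    for j in range(1, D):
        psi[j - 1, :j] = 1.0 / np.sqrt(j * (j + 1))
        psi[j - 1, j] = -np.sqrt(j / (j + 1))
    return psi


def ilr(x, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates, ``psi @ clr(x)`` row-wise."""
    arr = _as_positive(x)
    psi = ilr_basis(arr.shape[-1]) if basis is None else np.asarray(basis)
    return clr(arr) @ psi.T


def ilr_inv(z, basis: np.ndarray | None = None, kappa: float = 1.0) -> np.ndarray:
    """Compositions from ilr coordinates (``clr = psi.T @ z``)."""
    zarr = np.asarray(z, dtype=float)
    psi = ilr_basis(zarr.shape[-1] + 1) if basis is None else np.asarray(basis)
    return clr_inv(zarr @ psi, kappa)


def aitchison_distance(x, y) -> float:
    """Euclidean distance between clr images; the simplex metric."""
    return float(np.linalg.norm(clr(x) - clr(y)))


def aitchison_distance_matrix(X) -> np.ndarray:
    """Pairwise Aitchison distances between rows of a composition matrix."""
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(clr(np.atleast_2d(X))))


def variation_matrix(X, ddof: int = 1) -> np.ndarray:
    """Pairwise log-ratio variances ``T_ij = var(ln(x_i/x_j))``.

    Symmetric with zero diagonal; small entries mark nearly proportional
    parts (the "short links" of a compositional biplot).
    """
    arr = np.atleast_2d(_as_positive(X))
    if arr.shape[0] < 2:
        raise ValueError("variation matrix needs at least two compositions")
    logx = np.log(arr)
    D = arr.shape[1]
    T = np.empty((D, D))
    for i in range(D):
        T[i] = np.var(logx[:, [i]] - logx, axis=0, ddof=ddof)
    T = 0.5 * (T + T.T)
    np.fill_diagonal(T, 0.0)
    return T


def total_variance(X, ddof: int = 1) -> float:
    """Total (metric) variance: ``sum_ij T_ij / (2 D)``."""
    T = variation_matrix(X, ddof=ddof)
    return float(T.sum() / (2.0 * T.shape[0]))


def center_data(X) -> tuple[np.ndarray, np.ndarray]:
    """Perturb every row by the inverse closed geometric mean.

    Returns the centred rows and the centre itself. The geometric centre of
    the output is the barycentre of the simplex.
    """
    arr = np.atleast_2d(_as_positive(X))
    center = closure(np.exp(np.log(arr).mean(axis=0)))
    centered = closure(arr / center)
    return (centered if np.asarray(X).ndim == 2 else centered[0]), center


def subcomposition(x, labels: list[str], subset: list[str]) -> np.ndarray:
    """Re-closed selection of parts named in ``subset``."""
    if len(subset) < 2:
        raise ValueError("a subcomposition needs at least two parts")
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [s for s in subset if s not in index]
    if missing:
        raise KeyError(f"unknown parts: {missing}")
    cols = [index[s] for s in subset]
    return closure(np.asarray(x, dtype=float)[..., cols])


def ternary_coords(x) -> np.ndarray:
    """Planar coordinates of 3-part compositions.

    Vertex convention (counter-clockwise): part 1 at (0, 0), part 2 at
    (1, 0), part 3 at (1/2, sqrt(3)/2); the barycentre maps to
    (1/2, sqrt(3)/6).
    """
    arr = closure(x)
    if arr.shape[-1] != 3:
        raise ValueError("ternary coordinates require exactly three parts")
    u = arr[..., 1] + 0.5 * arr[..., 2]
    v = (np.sqrt(3.0) / 2.0) * arr[..., 2]
    return np.stack([u, v], axis=-1)


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal contrast matrix together with its part ordering."""

    psi: np.ndarray
    part_order: tuple[str, ...]

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        D = len(self.part_order)
        if psi.shape != (D - 1, D):
            raise ValueError("psi must be (D-1) x D for D parts")
        if not np.allclose(psi @ psi.T, np.eye(D - 1), atol=1e-10):
            raise ValueError("psi rows must be orthonormal")
        if not np.allclose(psi.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("psi rows must sum to zero")
        object.__setattr__(self, "psi", psi)

    @classmethod
    def default(cls, part_order) -> "IlrBasis":
        order = tuple(part_order)
        return cls(ilr_basis(len(order)), order)


@dataclass(frozen=True)
class Composition:
    """Strictly positive parts closed to ``kappa``, with part labels."""

    parts: np.ndarray
    labels: tuple[str, ...] = ()
    kappa: float = 1.0

    def __post_init__(self):
        arr = closure(self.parts, self.kappa)
        labels = tuple(self.labels) if self.labels else tuple(
            f"part_{i}" for i in range(arr.shape[-1])
        )
        if arr.ndim != 1:
            raise ValueError("Composition holds a single vector; use arrays for matrices")
        if len(labels) != arr.shape[0]:
            raise ValueError("label count must match part count")
        if abs(arr.sum() - self.kappa) > _CLOSURE_TOL * max(1.0, self.kappa):
            raise ValueError("closure failed")  # pragma: no cover - closure guarantees
        object.__setattr__(self, "parts", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def n_parts(self) -> int:
        return self.parts.shape[0]

    def _check_match(self, other: "Composition"):
        if self.labels != other.labels:
            raise ValueError("part labels do not match")

    def perturb(self, other: "Composition") -> "Composition":
        self._check_match(other)
        return Composition(perturb(self.parts, other.parts), self.labels, self.kappa)

    def power(self, a: float) -> "Composition":
        return Composition(power(self.parts, a), self.labels, self.kappa)

    def inverse(self) -> "Composition":
        return self.power(-1.0)

    def clr(self) -> np.ndarray:
        return clr(self.parts)

    def ilr(self, basis: IlrBasis | None = None) -> np.ndarray:
        psi = basis.psi if basis is not None else None
        return ilr(self.parts, psi)

    def distance(self, other: "Composition") -> float:
        self._check_match(other)
        return aitchison_distance(self.parts, other.parts)

    def subcomposition(self, subset) -> "Composition":
        sub = list(subset)
        return Composition(
            subcomposition(self.parts, list(self.labels), sub), tuple(sub), self.kappa
        )

    @classmethod
    def neutral(cls, labels) -> "Composition":
        order = tuple(labels)
        return cls(np.full(len(order), 1.0 / len(order)), order)
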