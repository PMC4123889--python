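"""Moran eigenvectors and stepwise residual-autocorrelation filtering.

Eigenvector spatial filtering represents latent spatial structure with the
eigenvectors of the doubly-projected, symmetrized weight matrix

    M ((V + V^T)/2) M,      M = I - X (X^T X)^{-1} X^T,

for the simultaneous-autoregressive (SAR) family.  Each eigenvector is a map
pattern over the areas with a characteristic Moran's I; with an intercept-only
projector the Moran's I of eigenvector *i* equals (J/S0)·λ_i.  A subset is
selected greedily to minimize the |z(Moran's I)| of a model's area-level
residuals, and enters the regression as synthetic covariates that "filter out"
the residual spatial dependency.

Extraction is done on an orthonormal basis of the orthocomplement of the
projector's column space, so every returned eigenvector is exactly orthogonal
to the projected-out design and the spectrum is free of the k trivial zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .moran import DegenerateInputError, MoranResult, moran_i
from .weights import SpatialWeights, islands

__all__ = [
    "Projector",
    "EigenvectorSet",
    "FilterResult",
    "make_projector",
    "extract_eigenvectors",
    "candidate_pool",
    "select_stepwise",
    "expand_to_individuals",
]

logger = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class Projector:
    """The annihilator M = I - X(X^TX)^{-1}X^T of a full-rank design X.

    ``complement`` is an orthonormal J×(J-k) basis of the orthocomplement of
    col(X); applying M is equivalent to projecting onto that basis.
    """

    basis: np.ndarray = field(repr=False)
    complement: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return self.basis.shape[0]

    @property
    def rank(self) -> int:
        return self.basis.shape[1]

    def apply(self, v: np.ndarray) -> np.ndarray:
        """Matrix-free application of M to a vector or column stack."""
        v = np.asarray(v, dtype=float)
        return self.complement @ (self.complement.T @ v)

    def matrix(self) -> np.ndarray:
        return self.complement @ self.complement.T


def make_projector(area_design, n_areas: int | None = None) -> Projector:
    """Build the projector for ``area_design`` (J×k array or "intercept-only").

    Raises :class:`CollinearityError` when the design is rank deficient, and
    rejects designs that span all of R^J (M would be identically zero).
    """
    if isinstance(area_design, str):
        if area_design != "intercept-only":
            raise ValueError(f"unknown design spec {area_design!r}")
        if n_areas is None:
            raise ValueError("intercept-only projector needs n_areas")
        x = np.ones((n_areas, 1))
    else:
        x = np.atleast_2d(np.asarray(area_design, dtype=float))
        if x.shape[0] < x.shape[1]:
            raise CollinearityError("more columns than areas")
    j, k = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        # name the dependent columns by greedy QR pivoting
        _, r, piv = _qr_pivot(x)
        dep = sorted(int(c) for c in piv[rank:])
        raise CollinearityError(f"rank-deficient design: dependent columns {dep}")
    if rank >= j:
        raise CollinearityError("design spans all of R^J; projector is zero")
    # orthonormal basis of the orthocomplement via full SVD
    u, s, _ = np.linalg.svd(x, full_matrices=True)
    comp = u[:, k:]
    return Projector(basis=x, complement=comp)


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    return qr(x, pivoting=True)


@dataclass(frozen=True)
class EigenvectorSet:
    """Moran eigenvectors over the areas of one weight matrix.

    Columns of ``vectors`` are unit norm, mutually orthogonal, orthogonal to
    the projector basis, and stored in descending order of their Moran's I
    (so index 0 is the most positively autocorrelated pattern; reports label
    it e_1).
    """

    area_ids: tuple[str, ...]
    vectors: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray = field(repr=False)
    moran_of_vector: np.ndarray = field(repr=False)

    @property
    def n_areas(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]

    @property
    def ordering(self) -> np.ndarray:
        """Indices sorted by descending Moran's I (identity for this storage)."""
        return np.argsort(-self.moran_of_vector, kind="stable")

    def label(self, index: int) -> str:
        """Report label in descending-Moran numbering (index 0 → ``e_1``)."""
        return f"e_{index + 1}"

    def to_frame(self, selected: Sequence[int] | None = None):
        import pandas as pd

        idx = list(selected) if selected is not None else list(range(self.n_vectors))
        data = {"area_id": list(self.area_ids)}
        for k in idx:
            data[self.label(k)] = self.vectors[:, k]
        return pd.DataFrame(data)


def extract_eigenvectors(weights: SpatialWeights, projector: Projector) -> EigenvectorSet:
    """Eigen-decompose M·((V+Vᵀ)/2)·M and return all J−k nontrivial vectors.

    The sign of each eigenvector is fixed so that its first coordinate with
    magnitude above 1e-12 is positive (eigenvectors are sign-indeterminate).
    """
    isl = islands(weights)
    if isl:
        raise ValueError(f"islands present: {isl}; drop them before extraction")
    j = weights.n_areas
    if j < 2:
        raise ValueError("eigenvector extraction needs at least 2 areas")
    if projector.n != j:
        raise ValueError("projector size does not match weights")
    w_sym = 0.5 * (weights.matrix + weights.matrix.T)
    q = projector.complement  # J×(J-k), orthonormal
    b = q.T @ w_sym @ q
    lam, u = np.linalg.eigh(0.5 * (b + b.T))
    order = np.argsort(-lam, kind="stable")
    lam = lam[order]
    vecs = q @ u[:, order]
    # deterministic sign convention
    for c in range(vecs.shape[1]):
        col = vecs[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, c] = -col
    morans = np.array([moran_i(vecs[:, c], weights).i_value for c in range(vecs.shape[1])])
    # descending eigenvalue order is descending Moran order for the
    # intercept-only projector; enforce Moran ordering in general
    m_order = np.argsort(-morans, kind="stable")
    return EigenvectorSet(
        area_ids=weights.area_ids,
        vectors=vecs[:, m_order],
        eigenvalues=lam[m_order],
        moran_of_vector=morans[m_order],
    )


def candidate_pool(
    eigenset: EigenvectorSet, rule: str = "positive-moran", c: float = 0.25
) -> list[int]:
    """Indices eligible for selection.

    "positive-moran" keeps vectors with Moran's I > 0 (positive spatial
    dependency patterns); "eigenvalue-ratio" keeps eigenvalue/max ≥ ``c``.
    """
    if eigenset.n_vectors == 0:
        raise ValueError("empty eigenvector set")
    if rule == "positive-moran":
        pool = [int(i) for i in np.flatnonzero(eigenset.moran_of_vector > 0)]
    elif rule == "eigenvalue-ratio":
        lam_max = eigenset.eigenvalues.max()
        if lam_max <= 0:
            pool = []
        else:
            pool = [int(i) for i in np.flatnonzero(eigenset.eigenvalues / lam_max >= c)]
    else:
        raise ValueError(f"unknown pool rule {rule!r}")
    if not pool:
        logger.warning("candidate pool is empty under rule %r", rule)
    return pool


@dataclass(frozen=True)
class FilterResult:
    """Outcome of stepwise eigenvector selection."""

    selected_indices: tuple[int, ...]
    z_path: tuple[float, ...]
    initial_z: float
    final_moran: MoranResult
    converged: bool

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)

    def to_dict(self) -> dict:
        return {
            "selected_indices": list(self.selected_indices),
            "selected_labels": [f"e_{i + 1}" for i in self.selected_indices],
            "z_path": list(self.z_path),
            "initial_z": self.initial_z,
            "final_moran": self.final_moran.to_dict(),
            "converged": self.converged,
        }


class SelectionError(RuntimeError):
    """Every candidate failed during a selection step."""


def _abs_z(residuals: np.ndarray, weights: SpatialWeights) -> tuple[float, MoranResult]:
    res = moran_i(residuals, weights)
    return abs(res.z_score), res


def select_stepwise(
    fit_fn: Callable[[Sequence[int]], np.ndarray],
    eigenset: EigenvectorSet,
    weights: SpatialWeights,
    threshold: float = 0.1,
    max_vectors: int | None = None,
    pool: Sequence[int] | None = None,
) -> FilterResult:
    """Greedy Moran's-I minimization over the candidate pool.

    ``fit_fn`` maps a list of eigenvector column indices to the per-area
    residual vector of the refit model.  At each step every remaining
    candidate is evaluated and the one minimizing |z(Moran's I)| of the
    residuals is appended; ties within 1e-12 prefer the candidate with higher
    Moran's I, then the lower index.  A candidate is only accepted if it does
    not increase |z|.  Stops when |z| < ``threshold`` (converged), the pool is
    exhausted, ``max_vectors`` is reached, or no candidate improves.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if pool is None:
        pool = candidate_pool(eigenset)
    remaining = list(dict.fromkeys(int(i) for i in pool))
    if max_vectors is None:
        max_vectors = min(eigenset.n_vectors, 100)

    current_resid = np.asarray(fit_fn([]), dtype=float)
    current_z, current_moran = _abs_z(current_resid, weights)
    initial_z = current_z
    selected: list[int] = []
    z_path: list[float] = []

    while current_z >= threshold and remaining and len(selected) < max_vectors:
        best = None  # (z, -moran, index, residuals, MoranResult)
        n_failed = 0
        for cand in remaining:
            try:
                resid = np.asarray(fit_fn(selected + [cand]), dtype=float)
                z, mres = _abs_z(resid, weights)
            except (DegenerateInputError, np.linalg.LinAlgError, ValueError) as exc:
                logger.warning("candidate %d skipped: %s", cand, exc)
                n_failed += 1
                continue
            key = (z, -eigenset.moran_of_vector[cand], cand)
            if best is None or _tie_less(key, best[:3]):
                best = (*key, resid, mres)
        if best is None:
            if n_failed == len(remaining):
                raise SelectionError("all candidates failed in this step")
            break
        z_best, _, idx, resid_best, moran_best = best
        if z_best > current_z + 1e-12:
            # greedy minimization never accepts a worsening step
            break
        selected.append(int(idx))
        remaining.remove(int(idx))
        z_path.append(float(z_best))
        current_z, current_resid, current_moran = z_best, resid_best, moran_best

    return FilterResult(
        selected_indices=tuple(selected),
        z_path=tuple(z_path),
        initial_z=float(initial_z),
        final_moran=current_moran,
        converged=bool(current_z < threshold),
    )


def _tie_less(a: tuple, b: tuple) -> bool:
    """Lexicographic comparison with a 1e-12 tolerance on the leading |z|."""
    if a[0] < b[0] - 1e-12:
        return True
    if a[0] > b[0] + 1e-12:
        return False
    return a[1:] < b[1:]


def expand_to_individuals(
    eigenset: EigenvectorSet,
    selected: Sequence[int],
    area_of_individual: Sequence[str],
) -> np.ndarray:
    """Broadcast area-level eigenvectors to an N×p individual-level matrix.

    Row *i* holds the eigenvector values of individual *i*'s area; column
    order follows ``selected``.
    """
    pos: Mapping[str, int] = {a: k for k, a in enumerate(eigenset.area_ids)}
    try:
        rows = np.array([pos[a] for a in area_of_individual])
    except KeyError as exc:
        raise KeyError(f"unknown area id: {exc.args[0]!r}") from None
    sel = list(selected)
    if not sel:
        return np.zeros((len(rows), 0))
    return eigenset.vectors[np.ix_(rows, sel)]
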