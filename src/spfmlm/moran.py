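"""Global Moran's I with analytic (normality) inference and a permutation test.

The statistic for per-area values ``y`` and binary symmetric weights ``v``::

    I = n / S0 * sum_ij v_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

with S0 = sum_ij v_ij.  Under the null of no spatial structure the expectation
is E[I] = -1/(n-1); the variance used for the z-score is the closed form under
the normality assumption, built from the weight sums S0, S1, S2.  A conditional
permutation test is provided as a distribution-free cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .weights import SpatialWeights

__all__ = ["MoranResult", "moran_i", "moran_moments", "moran_permutation_test"]


class DegenerateInputError(ValueError):
    """The statistic is undefined for this input (e.g. constant values)."""


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its null moments and normal-approximation test."""

    i_value: float
    expected_i: float
    variance_i: float
    z_score: float
    p_value: float
    n_used: int

    def to_dict(self) -> dict:
        return {
            "I": self.i_value,
            "expected_I": self.expected_i,
            "variance_I": self.variance_i,
            "z": self.z_score,
            "p": self.p_value,
            "n": self.n_used,
        }


def _check_values(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    y = np.asarray(values, dtype=float).ravel()
    if y.size != weights.n_areas:
        raise ValueError(
            f"values length {y.size} does not match {weights.n_areas} areas"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("values contain non-finite entries")
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant values: Moran's I is undefined (0/0)")
    return y


def _i_statistic(y: np.ndarray, weights: SpatialWeights) -> float:
    z = y - y.mean()
    num = z @ weights.matrix @ z
    den = z @ z
    return float(weights.n_areas / weights.s0 * num / den)


def moran_moments(weights: SpatialWeights, n: int | None = None) -> tuple[float, float]:
    """Null expectation and normality-assumption variance of Moran's I.

    Uses the standard weight sums: S0 = Σv_ij, S1 = ½Σ(v_ij+v_ji)²,
    S2 = Σ_i (Σ_j v_ij + Σ_j v_ji)².
    """
    if n is None:
        n = weights.n_areas
    if n < 3:
        raise ValueError("moments require at least 3 areas")
    v = weights.matrix
    s0 = weights.s0
    if s0 <= 0:
        raise DegenerateInputError("weight matrix has no links (S0 = 0)")
    s1 = 0.5 * float(((v + v.T) ** 2).sum())
    s2 = float(((v.sum(axis=1) + v.sum(axis=0)) ** 2).sum())
    e_i = -1.0 / (n - 1)
    var = (n * n * s1 - n * s2 + 3.0 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i * e_i
    return e_i, var


def moran_i(values, weights: SpatialWeights) -> MoranResult:
    """Moran's I of ``values`` (aligned to ``weights.area_ids``) with a z-test.

    The two-sided p-value comes from the standard normal applied to
    ``(I - E[I]) / sqrt(Var[I])`` with the normality-assumption variance.
    """
    y = _check_values(values, weights)
    n = weights.n_areas
    if n < 2:
        raise ValueError("Moran's I requires at least 2 areas")
    i_val = _i_statistic(y, weights)
    if n >= 3:
        e_i, var = moran_moments(weights, n)
    else:
        e_i, var = -1.0, np.nan
    if not np.isfinite(var) or var <= 0:
        z = np.nan
        p = np.nan
    else:
        z = (i_val - e_i) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return MoranResult(i_val, e_i, var, float(z), float(p), n)


def moran_permutation_test(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> float:
    """Pseudo p-value ``(rank + 1)/(n_perm + 1)`` from random relabelling.

    ``alternative`` is "greater", "less", or "two-sided" (folded tail).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    y = _check_values(values, weights)
    rng = np.random.default_rng(seed)
    obs = _i_statistic(y, weights)
    sims = np.empty(n_perm)
    for k in range(n_perm):
        sims[k] = _i_statistic(rng.permutation(y), weights)
    if alternative == "greater":
        rank = int((sims >= obs).sum())
    elif alternative == "less":
        rank = int((sims <= obs).sum())
    elif alternative == "two-sided":
        e_i = -1.0 / (weights.n_areas - 1)
        rank = int((np.abs(sims - e_i) >= abs(obs - e_i)).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (rank + 1) / (n_perm + 1)
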