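"""Two-level linear mixed models: random intercept plus one random slope.

The model, for individual *i* in neighborhood *j*::

    individual level:    Y_ij = b_0j + b_1j X_ij + r_ij
    neighborhood level:  b_0j = g00 + g01 Z_j + u_0j
                         b_1j = g10 + u_1j

with r_ij ~ N(0, sigma2), u_0j ~ N(0, tau00), u_1j ~ N(0, tau11).  The random
intercept and random slope are independent by default (diagonal covariance);
an unstructured 2×2 covariance is available.  Estimation is by maximum
likelihood by default so that models differing in fixed effects can be
compared by AIC; REML is available for final variance reporting.

Fitting is delegated to statsmodels MixedLM; this module owns the model
specification, the AIC convention (-2·loglik + 2·(fixed effects + variance
parameters)), ICC, conditional modes (BLUPs) of the area intercepts, and
model comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoLevelData",
    "MLMSpec",
    "MLMFit",
    "fit_mlm",
    "icc",
    "icc_from_variances",
    "conditional_modes",
    "area_mean_residuals",
    "compare_fits",
]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Inconsistent two-level data."""


class EstimationError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class TwoLevelData:
    """Linked individual- and neighborhood-level tables.

    ``individuals`` must carry ``area_id`` and the outcome column;
    ``neighborhoods`` must carry ``area_id`` plus area covariates.  Records
    with missing values in used columns are removed listwise at load time.
    """

    individuals: pd.DataFrame
    neighborhoods: pd.DataFrame
    outcome: str = "outcome"

    def __post_init__(self) -> None:
        for col in ("area_id", self.outcome):
            if col not in self.individuals.columns:
                raise DataError(f"individuals table missing column {col!r}")
        if "area_id" not in self.neighborhoods.columns:
            raise DataError("neighborhoods table missing column 'area_id'")
        if self.neighborhoods["area_id"].duplicated().any():
            raise DataError("duplicate area_id in neighborhoods table")
        known = set(self.neighborhoods["area_id"].astype(str))
        used = set(self.individuals["area_id"].astype(str))
        orphan = sorted(used - known)
        if orphan:
            raise DataError(f"individuals reference unknown areas: {orphan[:5]}")
        counts = self.individuals.groupby("area_id").size()
        if len(counts) < 2:
            raise DataError("need at least 2 areas")
        thin = counts[counts < 2]
        if len(thin):
            raise DataError(f"areas with fewer than 2 individuals: {list(thin.index)[:5]}")

    @property
    def area_ids(self) -> list[str]:
        return sorted(self.individuals["area_id"].astype(str).unique())

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_areas(self) -> int:
        return self.individuals["area_id"].nunique()

    def merged(self) -> pd.DataFrame:
        """Individual table joined with its neighborhood covariates."""
        ind = self.individuals.copy()
        ind["area_id"] = ind["area_id"].astype(str)
        nbh = self.neighborhoods.copy()
        nbh["area_id"] = nbh["area_id"].astype(str)
        return ind.merge(nbh, on="area_id", how="left", validate="many_to_one")

    @classmethod
    def from_frames(
        cls,
        individuals: pd.DataFrame,
        neighborhoods: pd.DataFrame,
        outcome: str = "outcome",
        used_columns: Sequence[str] | None = None,
    ) -> "TwoLevelData":
        """Validate and listwise-delete missing records (logged with counts)."""
        ind = individuals.copy()
        cols = ["area_id", outcome] + [
            c for c in (used_columns or []) if c in ind.columns
        ]
        before = len(ind)
        ind = ind.dropna(subset=[c for c in dict.fromkeys(cols)])
        dropped = before - len(ind)
        if dropped:
            logger.info("listwise deletion removed %d of %d individual records", dropped, before)
        return cls(ind.reset_index(drop=True), neighborhoods.reset_index(drop=True), outcome)

    @classmethod
    def from_csv(
        cls,
        individuals_path,
        neighborhoods_path,
        outcome: str = "outcome",
        used_columns: Sequence[str] | None = None,
    ) -> "TwoLevelData":
        ind = pd.read_csv(individuals_path, dtype={"area_id": str})
        nbh = pd.read_csv(neighborhoods_path, dtype={"area_id": str})
        return cls.from_frames(ind, nbh, outcome=outcome, used_columns=used_columns)


@dataclass(frozen=True)
class MLMSpec:
    """Which covariates enter the model and how.

    ``random_slope`` names at most one individual covariate whose slope varies
    by area; the intercept is always random.  ``eigen_columns`` are appended
    spatial-filter covariates (fixed effects only).
    """

    fixed_individual: tuple[str, ...] = ()
    fixed_neighborhood: tuple[str, ...] = ()
    random_slope: str | None = None
    eigen_columns: tuple[str, ...] = ()
    estimation: str = "ML"
    random_structure: str = "diagonal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_individual", tuple(self.fixed_individual))
        object.__setattr__(self, "fixed_neighborhood", tuple(self.fixed_neighborhood))
        object.__setattr__(self, "eigen_columns", tuple(self.eigen_columns))
        if self.random_slope is not None and self.random_slope not in self.fixed_individual:
            raise ValueError("random_slope must be one of the fixed individual covariates")
        overlap = set(self.eigen_columns) & set(self.fixed_individual + self.fixed_neighborhood)
        if overlap:
            raise ValueError(f"eigen_columns overlap covariates: {sorted(overlap)}")
        if self.estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        if self.random_structure not in ("diagonal", "unstructured"):
            raise ValueError("random_structure must be 'diagonal' or 'unstructured'")

    @property
    def fixed_effects(self) -> tuple[str, ...]:
        return self.fixed_individual + self.fixed_neighborhood + self.eigen_columns

    def with_eigen(self, eigen_columns: Sequence[str]) -> "MLMSpec":
        return replace(self, eigen_columns=tuple(eigen_columns))


@dataclass(frozen=True)
class MLMFit:
    """Estimates from one mixed-model fit."""

    spec: MLMSpec
    gamma: pd.DataFrame = field(repr=False)  # columns: estimate, se, p
    var_individual: float
    var_intercept: float
    var_slope: float | None
    loglik: float
    n_params: int
    conditional_modes_: pd.Series = field(repr=False)
    marginal_residuals_: pd.Series = field(repr=False)
    area_of_obs_: pd.Series = field(repr=False)
    n_obs: int
    n_areas: int
    converged: bool

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def gamma_dict(self) -> dict:
        return {
            name: {
                "estimate": float(r["estimate"]),
                "se": float(r["se"]),
                "p": float(r["p"]),
            }
            for name, r in self.gamma.iterrows()
        }


def _design(data: TwoLevelData, spec: MLMSpec, extra: pd.DataFrame | None) -> pd.DataFrame:
    df = data.merged()
    if extra is not None:
        if len(extra) != len(df):
            raise DataError("extra columns do not align with the individual table")
        df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    missing = [c for c in spec.fixed_effects if c not in df.columns]
    if missing:
        raise DataError(f"covariates not found in data: {missing}")
    use = ["area_id", data.outcome, *spec.fixed_effects]
    out = df[list(dict.fromkeys(use))].copy()
    if out.isna().any().any():
        raise DataError("missing values remain in modeling columns")
    return out


def fit_mlm(
    data: TwoLevelData,
    spec: MLMSpec,
    extra_columns: pd.DataFrame | None = None,
) -> MLMFit:
    """Fit the two-level model by (RE)ML and return estimates and BLUPs.

    ``extra_columns`` may supply individual-level columns (e.g. expanded
    eigenvectors) not present in the stored tables.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = _design(data, spec, extra_columns)
    # rename to parser-safe symbols; keep the map for reporting
    safe = {name: f"v{k}" for k, name in enumerate(spec.fixed_effects)}
    df = df.rename(columns={data.outcome: "y_", **safe})

    rhs = " + ".join(safe.values()) if safe else "1"
    formula = f"y_ ~ {rhs}"
    vc_formula = None
    if spec.random_slope is None:
        re_formula = "1"
    elif spec.random_structure == "diagonal":
        re_formula = "1"
        vc_formula = {"slope": f"0 + {safe[spec.random_slope]}"}
    else:
        re_formula = f"1 + {safe[spec.random_slope]}"

    fixed_rank = np.linalg.matrix_rank(
        np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in safe.values()])
    )
    if fixed_rank < 1 + len(safe):
        raise DataError("collinear fixed-effect design")

    model = smf.mixedlm(
        formula, df, groups=df["area_id"], re_formula=re_formula, vc_formula=vc_formula
    )
    reml = spec.estimation == "REML"
    result = None
    last_exc: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        # gradient methods occasionally stall or report a spurious boundary
        # solution (even flagging convergence); run a derivative-free method
        # as well and keep the best finite log-likelihood
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=reml, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_exc = exc
                continue
            if not np.isfinite(cand.llf):
                continue
            if result is None or cand.llf > result.llf + 1e-6:
                result = cand
            if method == "powell" and result.converged:
                break  # lbfgs and powell agree often enough; nm is a last resort
    if result is None:
        raise EstimationError(f"mixed-model fit failed: {last_exc}")
    if not result.converged:
        logger.warning("optimizer did not flag convergence; estimates may sit on a boundary")

    inv = {v: k for k, v in safe.items()}
    names = [("Intercept" if p == "Intercept" else inv.get(p, p)) for p in result.fe_params.index]
    gamma = pd.DataFrame(
        {
            "estimate": result.fe_params.to_numpy(),
            "se": result.bse_fe.to_numpy(),
            "p": result.pvalues[result.fe_params.index].to_numpy(),
        },
        index=names,
    )

    sigma2 = float(result.scale)
    if spec.random_slope is None:
        tau00 = float(result.cov_re.iloc[0, 0])
        tau11 = None
    elif spec.random_structure == "diagonal":
        tau00 = float(result.cov_re.iloc[0, 0])
        tau11 = float(result.vcomp[0])
    else:
        tau00 = float(result.cov_re.iloc[0, 0])
        tau11 = float(result.cov_re.iloc[1, 1])
    if min(tau00, sigma2) < 0:
        raise EstimationError("negative variance estimate")
    if tau00 == 0 or (tau11 is not None and tau11 == 0):
        logger.warning("variance component estimated at the zero boundary")

    n_var = 2 + (0 if tau11 is None else 1)
    if spec.random_slope is not None and spec.random_structure == "unstructured":
        n_var += 1  # intercept-slope covariance
    n_params = len(gamma) + n_var

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            re_modes = result.random_effects
        modes = pd.Series(
            {str(g): float(vals.iloc[0]) for g, vals in re_modes.items()}, name="u0"
        ).sort_index()
    except (ValueError, np.linalg.LinAlgError):
        # tau00 at the zero boundary: complete shrinkage, all modes are 0
        groups = sorted(df["area_id"].astype(str).unique())
        modes = pd.Series(0.0, index=groups, name="u0")

    fe_pred = result.predict(df)  # fixed-effects-only prediction
    resid = df["y_"] - fe_pred

    return MLMFit(
        spec=spec,
        gamma=gamma,
        var_individual=sigma2,
        var_intercept=tau00,
        var_slope=tau11,
        loglik=float(result.llf),
        n_params=n_params,
        conditional_modes_=modes,
        marginal_residuals_=resid,
        area_of_obs_=df["area_id"].astype(str),
        n_obs=len(df),
        n_areas=df["area_id"].nunique(),
        converged=bool(result.converged),
    )


def icc_from_variances(var_intercept: float, var_individual: float) -> float:
    """ICC = tau00 / (tau00 + sigma2), the between-area variance share."""
    total = var_intercept + var_individual
    if total <= 0:
        raise ValueError("both variance components are zero; ICC undefined")
    return var_intercept / total


def icc(fit: MLMFit) -> float:
    """Intra-class correlation from a null-model fit."""
    if fit.spec.fixed_effects:
        raise ValueError("ICC is defined on the null (covariate-free) model")
    return icc_from_variances(fit.var_intercept, fit.var_individual)


def conditional_modes(fit: MLMFit, ordering: Sequence[str] | None = None) -> np.ndarray:
    """Empirical-Bayes predictions of u_0j, aligned to ``ordering``.

    These are the neighborhood-level residuals whose spatial dependency the
    pipeline diagnoses.
    """
    modes = fit.conditional_modes_
    if ordering is None:
        return modes.to_numpy()
    missing = [a for a in ordering if a not in modes.index]
    if missing:
        raise KeyError(f"areas absent from the fit: {missing[:5]}")
    return modes.loc[list(ordering)].to_numpy()


def area_mean_residuals(fit: MLMFit, ordering: Sequence[str] | None = None) -> np.ndarray:
    """Per-area means of the marginal (fixed-effects-only) residuals."""
    means = fit.marginal_residuals_.groupby(fit.area_of_obs_).mean().sort_index()
    if ordering is None:
        return means.to_numpy()
    missing = [a for a in ordering if a not in means.index]
    if missing:
        raise KeyError(f"areas absent from the fit: {missing[:5]}")
    return means.loc[list(ordering)].to_numpy()


def compare_fits(fits: dict[str, MLMFit], baseline: str | None = None) -> pd.DataFrame:
    """Side-by-side AIC/loglik/variance table with proportional reductions.

    Variance reductions are relative to ``baseline`` (default: the first fit),
    in the "explains X% of individual-level variance" style.  Refuses to mix
    REML fits with different fixed effects.
    """
    if not fits:
        raise ValueError("no fits to compare")
    names = list(fits)
    modes = {f.spec.estimation for f in fits.values()}
    if "REML" in modes:
        fe_sets = {f.spec.fixed_effects for f in fits.values()}
        if len(fe_sets) > 1:
            raise ValueError(
                "REML fits with different fixed effects are not comparable; refit with ML"
            )
    if baseline is None:
        baseline = names[0]
    base = fits[baseline]
    rows = []
    for name in names:
        f = fits[name]
        row = {
            "model": name,
            "estimation": f.spec.estimation,
            "aic": f.aic,
            "loglik": f.loglik,
            "var_individual": f.var_individual,
            "var_intercept": f.var_intercept,
            "var_slope": f.var_slope,
            "n_params": f.n_params,
        }
        if base.var_individual > 0:
            row["prop_reduction_individual"] = 1 - f.var_individual / base.var_individual
        if base.var_intercept > 0:
            row["prop_reduction_intercept"] = 1 - f.var_intercept / base.var_intercept
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
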