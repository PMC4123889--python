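"""The spatially filtered multilevel modeling pipeline.

Model sequence, mirroring the usual reporting layout for this family of
analyses:

1. null model (random intercept only) → ICC;
2. Level-1 model (individual covariates, random income-type slope optional);
3. Level-2 model (individual + neighborhood covariates);
4. Moran diagnosis of the Level-2 neighborhood-level residuals
   (conditional modes of u_0j by default);
5. if |z(Moran's I)| ≥ threshold: stepwise Moran-eigenvector selection and a
   refit of the Level-2 model with the selected eigenvectors appended as
   fixed effects — the spatially filtered multilevel model.

The report collects, per model, the fixed-effect table with significance
stars, the variance components, AIC and log-likelihood, plus the before/after
Moran results and the selection path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .eigenfilter import (
    EigenvectorSet,
    FilterResult,
    candidate_pool,
    expand_to_individuals,
    extract_eigenvectors,
    make_projector,
    select_stepwise,
)
from .mlm import (
    MLMFit,
    MLMSpec,
    TwoLevelData,
    area_mean_residuals,
    conditional_modes,
    fit_mlm,
    icc,
)
from .moran import MoranResult, moran_i
from .weights import SpatialWeights, islands

__all__ = ["PipelineConfig", "Report", "run_pipeline", "residual_fn_factory", "export_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the model sequence on one dataset."""

    fixed_individual: tuple[str, ...] = ()
    fixed_neighborhood: tuple[str, ...] = ()
    random_slope: str | None = None
    estimation: str = "ML"
    random_structure: str = "diagonal"
    outcome: str = "outcome"
    threshold: float = 0.1
    candidate_rule: str = "positive-moran"
    ratio_c: float = 0.25
    projector: str = "intercept-only"  # or "area-covariates"
    selection_mode: str = "fast-OLS"  # or "exact-refit"
    residual_source: str = "conditional-modes"  # or "area-means"
    max_vectors: int | None = None
    # fast-OLS selection minimizes |z| of OLS-filtered residuals; the refit
    # mixed model's residuals can land back above the threshold, so selection
    # is re-based on the refit model and repeated up to max_rounds times
    max_rounds: int = 3
    drop_islands: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.selection_mode not in ("fast-OLS", "exact-refit"):
            raise ValueError("selection_mode must be 'fast-OLS' or 'exact-refit'")
        if self.projector not in ("intercept-only", "area-covariates"):
            raise ValueError("projector must be 'intercept-only' or 'area-covariates'")
        if self.residual_source not in ("conditional-modes", "area-means"):
            raise ValueError("residual_source must be 'conditional-modes' or 'area-means'")
        object.__setattr__(self, "fixed_individual", tuple(self.fixed_individual))
        object.__setattr__(self, "fixed_neighborhood", tuple(self.fixed_neighborhood))

    def base_spec(self) -> MLMSpec:
        return MLMSpec(
            fixed_individual=self.fixed_individual,
            fixed_neighborhood=self.fixed_neighborhood,
            random_slope=self.random_slope,
            estimation=self.estimation,
            random_structure=self.random_structure,
        )


@dataclass(frozen=True)
class Report:
    """Full pipeline output; serializes to JSON and a Table-2-style text table."""

    models: dict  # name -> MLMFit, in fitted order
    icc_null: float
    moran_before: MoranResult
    moran_after: MoranResult | None
    filter_result: FilterResult | None
    selected_eigenvectors: pd.DataFrame | None = field(repr=False)
    notes: tuple[str, ...]
    config: PipelineConfig
    provenance: dict

    def to_dict(self) -> dict:
        blocks = {}
        for name, fit in self.models.items():
            blocks[name] = {
                "estimation": fit.spec.estimation,
                "gamma": fit.gamma_dict(),
                "var_individual": fit.var_individual,
                "var_intercept": fit.var_intercept,
                "var_slope": fit.var_slope,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "n_params": fit.n_params,
                "n_obs": fit.n_obs,
                "n_areas": fit.n_areas,
                "converged": fit.converged,
            }
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.config.__dict__.items()}
        return {
            "models": blocks,
            "icc_null": self.icc_null,
            "moran_before": self.moran_before.to_dict(),
            "moran_after": None if self.moran_after is None else self.moran_after.to_dict(),
            "filter": None if self.filter_result is None else self.filter_result.to_dict(),
            "selected_eigenvectors": (
                None
                if self.selected_eigenvectors is None
                else self.selected_eigenvectors.to_dict(orient="list")
            ),
            "notes": list(self.notes),
            "config": cfg,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        return _format_table(self)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _provenance(config: PipelineConfig) -> dict:
    import scipy
    import statsmodels

    return {
        "spfmlm": _pkg_version,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.version.version
        if hasattr(statsmodels, "version")
        else statsmodels.__version__,
        "seed": config.seed,
    }


def residual_fn_factory(
    data: TwoLevelData,
    spec: MLMSpec,
    weights: SpatialWeights,
    eigenset: EigenvectorSet,
    mode: str = "fast-OLS",
    base_fit: MLMFit | None = None,
    residual_source: str = "conditional-modes",
) -> Callable[[Sequence[int]], np.ndarray]:
    """Residual-producing contract for stepwise selection.

    fast-OLS: the mixed model is fit once; each candidate set is evaluated by
    regressing the fixed base neighborhood residual vector on the candidate
    eigenvector columns at the area level and returning the OLS residual
    (the single-level behavior of standard spatial-filtering software).

    exact-refit: each candidate set triggers a full mixed-model refit with the
    expanded eigenvectors as fixed effects; the returned residuals are the
    refit conditional modes.  Faithful to the multilevel reading, but J times
    slower per step.
    """
    ordering = list(weights.area_ids)
    resid_of = conditional_modes if residual_source == "conditional-modes" else area_mean_residuals

    if mode == "fast-OLS":
        if base_fit is None:
            base_fit = fit_mlm(data, spec)
        base = np.asarray(resid_of(base_fit, ordering), dtype=float)

        def fn(selected: Sequence[int]) -> np.ndarray:
            if not selected:
                return base
            e = eigenset.vectors[:, list(selected)]
            x = np.column_stack([np.ones(len(base)), e])
            beta, *_ = np.linalg.lstsq(x, base, rcond=None)
            return base - x @ beta

        return fn

    if mode != "exact-refit":
        raise ValueError(f"unknown selection mode {mode!r}")

    area_of_ind = data.individuals["area_id"].astype(str).tolist()

    def fn_refit(selected: Sequence[int]) -> np.ndarray:
        if not selected:
            fit = base_fit if base_fit is not None else fit_mlm(data, spec)
            return np.asarray(resid_of(fit, ordering), dtype=float)
        cols = [f"E{k}" for k in selected]
        extra = pd.DataFrame(
            expand_to_individuals(eigenset, list(selected), area_of_ind), columns=cols
        )
        fit = fit_mlm(data, spec.with_eigen(cols), extra_columns=extra)
        return np.asarray(resid_of(fit, ordering), dtype=float)

    return fn_refit


def run_pipeline(
    data: TwoLevelData, weights: SpatialWeights, config: PipelineConfig
) -> Report:
    """Fit the full model sequence and return the report."""
    notes: list[str] = []

    data_areas = set(data.individuals["area_id"].astype(str))
    w_areas = set(weights.area_ids)
    missing = sorted(data_areas - w_areas)
    if missing:
        raise ValueError(f"[weights] areas in data but not in weights: {missing[:5]}")
    if w_areas - data_areas:
        weights = weights.subset([a for a in weights.area_ids if a in data_areas])
        notes.append(f"weights restricted to the {weights.n_areas} areas present in the data")

    isl = islands(weights)
    if isl:
        if not config.drop_islands:
            raise ValueError(
                f"[weights] islands present ({isl[:5]}); pass drop_islands=True to remove them"
            )
        weights = weights.drop_islands()
        keep = set(weights.area_ids)
        ind = data.individuals[data.individuals["area_id"].astype(str).isin(keep)]
        nbh = data.neighborhoods[data.neighborhoods["area_id"].astype(str).isin(keep)]
        data = TwoLevelData(ind.reset_index(drop=True), nbh.reset_index(drop=True), data.outcome)
        notes.append(f"dropped {len(isl)} island area(s): {isl}")

    base = config.base_spec()
    models: dict[str, MLMFit] = {}
    try:
        models["null"] = fit_mlm(
            data,
            MLMSpec(estimation=config.estimation),
        )
    except Exception as exc:
        raise RuntimeError(f"[null] {exc}") from exc
    icc_null = icc(models["null"])

    try:
        models["level1"] = fit_mlm(
            data,
            MLMSpec(
                fixed_individual=config.fixed_individual,
                random_slope=config.random_slope,
                estimation=config.estimation,
                random_structure=config.random_structure,
            ),
        )
    except Exception as exc:
        raise RuntimeError(f"[level1] {exc}") from exc

    try:
        models["level2"] = fit_mlm(data, base)
    except Exception as exc:
        raise RuntimeError(f"[level2] {exc}") from exc

    ordering = list(weights.area_ids)
    resid_of = (
        conditional_modes if config.residual_source == "conditional-modes" else area_mean_residuals
    )

    def resid_for_moran(fit: MLMFit) -> np.ndarray:
        r = np.asarray(resid_of(fit, ordering), dtype=float)
        if np.ptp(r) == 0:
            # tau00 at the zero boundary collapses the modes to a constant;
            # diagnose the raw area-mean residuals instead
            r = np.asarray(area_mean_residuals(fit, ordering), dtype=float)
        return r

    moran_before = moran_i(resid_for_moran(models["level2"]), weights)

    moran_after: MoranResult | None = None
    filter_result: FilterResult | None = None
    eig_table: pd.DataFrame | None = None

    if abs(moran_before.z_score) < config.threshold:
        notes.append(
            f"no filtering: |z(Moran's I)| = {abs(moran_before.z_score):.4f} "
            f"< threshold {config.threshold}"
        )
    else:
        if config.projector == "intercept-only":
            projector = make_projector("intercept-only", weights.n_areas)
        else:
            z = data.neighborhoods.set_index("area_id").loc[
                ordering, list(config.fixed_neighborhood)
            ]
            design = np.column_stack([np.ones(len(ordering)), z.to_numpy(float)])
            projector = make_projector(design)
        eigenset = extract_eigenvectors(weights, projector)
        pool = candidate_pool(eigenset, config.candidate_rule, config.ratio_c)
        max_vec = config.max_vectors
        if max_vec is None:
            max_vec = min(weights.n_areas - projector.rank, 100)
        area_of_ind = data.individuals["area_id"].astype(str).tolist()

        # selection rounds: select against the current model's residuals,
        # refit with the accumulated eigenvectors, repeat while the refit
        # residual still exceeds the threshold (exact-refit needs one round)
        n_rounds = 1 if config.selection_mode == "exact-refit" else max(1, config.max_rounds)
        selected: list[int] = []
        z_path: list[float] = []
        current_fit = models["level2"]
        moran_current = moran_before
        best: tuple | None = None  # (|z_after|, fit, selected, z_path, moran)
        for _ in range(n_rounds):
            round_pool = [k for k in pool if k not in selected]
            if not round_pool or len(selected) >= max_vec:
                break
            fn = residual_fn_factory(
                data,
                base,
                weights,
                eigenset,
                mode=config.selection_mode,
                base_fit=current_fit,
                residual_source=config.residual_source,
            )
            try:
                step = select_stepwise(
                    fn,
                    eigenset,
                    weights,
                    threshold=config.threshold,
                    max_vectors=max_vec - len(selected),
                    pool=round_pool,
                )
            except Exception as exc:
                raise RuntimeError(f"[selection] {exc}") from exc
            if not step.selected_indices:
                break
            selected.extend(step.selected_indices)
            z_path.extend(step.z_path)
            cols = [eigenset.label(k) for k in selected]
            extra = pd.DataFrame(
                expand_to_individuals(eigenset, selected, area_of_ind), columns=cols
            )
            try:
                current_fit = fit_mlm(data, base.with_eigen(cols), extra_columns=extra)
            except Exception as exc:
                raise RuntimeError(f"[filtered] {exc}") from exc
            moran_current = moran_i(resid_for_moran(current_fit), weights)
            if best is None or abs(moran_current.z_score) < best[0]:
                best = (
                    abs(moran_current.z_score),
                    current_fit,
                    list(selected),
                    list(z_path),
                    moran_current,
                )
            if abs(moran_current.z_score) < config.threshold:
                break

        if best is not None:
            _, best_fit, selected, z_path, moran_current = best
            models["filtered"] = best_fit
            moran_after = moran_current
            filter_result = FilterResult(
                selected_indices=tuple(selected),
                z_path=tuple(z_path),
                initial_z=float(abs(moran_before.z_score)),
                final_moran=moran_after,
                converged=bool(abs(moran_after.z_score) < config.threshold),
            )
            eig_table = eigenset.to_frame(selected)
        else:
            notes.append("selection chose no eigenvectors; filtered model not fit")
            filter_result = FilterResult(
                selected_indices=(),
                z_path=(),
                initial_z=float(abs(moran_before.z_score)),
                final_moran=moran_before,
                converged=bool(abs(moran_before.z_score) < config.threshold),
            )
            moran_after = moran_before

    return Report(
        models=models,
        icc_null=icc_null,
        moran_before=moran_before,
        moran_after=moran_after,
        filter_result=filter_result,
        selected_eigenvectors=eig_table,
        notes=tuple(notes),
        config=config,
        provenance=_provenance(config),
    )


def _format_table(report: Report) -> str:
    """Aligned text table in the variables × models layout."""
    order = [n for n in ("null", "level1", "level2", "filtered") if n in report.models]
    titles = {
        "null": "Null",
        "level1": "Level-1",
        "level2": "Level-2",
        "filtered": "Spatially filtered",
    }
    var_rows: list[str] = []
    seen: set[str] = set()
    for name in order:
        for v in report.models[name].gamma.index:
            if v not in seen and v != "Intercept":
                seen.add(v)
                var_rows.append(v)

    def cell(fit: MLMFit, var: str) -> str:
        if var not in fit.gamma.index:
            return "-"
        est = fit.gamma.loc[var, "estimate"]
        return f"{est:.4g}{_stars(fit.gamma.loc[var, 'p'])}"

    rows: list[tuple[str, list[str]]] = []
    for v in var_rows:
        rows.append((v, [cell(report.models[n], v) for n in order]))
    rows.append(("Variance (individual)", [f"{report.models[n].var_individual:.4g}" for n in order]))
    rows.append(
        (
            "Variance (slope)",
            [
                "-" if report.models[n].var_slope is None else f"{report.models[n].var_slope:.4g}"
                for n in order
            ],
        )
    )
    rows.append(("Variance (neighborhood)", [f"{report.models[n].var_intercept:.4g}" for n in order]))
    rows.append(("Constant", [cell(report.models[n], "Intercept") for n in order]))
    n_sel = report.filter_result.n_selected if report.filter_result else None
    rows.append(
        (
            "Eigenvector selection",
            [
                (f"{n_sel} eigenvectors" if n == "filtered" and n_sel is not None else "-")
                for n in order
            ],
        )
    )
    mb, ma = report.moran_before, report.moran_after

    def moran_cell(n: str) -> str:
        if n == "level2":
            return f"{mb.i_value:.3f}{_stars(mb.p_value)}"
        if n == "filtered" and ma is not None:
            return f"{ma.i_value:.3f}{_stars(ma.p_value)}"
        return "-"

    rows.append(("Moran's I of nbhd residuals", [moran_cell(n) for n in order]))
    rows.append(("AIC", [f"{report.models[n].aic:.1f}" for n in order]))
    rows.append(("Log-likelihood", [f"{report.models[n].loglik:.1f}" for n in order]))

    head = ["Variables"] + [titles[n] for n in order]
    table = [head] + [[r[0]] + r[1] for r in rows]
    widths = [max(len(row[c]) for row in table) for c in range(len(head))]
    lines = []
    for k, row in enumerate(table):
        lines.append("  ".join(s.ljust(w) for s, w in zip(row, widths)).rstrip())
        if k == 0:
            lines.append("-" * (sum(widths) + 2 * (len(widths) - 1)))
    lines.append("")
    lines.append(f"ICC (null model): {report.icc_null:.3f}")
    lines.append(f"Estimation: {', '.join(f'{n}={report.models[n].spec.estimation}' for n in order)}")
    if report.filter_result is not None:
        fr = report.filter_result
        labels = ", ".join(f"e_{i + 1}" for i in fr.selected_indices)
        lines.append(
            f"Selected eigenvectors ({fr.n_selected}): {labels or 'none'}; "
            f"|z| path {['%.3f' % z for z in fr.z_path]}; converged={fr.converged}"
        )
    for note in report.notes:
        lines.append(f"Note: {note}")
    return "\n".join(lines) + "\n"


def export_report(report: Report, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json, report.txt and (if present) selected eigenvectors CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    jpath = out / "report.json"
    jpath.write_text(report.to_json() + "\n")
    paths["json"] = jpath
    tpath = out / "report.txt"
    tpath.write_text(report.to_text())
    paths["text"] = tpath
    if report.selected_eigenvectors is not None:
        cpath = out / "eigenvectors.csv"
        report.selected_eigenvectors.to_csv(cpath, index=False)
        paths["eigenvectors"] = cpath
    return paths


def load_report_dict(path: str | Path) -> dict:
    """Read back an exported report.json as a plain dict."""
    with open(path) as fh:
        return json.load(fh)
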