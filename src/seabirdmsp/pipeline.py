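"""End-to-end orchestration: survey -> models -> surfaces -> maps -> plans.

`fit_species_models` reproduces the model-building battery for each
species: variance-inflation screening of candidate covariates, a
per-covariate linear-vs-quadratic choice under negative binomial
regression (controlling for month and year), manual backward stepwise
simplification at the 0.05 level, promotion to a zero-inflated negative
binomial with detection-bias covariates in the inflation part, the
overdispersion and Vuong diagnostics, a year x oceanography interaction
chosen by likelihood ratio, and n-fold cross-validation.

`run_pipeline` chains the full analysis on a synthetic survey and
returns every intermediate product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import habitat_maps, human_use, kriging, prioritization, survey_prep, zinb
from .config import SimulationConfig
from .region import StudyRegion, default_region
from .synthetic_data import simulate_dataset
from .zinb import DETECTION_CANDIDATES, ModelSpec, Term, TestResult, ZINBFit

logger = logging.getLogger(__name__)

__all__ = ["SpeciesModelResult", "fit_species_models", "choose_form",
           "run_pipeline", "coefficient_table"]

#: habitat covariate candidates offered to every species model
HABITAT_CANDIDATES = ("sst", "sss", "ssf", "dist_land_m", "dist_200_m",
                      "dist_sefi_m", "npgo", "pdo", "soi", "ui")


@dataclass
class SpeciesModelResult:
    """Everything the model-building battery produced for one species."""

    species: str
    spec: ModelSpec
    fit: ZINBFit
    kind: str  # preferred family after the Vuong test
    vif: pd.Series
    lr_alpha: TestResult
    vuong: TestResult
    interaction_tests: list[TestResult] = field(default_factory=list)
    cv: TestResult | None = None


def choose_form(species: str, cov: str, data: pd.DataFrame, level: float = 0.05) -> Term:
    """Linear or quadratic form for one covariate, judged by the
    significance of the squared term in a single-covariate negative
    binomial model with month/year controls."""
    spec = ModelSpec(species=species, count_terms=(Term(cov, "quadratic"),),
                     inflation_terms=())
    try:
        f = zinb.fit(spec, data, kind="nb")
    except ValueError:
        return Term(cov, "linear")
    p = float(f.pvalues[f"{cov}^2"])
    return Term(cov, "quadratic" if p < level else "linear")


def fit_species_models(
    model_table: pd.DataFrame,
    species: list[str],
    candidates=HABITAT_CANDIDATES,
    level: float = 0.05,
    cv_folds: int = 10,
    seed: int = 0,
) -> dict[str, SpeciesModelResult]:
    results: dict[str, SpeciesModelResult] = {}
    vif, vif_ok = zinb.vif_screen(model_table, list(candidates))
    if not vif_ok:
        logger.warning("VIF screen flags collinearity: %s",
                       vif[vif >= 10].to_dict())
    usable = [c for c in candidates if vif[c] < 10]
    for sp in species:
        logger.info("building model for %s", sp)
        terms = tuple(choose_form(sp, c, model_table, level) for c in usable)
        full = ModelSpec(species=sp, count_terms=terms, inflation_terms=())
        reduced, nb_fit = zinb.backward_stepwise(full, model_table, level=level, kind="nb")
        pois_fit = zinb.fit(reduced, model_table, kind="poisson")
        lr = zinb.lr_test_alpha(nb_fit, pois_fit)
        zspec = ModelSpec(species=sp, count_terms=reduced.count_terms,
                          inflation_terms=DETECTION_CANDIDATES)
        zspec, zfit = zinb.select_detection_terms(zspec, model_table, level=level)
        vuong = zinb.vuong_test(zfit, nb_fit)
        kind = "zinb" if vuong.preferred == "zinb" else "nb"
        base = zspec if kind == "zinb" else reduced
        final_spec, final_fit, inter = zinb.select_interaction(
            base, model_table, level=level, kind=kind)
        cv = zinb.cross_validate(final_spec, model_table, folds=cv_folds,
                                 kind=kind, seed=seed)
        results[sp] = SpeciesModelResult(
            species=sp, spec=final_spec, fit=final_fit, kind=kind, vif=vif,
            lr_alpha=lr, vuong=vuong, interaction_tests=inter, cv=cv)
    return results


def coefficient_table(results: dict[str, SpeciesModelResult]) -> pd.DataFrame:
    """Tidy variable x species summary: form (L/Q), sign, significance."""
    rows = []
    for sp, res in results.items():
        pv = res.fit.pvalues
        for t in res.spec.count_terms:
            name = f"{t.name}^2" if t.form == "quadratic" else t.name
            coef = res.fit.summary().loc[name, "coef"]
            p = float(pv[name])
            stars = "***" if p < 1e-4 else "**" if p < 0.01 else "*" if p < 0.05 else ""
            rows.append(dict(species=sp, variable=t.name,
                             form="Q" if t.form == "quadratic" else "L",
                             sign="+" if coef > 0 else "-", p=p, stars=stars,
                             interaction=(res.spec.interaction == t.name)))
        for z in res.spec.inflation_terms:
            name = f"inflate:{z}"
            coef = res.fit.summary().loc[name, "coef"]
            p = float(pv[name])
            rows.append(dict(species=sp, variable=z, form="L",
                             sign="+" if coef > 0 else "-", p=p,
                             stars="***" if p < 1e-4 else "**" if p < 0.01 else "*" if p < 0.05 else "",
                             interaction=False))
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    config: SimulationConfig
    region: StudyRegion
    dataset: object
    model_table: pd.DataFrame
    prep_report: dict
    models: dict[str, SpeciesModelResult]
    surfaces: dict
    surface_summary: dict
    maps: dict
    cells: pd.DataFrame
    ensembles: dict  # (scenario, target) -> RunEnsemble


def run_pipeline(
    config: SimulationConfig | None = None,
    region: StudyRegion | None = None,
    species: list[str] | None = None,
    targets=(0.10, 0.30, 0.50),
    runs: int = 100,
    seed: int = 0,
    grid_resolution_m: float = 1000.0,
    cv_folds: int = 10,
) -> PipelineResult:
    """Simulate a survey program and run the complete analysis chain."""
    config = config or SimulationConfig(seed=seed)
    region = region or default_region()
    species = species or list(config.species)
    ds = simulate_dataset(config, region)
    table, report = survey_prep.build_model_table(
        ds.effort, ds.segments, ds.sightings, ds.ctd,
        ds.monthly_indices, ds.daily_upwelling, region, species)
    models = fit_species_models(table, species, cv_folds=cv_folds, seed=seed)
    cells = habitat_maps.build_grid(region, resolution_m=grid_resolution_m)
    grid = cells[["cx", "cy"]].to_numpy()
    surfaces, surf_summary = kriging.surface_suite(table, grid)
    fits = {sp: res.fit for sp, res in models.items()}
    maps = habitat_maps.build_habitat_maps(fits, table, surfaces, region, cells=cells)
    footprints = ds.activities
    cells_scored = human_use.score_cells(maps["cells"], footprints,
                                         cell_size_m=grid_resolution_m)
    ensembles = {}
    for scenario in (1, 2):
        for t in targets:
            prob = prioritization.build_problem(cells_scored, scenario, t)
            ensembles[(scenario, t)] = prioritization.run_ensemble(
                prob, R=runs, seed=seed)
    return PipelineResult(
        config=config, region=region, dataset=ds, model_table=table,
        prep_report=report, models=models, surfaces=surfaces,
        surface_summary=surf_summary, maps=maps, cells=cells_scored,
        ensembles=ensembles)
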