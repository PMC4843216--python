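"""End-to-end orchestration: ingest → grid → classify → infer → measure.

One configuration drives the whole chain; outputs are plain CSV plus a JSON
manifest listing every file with its row count and the configuration echoed
back.  A rerun with the same configuration and seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from . import absence, glm, metrics, persistence, records, simulate
from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, constants and output location for one pipeline run.

    Either ``scenario`` names a synthetic preset, or the three input paths
    point at occurrence / cell-covariate / country-covariate CSVs.
    """

    out_dir: str = "occgaps_out"
    scenario: Optional[str] = "high-effort"
    occurrences_path: Optional[str] = None
    cell_covariates_path: Optional[str] = None
    country_covariates_path: Optional[str] = None
    cutoff_year: int = 1980
    end_year: int = 2008
    threshold: float = 0.5
    effort_mode: str = "all_species"
    cell_size_km: float = 48.24
    seed: int = 0
    write_geojson: bool = False

    def __post_init__(self) -> None:
        if not self.cutoff_year < self.end_year:
            raise ValueError("cutoff_year must precede end_year")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.scenario is None and self.occurrences_path is None:
            raise ValueError("either a scenario preset or input paths are required")

    def model_config(self) -> persistence.ModelConfig:
        return persistence.ModelConfig(
            cutoff_year=self.cutoff_year,
            end_year=self.end_year,
            threshold=self.threshold,
            effort_mode=self.effort_mode,
        )

    def grid_spec(self) -> GridSpec:
        return GridSpec(cell_size_km=self.cell_size_km)


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = {"rows": int(len(df))}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON).

    Stage order: ingest (or simulate) → period-assign and grid → classify
    cells → persistence inference → extant matrices, richness, EOO → realm
    and country GLMs.  On a stage failure the manifest is still written,
    with a FAILED marker naming the stage, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.grid_spec()
    manifest: dict = {"config": asdict(config), "outputs": {}, "status": "ok"}
    stage = "ingest"
    t0 = time.perf_counter()
    try:
        if config.scenario is not None:
            scenario = simulate.scenario_preset(config.scenario, seed=config.seed)
            sim = simulate.simulate(scenario)
            _write(sim.cells, out / "cell_covariates.csv", manifest)
            _write(sim.countries, out / "country_covariates.csv", manifest)
            _write(sim.pairs, out / "truth_pairs.csv", manifest)
            _write(sim.effort, out / "truth_effort.csv", manifest)
            _write(sim.zero_cells, out / "truth_zero_cells.csv", manifest)
            occurrences = simulate.records_frame(sim.counts, spec)
            _write(occurrences, out / "occurrences.csv", manifest)
            recs = records.read_occurrences(out / "occurrences.csv")
            cell_cov = sim.cells
            country_cov = sim.countries
        else:
            for p in (config.occurrences_path, config.cell_covariates_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing input file: {p}")
            recs = records.read_occurrences(config.occurrences_path)
            cell_cov = pd.read_csv(config.cell_covariates_path)
            country_cov = (
                pd.read_csv(config.country_covariates_path)
                if config.country_covariates_path
                else None
            )

        stage = "grid"
        gridded = records.grid_records(recs, spec, config.cutoff_year)
        _write(gridded, out / "gridded_records.csv", manifest)
        logger.info("gridded %d records (%d read)", len(gridded), len(recs))

        stage = "classify"
        statuses = absence.classify_cells(gridded)
        joined, n_dropped = absence.attach_covariates(statuses, cell_cov)
        manifest["n_cells_without_covariates"] = n_dropped
        _write(joined, out / "cell_status.csv", manifest)
        if config.write_geojson:
            from .grid import CellIndex, cells_to_geojson, write_geojson

            gj = cells_to_geojson(
                [CellIndex(int(r.ix), int(r.iy)) for r in statuses.itertuples()], spec
            )
            write_geojson(gj, out / "cells.geojson")
            manifest["outputs"]["cells.geojson"] = {"rows": len(gj["features"])}

        stage = "persistence"
        pers = persistence.persistence_table(gridded, config.model_config())
        _write(pers, out / "persistence.csv", manifest)

        stage = "metrics"
        matrix = metrics.extant_matrix(gridded, pers)
        _write(matrix, out / "extant_matrix.csv", manifest)
        richness = metrics.richness_per_cell(matrix)
        _write(richness, out / "richness.csv", manifest)
        eoo = metrics.eoo_table(matrix, spec)
        _write(eoo, out / "eoo.csv", manifest)

        stage = "glm"
        coef_rows = []
        for realm in sorted(joined["realm"].dropna().unique()):
            try:
                fit = glm.fit_realm_model(joined, realm)
            except ValueError as exc:
                logger.warning("realm %s GLM skipped: %s", realm, exc)
                continue
            frame = fit.summary_frame()
            frame.insert(0, "realm", realm)
            frame["converged"] = fit.converged
            coef_rows.append(frame)
        realm_glm = (
            pd.concat(coef_rows, ignore_index=True)
            if coef_rows
            else pd.DataFrame(columns=["realm", "term", "estimate", "se", "z", "converged"])
        )
        _write(realm_glm, out / "realm_glm.csv", manifest)

        if country_cov is not None:
            country_tab = absence.summarize_by_country(joined, country_cov)
            _write(country_tab, out / "country_table.csv", manifest)
            ranking = glm.rank_country_models(country_tab)
            _write(ranking.to_frame(), out / "country_ranking.csv", manifest)
            best = ranking.best
            manifest["country_best_model"] = {
                "predictors": list(best.predictors),
                "aicc": best.aicc,
                "coefficients": best.fit.coefficients,
                "standard_errors": best.fit.standard_errors,
            }
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
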