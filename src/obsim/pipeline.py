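"""End-to-end orchestration: geography -> drive times -> scenarios -> metrics.

`run` evaluates the baseline (all hospitals) and every requested scenario at
every adjusted target, and emits the machine-readable union of the report
tables: retained sets, coverage curve, Gini curve, reallocation accounting
and per-municipality coverage, plus a provenance-stamped JSON report.  A run
is deterministic given its config and seed; the report JSON carries no
timestamps so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import access as _access
from . import metrics as _metrics
from . import scenarios as _scenarios
from . import synthgeo as _synthgeo
from .errors import ConfigurationError, DataError
from .synthgeo import Geography, SyntheticConfig

__all__ = ["RunConfig", "ScenarioResult", "SimulationReport", "run",
           "compare_scenarios", "load_config"]

logger = logging.getLogger("obsim")

DEFAULT_SCENARIOS = ("S1_volume", "S2_msa_volume", "S3_maxcover_greedy")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulation run.

    Geography comes either from a :class:`SyntheticConfig` (``synthetic``)
    or from a directory of CSV tables (``geography_dir``); exactly one must
    be given.  ``national_targets`` are intended national hospital counts,
    each scaled by ``reporting_fraction`` (round half-up) before use.
    """

    synthetic: SyntheticConfig | None = None
    geography_dir: str | None = None
    scenarios: tuple[str, ...] = DEFAULT_SCENARIOS
    national_targets: tuple[int, ...] = (1000, 800, 600)
    reporting_fraction: float = _metrics.DEFAULT_REPORTING_FRACTION
    threshold_min: float = _access.THRESHOLD_NEAR_MIN
    fixed_designations: tuple[str, ...] = ("general_pmc", "regional_pmc",
                                           "academic")
    exact_mode: str = "auto"
    baseline_only: bool = False
    out_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.geography_dir is None):
            raise ConfigurationError(
                "exactly one of synthetic / geography_dir must be set")
        if not self.baseline_only and not self.scenarios:
            raise ConfigurationError("scenario list must be non-empty")
        for s in self.scenarios:
            if s not in _scenarios.SCENARIO_LABELS:
                raise ConfigurationError(f"unknown scenario {s!r}")
        if any(t < 1 for t in self.national_targets):
            raise ConfigurationError("national targets must be >= 1")
        if not self.national_targets and any(
                s != "FIXED_designation" for s in self.scenarios):
            raise ConfigurationError("targets required for k-based scenarios")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (JSON being a YAML subset works too)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    if "synthetic" in raw and raw["synthetic"] is not None:
        try:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        except TypeError as exc:
            raise ConfigurationError(f"bad synthetic block: {exc}") from exc
    for key in ("scenarios", "national_targets", "fixed_designations"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"bad run config: {exc}") from exc


@dataclass
class ScenarioResult:
    """Everything reported for one (scenario, target) evaluation."""

    scenario: str
    national_target: int | None
    target_k: int
    retained: _scenarios.RetainedSet
    coverage: _metrics.CoverageResult
    gini_value: float
    gini_n: int
    absorption: _metrics.AbsorptionRow

    def summary(self) -> dict:
        return {
            "scenario": self.scenario,
            "national_target": self.national_target,
            "k": self.target_k,
            "retained_n": len(self.retained),
            "covered_pop": self.coverage.covered_pop,
            "total_pop": self.coverage.total_pop,
            "coverage_fraction": self.coverage.fraction,
            "gini": self.gini_value,
            "n_municipalities": self.gini_n,
            "hospitals_absorbed": self.absorption.hospitals_absorbed,
            "births_absorbed": self.absorption.births_absorbed,
            "obstetricians_closed": self.absorption.obstetricians_closed,
            "midwives_closed": self.absorption.midwives_closed,
            "births_per_hospital_after":
                self.absorption.births_per_hospital_after,
            "obstetricians_per_hospital_after":
                self.absorption.obstetricians_per_hospital_after,
            "midwives_per_hospital_after":
                self.absorption.midwives_per_hospital_after,
            "retained_ids": list(self.retained.hospital_ids),
        }


@dataclass
class SimulationReport:
    baseline: ScenarioResult
    rows: list[ScenarioResult]
    provenance: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance,
                "baseline": self.baseline.summary(),
                "rows": [r.summary() for r in self.rows]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _evaluate(geo: Geography, matrix: _access.AccessMatrix,
              retained: _scenarios.RetainedSet, threshold: float,
              scenario: str, national_target: int | None) -> ScenarioResult:
    acc = _access.classify_access(matrix, retained, near_min=threshold)
    cov = _metrics.population_coverage(acc, geo.cells, threshold)
    fracs = cov.per_municipality["fraction"].dropna().to_numpy()
    if len(fracs) == 0 or float(fracs.sum()) == 0.0:
        gini_value, gini_n = float("nan"), len(fracs)
        logger.warning("%s k=%d: all-zero municipality coverage, Gini "
                       "undefined", scenario, retained.target_k)
    else:
        g = _metrics.gini(fracs)
        gini_value, gini_n = g.value, g.n_units
    absorption = _metrics.reallocation_accounting(geo.hospitals, retained)
    return ScenarioResult(scenario=scenario, national_target=national_target,
                          target_k=retained.target_k, retained=retained,
                          coverage=cov, gini_value=gini_value, gini_n=gini_n,
                          absorption=absorption)


def _select(scenario: str, geo: Geography, cov_sets, k: int,
            config: RunConfig) -> _scenarios.RetainedSet:
    if scenario == "S1_volume":
        return _scenarios.scenario_volume(geo.hospitals, k)
    if scenario == "S2_msa_volume":
        return _scenarios.scenario_msa_volume(geo.hospitals, k)
    if scenario == "S3_maxcover_greedy":
        return _scenarios.scenario_maxcover_greedy(cov_sets, k)
    if scenario == "S3_maxcover_exact":
        return _scenarios.scenario_maxcover_exact(cov_sets, k,
                                                  mode=config.exact_mode)
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def run(config: RunConfig) -> SimulationReport:
    """Execute the full simulation described by ``config``.

    Deterministic for a fixed config and seed; raises with the failing
    stage recorded as an exception note.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    t0 = time.perf_counter()

    stage = "geography"
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            if config.seed is not None:
                syn = dataclasses.replace(syn, seed=config.seed)
            geo = _synthgeo.generate_geography(syn)
        else:
            geo = _synthgeo.read_geography(config.geography_dir)
        logger.info("geography: %d cells, %d hospitals, %d nodes (%.1fs)",
                    len(geo.cells), len(geo.hospitals), geo.network.n_nodes,
                    time.perf_counter() - t0)

        stage = "access"
        matrix = _access.travel_time_matrix(geo)
        logger.info("access: %dx%d drive-time matrix (%.1fs)",
                    *matrix.minutes.shape, time.perf_counter() - t0)

        stage = "scenarios"
        cov_sets = _scenarios.build_coverage_sets(matrix, geo.cells,
                                                  config.threshold_min)
        n = len(geo.hospitals)
        baseline_set = _scenarios.RetainedSet(
            "BASELINE", n, tuple(geo.hospitals.sort_values("id")["id"]))

        stage = "metrics"
        baseline = _evaluate(geo, matrix, baseline_set, config.threshold_min,
                             "BASELINE", None)
        rows: list[ScenarioResult] = []
        if not config.baseline_only:
            adjusted = [(t, _metrics.adjust_target(t, config.reporting_fraction))
                        for t in config.national_targets]
            for scenario in config.scenarios:
                if scenario == "FIXED_designation":
                    retained = _scenarios.scenario_fixed(
                        geo.hospitals, config.fixed_designations)
                    rows.append(_evaluate(geo, matrix, retained,
                                          config.threshold_min, scenario, None))
                    continue
                for nat, k in adjusted:
                    retained = _select(scenario, geo, cov_sets, k, config)
                    rows.append(_evaluate(geo, matrix, retained,
                                          config.threshold_min, scenario, nat))
    except Exception as exc:
        if hasattr(exc, "add_note"):
            exc.add_note(f"pipeline stage: {stage}")
        raise

    report = SimulationReport(baseline=baseline, rows=rows,
                              provenance=_provenance(config))
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    logger.info("run complete: %d scenario rows (%.1fs)", len(rows),
                time.perf_counter() - t0)
    return report


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    return {"config": cfg, "config_sha256": digest,
            "seed": config.seed, "software_version": __version__}


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report(report: SimulationReport, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_rows = [report.baseline] + report.rows

    retained = pd.DataFrame(
        [(r.scenario, r.target_k, rank + 1, hid)
         for r in all_rows
         for rank, hid in enumerate(r.retained.hospital_ids)],
        columns=["scenario", "target_k", "rank", "hospital_id"])
    coverage = pd.DataFrame(
        [(r.scenario, r.national_target, r.target_k, r.coverage.covered_pop,
          r.coverage.total_pop, r.coverage.fraction) for r in all_rows],
        columns=["scenario", "national_target", "k", "covered_pop",
                 "total_pop", "fraction"])
    gini_curve = pd.DataFrame(
        [(r.scenario, r.national_target, r.target_k, r.gini_value, r.gini_n)
         for r in all_rows],
        columns=["scenario", "national_target", "k", "gini",
                 "n_municipalities"])
    absorption = pd.DataFrame([
        {"scenario": r.scenario, "national_target": r.national_target,
         "k": r.target_k, **{f: getattr(r.absorption, f) for f in (
             "retained_n", "hospitals_absorbed", "births_absorbed",
             "obstetricians_closed", "midwives_closed",
             "births_per_hospital_after", "obstetricians_per_hospital_after",
             "midwives_per_hospital_after")}}
        for r in all_rows])
    muni = pd.concat(
        [r.coverage.per_municipality.assign(scenario=r.scenario,
                                            k=r.target_k)
         for r in all_rows], ignore_index=True)[
        ["scenario", "k", "municipality_id", "covered", "total", "fraction"]]

    paths = {}
    for name, frame in (("retained.csv", retained),
                        ("coverage_curve.csv", coverage),
                        ("gini_curve.csv", gini_curve),
                        ("absorption.csv", absorption),
                        ("municipality_coverage.csv", muni)):
        path = out / name
        frame.to_csv(path, index=False)
        paths[name] = path
    report_path = out / "report.json"
    report_path.write_text(report.to_json())
    paths["report.json"] = report_path
    return paths


def compare_scenarios(report: SimulationReport) -> pd.DataFrame:
    """Rank scenarios by coverage at each shared target size.

    Exact max-cover, when present, is listed first at its k (it is optimal
    by construction); everything else sorts by descending coverage.
    Requires at least two scenarios evaluated at a common k.
    """
    frame = pd.DataFrame(
        [(r.scenario, r.target_k, r.coverage.fraction) for r in report.rows],
        columns=["scenario", "k", "fraction"])
    shared = frame.groupby("k")["scenario"].nunique()
    valid_k = shared[shared >= 2].index
    if len(valid_k) == 0:
        raise DataError("no target size shared by two or more scenarios")
    frame = frame[frame["k"].isin(valid_k)].copy()
    frame["_exact"] = (frame["scenario"] == "S3_maxcover_exact").astype(int)
    frame = (frame.sort_values(["k", "_exact", "fraction", "scenario"],
                               ascending=[True, False, False, True])
             .drop(columns="_exact").reset_index(drop=True))
    frame["rank"] = frame.groupby("k").cumcount() + 1
    return frame


def plot_curves(report: SimulationReport, out_dir: str | Path) -> list[Path]:
    """Optional convenience plots of the coverage and Gini curves; the CSVs
    remain the contract."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for attr, name, ylabel in (("coverage", "coverage_curve.png",
                                "population coverage"),
                               ("gini", "gini_curve.png",
                                "Gini coefficient")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for scenario in sorted({r.scenario for r in report.rows}):
            pts = sorted((r.target_k,
                          r.coverage.fraction if attr == "coverage"
                          else r.gini_value)
                         for r in report.rows if r.scenario == scenario)
            ax.plot([p[0] for p in pts], [p[1] for p in pts],
                    marker="o", label=scenario)
        ax.set_xlabel("retained hospitals (k)")
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / name
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
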