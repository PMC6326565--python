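"""Monte Carlo orchestration of the dose-scheme comparison study.

Runs replicated trials for every scenario of the grid (truth shape x
true MTD x sample size x dose scheme x design), summarizes each
scenario's operating characteristics, and aggregates metrics across the
16 truth scenarios (4 shapes x 4 MTDs) per (design, scheme, n) cell as
median and 25th/75th percentiles.

Replicate random streams are derived counter-style from
(base seed, scenario index, replicate index), so results are invariant
to execution order and to the replicate counts of other scenarios.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .designs import FeasibilitySchedule, TrialResult, get_scheme, run_trial
from .model import ModelSpace, PriorSpec
from .oc import (
    DEFAULT_DLT_BAND,
    DEFAULT_MTD_DELTA,
    DEFAULT_TOX_BAND,
    OCSummary,
    optimal_mtd_interval,
    optimal_mtd_table,
    optimal_toxicity_interval,
    optimal_toxicity_table,
    summarize_trials,
)
from .truth import ScenarioSpec, study_grid
from . import truth as _truth_mod

__all__ = ["StudyConfig", "StudyReport", "run_scenario", "run_study", "aggregate"]

_METRICS = (
    "bias",
    "abs_bias",
    "rmse",
    "mean_dlt_rate",
    "pct_trials_dlt_in_band",
    "pct_trials_mtd_in_mtd_interval",
    "pct_trials_mtd_in_tox_interval",
    "pct_patients_in_mtd_interval",
    "pct_patients_in_tox_interval",
)


@dataclass
class StudyConfig:
    """Configuration of one study run (defaults mirror the full study)."""

    designs: Sequence[str] = ("crm", "ewoc")
    shapes: Sequence[tuple[str, float]] = _truth_mod.STUDY_SHAPES
    mtds: Sequence[float] = _truth_mod.STUDY_MTDS
    sample_sizes: Sequence[int] = _truth_mod.STUDY_SAMPLE_SIZES
    scheme_names: Sequence[str] = _truth_mod.STUDY_SCHEME_NAMES
    replicates: int = 1000
    base_seed: int = 0
    resolution: tuple[int, int] = (201, 201)
    theta: float = 0.33
    rho0_true_by_shape: Mapping[str, float] | None = None
    alpha_init: float = 0.05
    alpha_increment: float = 0.05
    alpha_cap: float = 0.5
    alpha_conditional: bool = True
    rounding: str = "nearest"
    no_skip: bool = True
    estimator: str = "mean"
    mtd_delta: float = DEFAULT_MTD_DELTA
    tox_band: float = DEFAULT_TOX_BAND
    dlt_band: float = DEFAULT_DLT_BAND
    n_jobs: int = 1

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "shapes" in d:
            d["shapes"] = tuple((s, float(l)) for s, l in d["shapes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def space(self) -> ModelSpace:
        return ModelSpace(theta=self.theta)

    def schedule(self) -> FeasibilitySchedule:
        return FeasibilitySchedule(
            alpha_init=self.alpha_init,
            increment=self.alpha_increment,
            cap=self.alpha_cap,
            conditional=self.alpha_conditional,
        )

    def scenarios(self) -> list[ScenarioSpec]:
        return study_grid(
            designs=tuple(self.designs),
            shapes=tuple(self.shapes),
            mtds=tuple(self.mtds),
            sample_sizes=tuple(self.sample_sizes),
            scheme_names=tuple(self.scheme_names),
            replicates=self.replicates,
            base_seed=self.base_seed,
            rho0_true_by_shape=dict(self.rho0_true_by_shape or {}),
        )


@dataclass
class StudyReport:
    """Per-scenario summary rows plus cross-scenario aggregates."""

    summaries: pd.DataFrame
    aggregates: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "oc_summary.csv", index=False)
        self.aggregates.to_csv(out / "aggregates.csv", index=False)
        optimal_mtd_table().to_csv(out / "table1.csv", index=False)
        optimal_toxicity_table().to_csv(out / "table2.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _replicate_rng(base_seed: int, scenario_index: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([base_seed, scenario_index, replicate])
    )


def run_scenario(
    spec: ScenarioSpec, config: StudyConfig, keep_results: bool = False
) -> tuple[dict, list[TrialResult]]:
    """Run all replicates of one scenario and summarize."""
    space = config.space()
    truth = spec.truth(space)
    scheme = get_scheme(spec.scheme_name)
    if scheme.mode == "discrete":
        scheme = type(scheme)(
            mode=scheme.mode,
            doses=scheme.doses,
            rounding=config.rounding,
            no_skip=config.no_skip,
        )
    prior = PriorSpec()
    schedule = config.schedule()
    results = []
    for rep in range(spec.replicates):
        rng = _replicate_rng(config.base_seed, spec.index, rep)
        results.append(
            run_trial(
                spec.design,
                truth,
                scheme,
                spec.n,
                rng,
                schedule=schedule,
                prior=prior,
                space=space,
                resolution=config.resolution,
                estimator=config.estimator,
            )
        )
    intervals = {
        "mtd": optimal_mtd_interval(spec.gamma_true, config.mtd_delta),
        "tox": optimal_toxicity_interval(truth, config.tox_band),
    }
    summary = summarize_trials(results, truth, intervals, dlt_band=config.dlt_band)
    row = _summary_row(spec, summary)
    return row, (results if keep_results else [])


def _summary_row(spec: ScenarioSpec, s: OCSummary) -> dict:
    return {
        "scenario_id": spec.scenario_id,
        "design": spec.design,
        "shape": spec.shape,
        "slant": spec.slant,
        "true_mtd": spec.gamma_true,
        "rho0_true": spec.rho0_true,
        "n": spec.n,
        "scheme": spec.scheme_name,
        "replicates": s.replicates,
        "bias": s.bias,
        "abs_bias": abs(s.bias),
        "rmse": s.rmse,
        "mean_dlt_rate": s.mean_dlt_rate,
        "pct_trials_dlt_in_band": s.pct_trials_dlt_in_band,
        "pct_trials_mtd_in_mtd_interval": s.pct_trials_mtd_in_interval["mtd"],
        "pct_trials_mtd_in_tox_interval": s.pct_trials_mtd_in_interval["tox"],
        "pct_patients_in_mtd_interval": s.pct_patients_optimal["mtd"],
        "pct_patients_in_tox_interval": s.pct_patients_optimal["tox"],
    }


def run_study(config: StudyConfig, progress: bool = False) -> StudyReport:
    """Run every scenario of the configured grid and aggregate."""
    specs = config.scenarios()
    rows = []
    if config.n_jobs > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=config.n_jobs)(
            delayed(run_scenario)(spec, config) for spec in specs
        )
        rows = [r for r, _ in rows]
    else:
        for i, spec in enumerate(specs):
            if progress:
                print(f"[{i + 1}/{len(specs)}] {spec.scenario_id}", flush=True)
            row, _ = run_scenario(spec, config)
            rows.append(row)
    summaries = pd.DataFrame(rows)
    aggregates = aggregate(summaries)
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_scenarios": len(specs),
        "scenario_seeds": {s.scenario_id: s.seed for s in specs},
    }
    return StudyReport(summaries=summaries, aggregates=aggregates, manifest=manifest)


def aggregate(
    summaries: pd.DataFrame,
    group_keys: Sequence[str] = ("design", "scheme", "n"),
    metrics: Sequence[str] = _METRICS,
    expected_group_size: int | None = 16,
) -> pd.DataFrame:
    """Median and 25th/75th percentiles of each metric per group.

    The canonical grouping pools the 16 truth scenarios (4 shapes x
    4 MTDs) per (design, scheme, n) cell.  Quantiles use linear
    interpolation between order statistics.
    """
    metrics = [m for m in metrics if m in summaries.columns]
    rows = []
    for keys, grp in summaries.groupby(list(group_keys), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_keys, keys))
        row["n_scenarios"] = len(grp)
        if expected_group_size is not None and len(grp) != expected_group_size:
            row["incomplete"] = True
        for m in metrics:
            v = grp[m].to_numpy(dtype=float)
            row[f"{m}_q25"] = float(np.percentile(v, 25))
            row[f"{m}_median"] = float(np.percentile(v, 50))
            row[f"{m}_q75"] = float(np.percentile(v, 75))
        rows.append(row)
    return pd.DataFrame(rows)
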