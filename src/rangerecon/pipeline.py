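"""End-to-end orchestration: synthetic scenario → prep → per-period SDM →
niche overlap → range table → prioritization.

`run_scenario` is the single entry point the CLI and the simulation
studies use; each stage is also callable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import niche as niche_mod
from . import prep, report, sdm, synth
from .types import ENV_VARS, OccurrenceSet, PseudoAbsenceSet, ScenarioConfig

logger = logging.getLogger(__name__)

__all__ = ["RunSettings", "ScenarioResult", "run_scenario"]


@dataclass(frozen=True)
class RunSettings:
    """Pipeline-wide knobs; `fast()` gives desk-scale simulation settings."""

    sdm: sdm.SDMSettings = field(default_factory=sdm.SDMSettings)
    buffer_km: float = 15.0
    n_pseudo_absences: int = 10_000
    vif_threshold: float = 10.0
    home_range_ha: float = 6.97
    niche_resolution: int = 100
    niche_subsamples: int = 100
    run_niche: bool = True
    run_priority: bool = True

    @classmethod
    def fast(cls, **kw) -> "RunSettings":
        return cls(sdm=sdm.SDMSettings.fast(), n_pseudo_absences=2000,
                   niche_resolution=60, niche_subsamples=50, **kw)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    scenario: synth.Scenario
    thinned: list[OccurrenceSet]
    pseudo_absences: list[PseudoAbsenceSet]
    selections: list[prep.PredictorSelection]
    range_results: list[sdm.RangeResult]
    table: report.RangeChangeTable
    overlap_tests: list[niche_mod.OverlapTest] | None = None
    rank: np.ndarray | None = None
    zones: np.ndarray | None = None

    def fit_record_frame(self) -> pd.DataFrame:
        rows = [{"period": r.period, "technique": f.technique, "run": f.run_index,
                 "tss": f.tss, "threshold": f.threshold_at_max_tss}
                for r in self.range_results for f in r.fit_records]
        return pd.DataFrame(rows)


def prepare_period(scenario: synth.Scenario, t: int, settings: RunSettings,
                   seed: int):
    """Thin occurrences, draw pseudo-absences and select predictors for
    period index t. Returns (thinned, pseudo_absences, selection)."""
    config = scenario.config
    occ = scenario.occurrences[t]
    thinned = prep.thin_occurrences(occ.points, settings.home_range_ha,
                                    config.grid.cell_size, period=occ.period,
                                    spec=config.grid)
    pa = prep.sample_pseudo_absences(
        scenario.roads, config.grid, presences=thinned,
        buffer_km=settings.buffer_km, n=settings.n_pseudo_absences,
        seed=np.random.SeedSequence(entropy=(seed, 1000 + t)), period=occ.period)
    stack = scenario.stacks[t]
    X = np.vstack([
        stack.extract(thinned.x, thinned.y, ENV_VARS),
        stack.extract(pa.points[:, 0], pa.points[:, 1], ENV_VARS),
    ])
    selection = prep.vif_select(X, threshold=settings.vif_threshold,
                                feature_names=list(ENV_VARS))
    return thinned, pa, selection


def run_scenario(config: ScenarioConfig, settings: RunSettings | None = None,
                 seed: int | None = None) -> ScenarioResult:
    """Run the full reconstruction on a synthetic scenario."""
    settings = settings or RunSettings()
    seed = config.seed if seed is None else seed
    scenario = synth.simulate_scenario(config)

    thinned, pas, selections, results = [], [], [], []
    for t, period in enumerate(config.periods):
        th, pa, sel = prepare_period(scenario, t, settings, seed)
        logger.info("period=%s occurrences=%d->%d pseudo_absences=%d retained=%s",
                    period, len(scenario.occurrences[t]), len(th), len(pa),
                    sel.retained)
        res = sdm.run_period(th, pa, scenario.stacks[t], sel,
                             settings=settings.sdm,
                             seed=np.random.SeedSequence(entropy=(seed, 2000 + t)))
        thinned.append(th)
        pas.append(pa)
        selections.append(sel)
        results.append(res)

    table = report.build_table([r.period for r in results],
                               [r.range_km2 for r in results],
                               study_area_km2=config.grid.total_area_km2)

    overlap = None
    if settings.run_niche:
        overlap = _niche_stage(scenario, thinned, selections, settings, seed)

    rank = zones = None
    if settings.run_priority:
        rank, zones = _priority_stage(scenario, results, settings)

    return ScenarioResult(config=config, scenario=scenario, thinned=thinned,
                          pseudo_absences=pas, selections=selections,
                          range_results=results, table=table,
                          overlap_tests=overlap, rank=rank, zones=zones)


def _niche_stage(scenario, thinned, selections, settings, seed):
    """PCA-env calibrated on all periods' availability; per-period
    partial-vs-total overlap tests."""
    variables = [v for v in ENV_VARS
                 if all(v in sel.retained for sel in selections)]
    if len(variables) < 2:
        variables = list(ENV_VARS)
    space = niche_mod.fit_env_space(scenario.stacks, variables)
    env_scores = np.vstack([space.transform(s.table(variables))
                            for s in scenario.stacks])
    occ_scores = []
    for t, th in enumerate(thinned):
        X = scenario.stacks[t].extract(th.x, th.y, variables)
        occ_scores.append(space.transform(X))
    pool = np.vstack(occ_scores)
    bounds = niche_mod.scores_bounds(env_scores)
    tests = []
    for t, th in enumerate(thinned):
        tests.append(niche_mod.partial_vs_total_test(
            pool, occ_scores[t], env_scores, B=settings.niche_subsamples,
            seed=np.random.SeedSequence(entropy=(seed, 3000 + t)),
            R=settings.niche_resolution, period=th.period, bounds=bounds))
    return tests


def _priority_stage(scenario, results, settings):
    """Zonation on the last period's consensus probability, conditioned on
    last-period land cover, with the disappearance cost layer."""
    from . import priority

    last = scenario.stacks[-1]
    feature = np.nan_to_num(results[-1].probability, nan=0.0)
    conditioned = priority.apply_conditions(feature, urban=last["urban"],
                                            forest=last["forest"])
    _, cost = priority.build_cost([r.binary for r in results])
    rank = priority.core_area_rank([conditioned], cost)
    zones = priority.reclassify(rank)
    return rank, zones
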