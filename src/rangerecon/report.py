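"""Range-change accounting and the climate-vs-human counterfactual.

All percentages are recomputed from the stored per-period ranges at
render time — reductions are never cached — and rounded to two decimals
only for presentation; machine outputs keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CLIMATE_VARS, HUMAN_VARS, STATIC_VARS, EnvStack

__all__ = [
    "DEFAULT_STUDY_AREA_KM2",
    "range_change",
    "RangeChangeTable",
    "build_table",
    "zone_area",
    "mean_consensus_tss",
    "CounterfactualSpec",
    "hybrid_stack",
    "counterfactual_range",
]

#: study-area extent used for the published accounting (km²)
DEFAULT_STUDY_AREA_KM2 = 512_684.0


def range_change(range_a: float, range_b: float) -> float:
    """Percent reduction from range_a to range_b: 100·(1 − b/a), two
    decimals. Negative values mean expansion."""
    if range_a <= 0:
        raise ValueError("baseline range must be positive")
    return round(100.0 * (1.0 - range_b / range_a), 2)


@dataclass
class RangeChangeTable:
    """Per-period range accounting in the style of a published range table."""

    periods: list[str]
    ranges_km2: list[float]
    study_area_km2: float = DEFAULT_STUDY_AREA_KM2

    @property
    def percent_of_study_area(self) -> list[float]:
        return [round(100.0 * r / self.study_area_km2, 2) for r in self.ranges_km2]

    @property
    def percent_reduction_vs_baseline(self) -> list[float]:
        base = self.ranges_km2[0]
        return [range_change(base, r) for r in self.ranges_km2]

    @property
    def inter_period_reduction(self) -> list[float]:
        """Reduction of each period relative to the one before (first is 0)."""
        return [0.0] + [range_change(a, b)
                        for a, b in zip(self.ranges_km2, self.ranges_km2[1:])]

    @property
    def mean_decadal_reduction(self) -> float:
        """Arithmetic mean of the consecutive inter-period reductions.

        Note this is a simple mean of percentages with differing baselines,
        not a compound rate — it matches how decadal decline is customarily
        reported.
        """
        steps = self.inter_period_reduction[1:]
        return round(float(np.mean(steps)), 2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "period": self.periods,
            "range_km2": self.ranges_km2,
            "percent_of_study_area": self.percent_of_study_area,
            "reduction_vs_baseline_pct": self.percent_reduction_vs_baseline,
            "inter_period_reduction_pct": self.inter_period_reduction,
        })


def build_table(periods: list[str], ranges_km2: list[float],
                study_area_km2: float = DEFAULT_STUDY_AREA_KM2) -> RangeChangeTable:
    """Assemble the range-change table from per-period range sizes."""
    if len(periods) < 2 or len(periods) != len(ranges_km2):
        raise ValueError("need matched periods and ranges, at least two periods")
    return RangeChangeTable(periods=list(periods), ranges_km2=list(map(float, ranges_km2)),
                            study_area_km2=study_area_km2)


def zone_area(fraction: float, study_area_km2: float = DEFAULT_STUDY_AREA_KM2) -> float:
    """Area of a top-fraction priority zone, to one decimal (km²)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return round(fraction * study_area_km2, 1)


def mean_consensus_tss(per_period_tss) -> float:
    """Arithmetic mean of per-period consensus TSS values, two decimals."""
    vals = np.asarray(list(per_period_tss), dtype=float)
    if vals.size == 0:
        raise ValueError("no TSS values supplied")
    return round(float(vals.mean()), 2)


@dataclass(frozen=True)
class CounterfactualSpec:
    """Which period supplies which ingredient of a hybrid projection.

    The model is trained on ``occurrence_period`` occurrences over a stack
    whose human-influence layers come from ``human_period``, then projected
    onto climate from ``climate_period`` + human layers from
    ``human_period``. Holding human pressure at an early decade while
    advancing the climate isolates the climatic contribution to range
    change.
    """

    occurrence_period: str
    climate_period: str
    human_period: str


def hybrid_stack(stacks: dict[str, EnvStack], climate_period: str,
                 human_period: str, label: str | None = None) -> EnvStack:
    """Stack with climate layers from one period and human-influence layers
    from another (topography is period-invariant)."""
    for p in (climate_period, human_period):
        if p not in stacks:
            raise KeyError(f"no stack for period {p!r}")
    clim = stacks[climate_period]
    hum = stacks[human_period]
    layers = {}
    for v in CLIMATE_VARS:
        layers[v] = clim[v]
    for v in STATIC_VARS:
        layers[v] = clim[v]
    for v in HUMAN_VARS:
        layers[v] = hum[v]
    return EnvStack(period=label or f"clim:{climate_period}+hum:{human_period}",
                    layers=layers, spec=clim.spec, mask=clim.mask & hum.mask)


def counterfactual_range(spec: CounterfactualSpec, stacks: dict[str, EnvStack],
                         occurrences, pseudo_absences, selection,
                         settings=None, seed=0) -> float:
    """Range (km²) under a hybrid climate/human assumption.

    With all three periods equal this reduces to the standard per-period
    pipeline. ``occurrences``/``pseudo_absences`` map period → point sets.
    """
    from .sdm import SDMSettings, run_period

    if settings is None:
        settings = SDMSettings()
    train = hybrid_stack(stacks, climate_period=spec.occurrence_period,
                         human_period=spec.human_period,
                         label=spec.occurrence_period)
    target = hybrid_stack(stacks, climate_period=spec.climate_period,
                          human_period=spec.human_period)
    result = run_period(occurrences[spec.occurrence_period],
                        pseudo_absences[spec.occurrence_period],
                        train, selection, settings=settings, seed=seed,
                        projection_stack=target)
    return result.range_km2
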