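"""Core-area conservation prioritization.

Produces a complementarity-based priority ranking of the landscape by
iteratively removing the cell whose loss least reduces the remaining
value of the worst-off feature, divided by the cell's cost:

    δ_i = max_j  w_j · q_ij / c_i,   q_ij = p'_ij / Σ_remaining p'_ij

(the exact core-area removal rule, no speed-up heuristics). Cells removed
early get low rank, the last cell rank 1. Feature layers are first
degraded by habitat-condition multipliers, and the cost layer encodes how
long ago the species disappeared from each cell — the longer absent, the
costlier the recovery, the lower the cell's priority.

The ranked surface is reclassified into Mandatory / Negotiated / Partial
Reserve zones and summarised over polygons (reserves, prefectures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from sklearn.base import BaseEstimator

from .types import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "build_cost",
    "apply_conditions",
    "CoreAreaZonation",
    "core_area_rank",
    "ZONE_LABELS",
    "reclassify",
    "polygon_summary",
]

_EPS = 1e-300


def build_cost(binary_ranges: list[np.ndarray], transform: str = "one_plus",
               zero_means_present_last: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Disappearance-index and cost grids from per-period presence rasters.

    The disappearance index d counts the trailing run of periods (ending at
    the most recent) in which a cell is absent, divided by P − 1 and clamped
    to [0, 1]: still present in the last period → 0; absent throughout →
    1. With four periods d ∈ {0, 1/3, 2/3, 1}. The default polarity (0 =
    still present) can be flipped for users reading the index the other way.

    transform: ``"one_plus"`` → c = 1 + d (bounded, strictly positive);
    ``"epsilon"`` → c = 0.05 + d (stronger cost effect).

    Returns (disappearance_index, cost).
    """
    if len(binary_ranges) < 2:
        raise ValueError("need at least two periods to build the cost layer")
    shapes = {b.shape for b in binary_ranges}
    if len(shapes) != 1:
        raise ValueError(f"period rasters are not co-registered: shapes {shapes}")
    stack = np.stack([np.asarray(b, dtype=bool) for b in binary_ranges])
    P = len(binary_ranges)
    trailing = np.zeros(stack.shape[1:], dtype=float)
    alive = np.ones(stack.shape[1:], dtype=bool)  # run still unbroken, scanning backwards
    for t in range(P - 1, -1, -1):
        absent = ~stack[t]
        trailing += (alive & absent)
        alive &= absent
    d = np.clip(trailing / (P - 1), 0.0, 1.0)
    if not zero_means_present_last:
        d = 1.0 - d
    if transform == "one_plus":
        cost = 1.0 + d
    elif transform == "epsilon":
        cost = 0.05 + d
    else:
        raise ValueError(f"unknown cost transform {transform!r}")
    return d, cost


def apply_conditions(feature: np.ndarray, urban: np.ndarray,
                     forest: np.ndarray, vegetation: np.ndarray | None = None) -> np.ndarray:
    """Degrade a feature by habitat condition: p' = p·(1−urban)·forest·veg.

    Urban cover enters inverted — it is a pressure, so high urban lowers
    value; forest and vegetation are quality multipliers in [0, 1].
    """
    feature = np.asarray(feature, dtype=float)
    conds = {"urban": np.asarray(urban, float), "forest": np.asarray(forest, float)}
    if vegetation is not None:
        conds["vegetation"] = np.asarray(vegetation, float)
    out = feature.copy()
    for name, c in conds.items():
        if c.shape != feature.shape:
            raise ValueError(f"condition layer {name!r} is not co-registered")
        finite = np.isfinite(c)
        if np.any((c[finite] < 0) | (c[finite] > 1)):
            raise ValueError(f"condition layer {name!r} has values outside [0, 1]")
    out *= (1.0 - conds["urban"])
    out *= conds["forest"]
    if vegetation is not None:
        out *= conds["vegetation"]
    return out


class CoreAreaZonation(BaseEstimator):
    """Exact core-area removal ranking.

    Parameters
    ----------
    weights : sequence of float or None
        One positive weight per feature (default: all 1).

    Attributes
    ----------
    rank_ : 2-D grid in (0, 1] over valid cells (NaN elsewhere); the cell
        removed at position i of N gets rank i/N, so the last-removed
        (most irreplaceable) cell has rank exactly 1.
    removal_order_ : flat indices of valid cells in removal order.
    """

    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, features: list[np.ndarray] | np.ndarray, cost: np.ndarray | None = None):
        if isinstance(features, np.ndarray) and features.ndim == 2:
            features = [features]
        shape = features[0].shape
        F = len(features)
        w = np.ones(F) if self.weights is None else np.asarray(self.weights, float)
        if len(w) != F or np.any(w <= 0):
            raise ValueError("need one positive weight per feature")
        if cost is None:
            cost = np.ones(shape)
        cost = np.asarray(cost, dtype=float)
        if cost.shape != shape:
            raise ValueError("cost grid is not co-registered with the features")

        P = np.stack([np.asarray(f, dtype=float).ravel() for f in features])
        c = cost.ravel()
        valid = np.all(np.isfinite(P), axis=0) & np.isfinite(c)
        if np.any(c[valid] <= 0):
            raise ValueError("cost must be strictly positive on valid cells")
        if np.any(P[:, valid] < 0):
            raise ValueError("feature values must be non-negative")
        idx = np.nonzero(valid)[0]
        N = len(idx)
        if N == 0:
            raise ValueError("no valid cells")

        p = P[:, idx]          # (F, N)
        cc = c[idx]
        pmax = (w[:, None] * p).max(axis=0)  # tie-break key: lower weighted value first

        order = np.empty(N, dtype=int)
        if p.sum() == 0:
            logger.warning("all features are zero after conditioning; "
                           "ranking by cost alone")
            # high cost → low priority → removed first; ties row-major
            order[:] = np.lexsort((idx, -cc))
        else:
            denom = p.sum(axis=1)  # per-feature remaining totals
            remaining = np.ones(N, dtype=bool)
            big = np.inf
            for step in range(N):
                q = np.where(denom[:, None] > _EPS, p / np.maximum(denom[:, None], _EPS), 0.0)
                delta = (w[:, None] * q).max(axis=0) / cc
                delta = np.where(remaining, delta, big)
                m = delta.min()
                cand = np.nonzero(delta == m)[0]
                if len(cand) > 1:
                    # lower conditioned value first, then row-major index
                    key = np.lexsort((idx[cand], pmax[cand]))
                    pick = cand[key[0]]
                else:
                    pick = cand[0]
                order[step] = pick
                remaining[pick] = False
                denom -= p[:, pick]
        self.removal_order_ = idx[order]
        rank_flat = np.full(c.shape, np.nan)
        rank_flat[idx[order]] = np.arange(1, N + 1) / N
        self.rank_ = rank_flat.reshape(shape)
        self.n_valid_ = N
        return self


def core_area_rank(features, cost=None, weights=None) -> np.ndarray:
    """Functional wrapper over :class:`CoreAreaZonation`; returns the rank grid."""
    return CoreAreaZonation(weights=weights).fit(features, cost).rank_


ZONE_LABELS = {3: "Mandatory", 2: "Negotiated", 1: "Partial", 0: "Other"}

# half-open zone intervals (lower, upper]: the published 0.89-0.90 gap is
# closed by carrying Partial Reserve up to 0.90
_ZONE_BOUNDS = (0.80, 0.90, 0.95)


def reclassify(rank: np.ndarray,
               bounds: tuple[float, float, float] = _ZONE_BOUNDS) -> np.ndarray:
    """Zone codes from the rank surface: Mandatory (> 0.95), Negotiated
    (0.90, 0.95], Partial (0.80, 0.90], Other (≤ 0.80); NaN cells get −1."""
    rank = np.asarray(rank, dtype=float)
    lo, mid, hi = bounds
    zones = np.full(rank.shape, -1, dtype=int)
    ok = np.isfinite(rank)
    zones[ok & (rank > hi)] = 3
    zones[ok & (rank > mid) & (rank <= hi)] = 2
    zones[ok & (rank > lo) & (rank <= mid)] = 1
    zones[ok & (rank <= lo)] = 0
    return zones


@dataclass
class PolygonSummary:
    polygon_id: int
    mean_rank: float
    fraction_priority: float
    share_of_priority_area: float
    level: str
    n_cells: int


def polygon_summary(rank: np.ndarray, spec: GridSpec, polygons: list[Polygon],
                    top_fraction: float = 0.10,
                    level_thresholds: tuple[float, float] = (0.90, 0.80)) -> pd.DataFrame:
    """Per-polygon priority statistics.

    For each polygon (reserve or prefecture): the mean rank over covered
    cells, the fraction of its cells inside the top-``top_fraction``
    priority area (rank > 1 − top_fraction), its share of the total
    priority-area cells, and a level — ``priority`` if mean rank ≥ the
    first threshold, ``important`` if ≥ the second, else ``normal``.
    Polygons covering no valid cell are excluded with a log entry.
    """
    if not polygons:
        raise ValueError("empty polygon set")
    rank = np.asarray(rank, dtype=float)
    xs, ys = spec.cell_centers()
    pts_x, pts_y = xs.ravel(), ys.ravel()
    flat = rank.ravel()
    cutoff = 1.0 - top_fraction
    total_priority = np.sum(flat > cutoff)
    rows = []
    for pid, poly in enumerate(polygons):
        inside = shapely.contains_xy(poly, pts_x, pts_y)
        vals = flat[inside]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.info("polygon %d covers no valid cells; excluded", pid)
            continue
        n_priority = int(np.sum(vals > cutoff))
        mean_rank = float(vals.mean())
        hi, lo = level_thresholds
        level = "priority" if mean_rank >= hi else ("important" if mean_rank >= lo else "normal")
        rows.append(PolygonSummary(
            polygon_id=pid, mean_rank=mean_rank,
            fraction_priority=n_priority / vals.size,
            share_of_priority_area=(n_priority / total_priority if total_priority else 0.0),
            level=level, n_cells=int(vals.size)))
    return pd.DataFrame([r.__dict__ for r in rows])
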