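"""Occurrence thinning, road-buffer pseudo-absence sampling and
collinearity-based predictor selection.

Historical occurrence records cluster around well-surveyed places, so they
are thinned to at most one record per home range (and per raster cell)
before modelling. Because record collection followed the transport network,
background (pseudo-absence) points are drawn only from a buffer around
roads, which keeps the sampling bias of presences and absences comparable.
Predictors are screened for collinearity by stepwise elimination on the
variance inflation factor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import shapely
from shapely.geometry import LineString
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .types import GridSpec, OccurrenceSet, PseudoAbsenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "thin_occurrences",
    "thinning_distance",
    "sample_pseudo_absences",
    "buffer_mask",
    "vif_select",
    "VIFSelector",
    "PredictorSelection",
]


def thinning_distance(home_range_area_ha: float, cell_size_km: float) -> float:
    """Minimum inter-record distance in km.

    The non-overlap criterion for two home ranges of area A (circle model)
    is the circle's diameter 2·sqrt(A/π); the result is floored at one cell
    so thinning never falls below the analysis resolution.
    """
    if home_range_area_ha <= 0:
        raise ValueError("home_range_area must be positive")
    area_km2 = home_range_area_ha / 100.0  # 1 km² = 100 ha
    diameter_km = 2.0 * np.sqrt(area_km2 / np.pi)
    return max(diameter_km, cell_size_km)


def thin_occurrences(points: np.ndarray, home_range_area_ha: float = 6.97,
                     cell_size_km: float = 1.0, period: str = "",
                     spec: GridSpec | None = None) -> OccurrenceSet:
    """Greedy sequential thinning in input order.

    A point is kept iff its distance to every already-kept point is at
    least ``thinning_distance(...)``; kept points are additionally
    deduplicated to one per raster cell when a grid is supplied. The greedy
    order makes the result deterministic and maximal: no removed point can
    be added back without violating the minimum distance.
    """
    d_min = thinning_distance(home_range_area_ha, cell_size_km)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return OccurrenceSet(period=period, points=np.empty((0, 2)))
    kept: list[np.ndarray] = []
    kept_cells: set[tuple[int, int]] = set()
    for p in pts:
        if kept:
            d = np.linalg.norm(np.array(kept) - p, axis=1)
            if d.min() < d_min:
                continue
        if spec is not None:
            r, c = spec.cell_index(p[0], p[1])
            cell = (int(r), int(c))
            if cell in kept_cells:
                continue
            kept_cells.add(cell)
        kept.append(p)
    return OccurrenceSet(period=period, points=np.array(kept))


def buffer_mask(spec: GridSpec, roads: list[LineString], buffer_km: float) -> np.ndarray:
    """Boolean grid of cells whose centre lies within ``buffer_km`` of a road."""
    if not roads:
        return np.zeros(spec.shape, dtype=bool)
    xs, ys = spec.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    network = shapely.union_all(roads)
    d = shapely.distance(pts, network)
    return (d <= buffer_km).reshape(spec.shape)


def sample_pseudo_absences(roads: list[LineString], spec: GridSpec,
                           presences: OccurrenceSet | None = None,
                           buffer_km: float = 15.0, n: int = 10_000,
                           seed=0, period: str = "",
                           valid: np.ndarray | None = None) -> PseudoAbsenceSet:
    """n background points uniform over buffer cells, excluding presence cells.

    Points are placed at cell centres. If fewer than n eligible cells
    exist, cells are re-used (sampling with replacement) and a warning is
    logged — the spatial coverage is then exhaustive, only multiplicities
    differ.
    """
    if not roads:
        raise ValueError("road network is empty: no buffer to sample pseudo-absences from")
    mask = buffer_mask(spec, roads, buffer_km)
    if valid is not None:
        mask &= valid
    if not mask.any():
        raise ValueError(
            f"road buffer of {buffer_km} km contains no valid cells on this grid")
    if presences is not None and len(presences) > 0:
        pr, pc = spec.cell_index(presences.x, presences.y)
        mask[pr, pc] = False
        if not mask.any():
            raise ValueError("every buffer cell is occupied by a presence")
    rows, cols = np.nonzero(mask)
    rng = np.random.default_rng(seed)
    if len(rows) >= n:
        pick = rng.choice(len(rows), size=n, replace=False)
    else:
        logger.warning("only %d eligible buffer cells for %d pseudo-absences; "
                       "sampling with replacement", len(rows), n)
        pick = rng.choice(len(rows), size=n, replace=True)
    xs, ys = spec.cell_centers()
    pts = np.column_stack([xs[rows[pick], cols[pick]], ys[rows[pick], cols[pick]]])
    return PseudoAbsenceSet(period=period, points=pts, n_requested=n)


class PredictorSelection:
    """Outcome of stepwise VIF elimination."""

    def __init__(self, retained: list[str], dropped: list[tuple[str, float]],
                 threshold: float):
        self.retained = retained
        self.dropped = dropped  # (name, VIF at removal), in removal order
        self.threshold = threshold

    def __repr__(self) -> str:
        return (f"PredictorSelection(retained={self.retained}, "
                f"dropped={self.dropped}, threshold={self.threshold})")


def _vif_one(X: np.ndarray, k: int) -> float:
    """VIF of column k regressed on the remaining columns (with intercept)."""
    y = X[:, k]
    others = np.delete(X, k, axis=1)
    A = np.column_stack([np.ones(len(X)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("constant predictor column")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def compute_vifs(X: np.ndarray) -> np.ndarray:
    """VIF of every column of X against the others."""
    X = np.asarray(X, dtype=float)
    return np.array([_vif_one(X, k) for k in range(X.shape[1])])


class VIFSelector(SelectorMixin, BaseEstimator):
    """Stepwise predictor elimination on the variance inflation factor.

    While any VIF ≥ ``threshold``, the predictor with the largest VIF is
    dropped and VIFs recomputed; ties are broken by dropping the
    later column in input order. Perfectly collinear columns get VIF = ∞
    and go first.

    Parameters
    ----------
    threshold : float, default 10.0
        Elimination threshold; retained predictors all have VIF below it.

    Attributes
    ----------
    support_ : bool array of shape (n_features,)
        Mask of retained predictors.
    selection_ : PredictorSelection
        Retained names and (name, VIF) removal history.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None, feature_names: list[str] | None = None):
        X = validate_data(self, X, ensure_min_features=2, ensure_min_samples=4)
        if X.shape[0] < X.shape[1] + 2:
            raise ValueError("need at least p+2 rows for VIF estimation")
        names = (feature_names if feature_names is not None
                 else getattr(self, "feature_names_in_",
                              None))
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        names = list(names)
        if np.any(np.ptp(X, axis=0) == 0):
            bad = [names[i] for i in np.nonzero(np.ptp(X, axis=0) == 0)[0]]
            raise ValueError(f"constant predictor column(s): {bad}")

        active = list(range(X.shape[1]))
        dropped: list[tuple[str, float]] = []
        while len(active) >= 2:
            vifs = compute_vifs(X[:, active])
            worst = np.max(vifs)
            if worst < self.threshold:
                break
            # argmax with ties broken toward the LATER column in input order
            cand = np.nonzero(vifs == worst)[0]
            j = cand.max()
            dropped.append((names[active[j]], float(worst)))
            del active[j]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[active] = True
        self.selection_ = PredictorSelection(
            retained=[names[i] for i in active], dropped=dropped,
            threshold=self.threshold)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_


def vif_select(design, threshold: float = 10.0,
               feature_names: list[str] | None = None) -> PredictorSelection:
    """Functional wrapper over :class:`VIFSelector`.

    ``design`` may be a pandas DataFrame (column names used) or an array.
    """
    try:
        import pandas as pd
        if isinstance(design, pd.DataFrame):
            if feature_names is None:
                feature_names = list(design.columns)
            design = design.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sel = VIFSelector(threshold=threshold).fit(design, feature_names=feature_names)
    return sel.selection_
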