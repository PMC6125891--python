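"""Core value types shared across the pipeline.

The pipeline operates on co-registered raster grids. A :class:`GridSpec`
fixes the geometry once; every layer, mask and rank surface produced
downstream must share it. Environmental layers for one decade are bundled
into an :class:`EnvStack`; occurrence and pseudo-absence points are plain
coordinate tables tagged with their period label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical environmental variable names, in stack order
ENV_VARS = ("MAT", "MAP", "NFFD", "Eref", "elevation", "aspect", "forest", "urban")

#: variables treated as climate when assembling counterfactual stacks
CLIMATE_VARS = ("MAT", "MAP", "NFFD", "Eref")

#: variables treated as human-influence layers (land-cover vintages)
HUMAN_VARS = ("forest", "urban")

#: static topographic variables, identical across periods
STATIC_VARS = ("elevation", "aspect")

DEFAULT_PERIODS = ("1970s", "1980s", "1990s", "2000s")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis raster.

    Cells are squares of ``cell_size`` km; ``origin`` is the map coordinate
    of the lower-left corner of the lower-left cell. Row 0 of an array is
    the *top* row of the map (image convention).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell centre, each shaped (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing map points; points outside raise."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        row = self.n_rows - 1 - row_from_bottom
        if np.any((col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)):
            raise ValueError("point outside grid bounds")
        return row, col


@dataclass
class EnvStack:
    """Named, co-registered raster layers for one time period."""

    period: str
    layers: dict[str, np.ndarray]
    spec: GridSpec
    mask: np.ndarray | None = None  # True = valid cell

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        for name, shp in shapes.items():
            if shp != self.spec.shape:
                raise ValueError(f"layer {name!r} shape {shp} != grid {self.spec.shape}")
        if self.mask.shape != self.spec.shape:
            raise ValueError("mask shape mismatch")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def table(self, variables: tuple[str, ...] | list[str]) -> np.ndarray:
        """Valid-cell predictor matrix, one row per valid cell (row-major order)."""
        return np.column_stack([self.layers[v][self.mask] for v in variables])

    def extract(self, x: np.ndarray, y: np.ndarray, variables) -> np.ndarray:
        """Predictor matrix at map points."""
        row, col = self.spec.cell_index(x, y)
        return np.column_stack([self.layers[v][row, col] for v in variables])


@dataclass
class OccurrenceSet:
    """Presence points for one period (map coordinates)."""

    period: str
    points: np.ndarray  # (n, 2) x, y
    source_tag: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class PseudoAbsenceSet:
    """Background points drawn from the road-buffer zone for one period."""

    period: str
    points: np.ndarray
    n_requested: int = 10_000

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TrueNiche:
    """Synthetic ground-truth suitability: Gaussian responses to elevation and
    mean annual temperature, times an exponential penalty on urban cover whose
    strength grows over periods (the anthropogenic-contraction driver)."""

    elev_opt: float = 600.0
    elev_sd: float = 350.0
    mat_opt: float = 17.0
    mat_sd: float = 4.0
    human_beta: tuple[float, ...] = (1.0, 2.5, 4.5, 7.0)

    def __post_init__(self) -> None:
        if self.elev_sd <= 0 or self.mat_sd <= 0:
            raise ValueError("sd parameters must be positive")
        if any(b < 0 for b in self.human_beta):
            raise ValueError("human_beta must be non-negative")
        if any(b2 < b1 for b1, b2 in zip(self.human_beta, self.human_beta[1:])):
            raise ValueError("human_beta must be non-decreasing over periods")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full synthetic-scenario description; a pure function of this plus the
    seed determines every generated artefact."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 1.0))
    periods: tuple[str, ...] = DEFAULT_PERIODS
    occurrences_per_period: tuple[int, ...] = (714, 561, 322, 117)
    seed: int = 0
    road_count: int = 6
    contraction_strength: float = 1.0
    niche: TrueNiche = field(default_factory=TrueNiche)

    def __post_init__(self) -> None:
        if len(self.occurrences_per_period) != len(self.periods):
            raise ValueError("one occurrence count per period required")
        if any(n < 0 for n in self.occurrences_per_period):
            raise ValueError("occurrence counts must be non-negative")
        if self.road_count < 0:
            raise ValueError("road_count must be non-negative")
        if self.contraction_strength < 0:
            raise ValueError("contraction_strength must be non-negative")

    def beta(self, period_index: int) -> float:
        """Human-pressure sensitivity for one period, scaled by contraction_strength."""
        return self.contraction_strength * self.niche.human_beta[period_index]
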