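"""Synthetic multi-period landscapes with a known range contraction.

Generates the inputs the reconstruction pipeline consumes — eight
environmental layers on a common grid over four decades, a road network,
occurrence points and test polygons — with the statistical structure the
analysis assumes: elevation-driven climate, human pressure (urban cover)
that intensifies over time near roads and at low elevations, and
occurrences drawn from a suitability surface whose sensitivity to human
pressure grows each decade. Range contraction and an upslope shift of the
occupied range therefore *emerge* from the generator rather than being
painted in, which is what makes downstream parameter-recovery tests
meaningful.

Every output is a pure function of (config, seed): the top-level seed is
split into independent streams for terrain, roads, climate noise and
per-period occurrence sampling.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box

from .types import DEFAULT_PERIODS, EnvStack, GridSpec, OccurrenceSet, ScenarioConfig, TrueNiche

__all__ = [
    "generate_landscape",
    "true_suitability",
    "sample_occurrences",
    "generate_roads",
    "generate_polygons",
    "simulate_scenario",
    "Scenario",
]

# fixed stream indices so each component gets an independent, reproducible RNG
_STREAM_TERRAIN = 0
_STREAM_ROADS = 1
_STREAM_CLIMATE = 2
_STREAM_URBAN = 3
_STREAM_OCC = 4  # + period index


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(config.seed, stream)))


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  n_waves: int = 5, noise_sd: float = 0.05) -> np.ndarray:
    """Standardised smooth random surface: a sum of 3-6 low-frequency
    sinusoids plus a little white Gaussian noise, rescaled to zero mean and
    unit sd. Dependency-light stand-in for a geostatistical simulator."""
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    u, v = yy / rows, xx / cols
    field = np.zeros(shape)
    for _ in range(n_waves):
        fy, fx = rng.uniform(0.5, 3.0, size=2)  # cycles across the grid
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.sin(2 * np.pi * (fy * u + fx * v) + phase)
    field += rng.normal(0.0, noise_sd * field.std() if field.std() > 0 else noise_sd, shape)
    return (field - field.mean()) / field.std()


def _elevation(config: ScenarioConfig) -> np.ndarray:
    """Terrain in metres, fixed across periods; smooth, range ≈ 0-1500 m."""
    rng = _rng(config, _STREAM_TERRAIN)
    z = _smooth_field(rng, config.grid.shape, n_waves=5)
    z = (z - z.min()) / (z.max() - z.min())
    return 1500.0 * z


def generate_roads(config: ScenarioConfig) -> list[LineString]:
    """Seeded random polylines biased toward low elevation.

    Endpoints and way-points are cell centres sampled with probability
    ∝ exp(−elev/300 m), emulating valley-following transport corridors.
    """
    elev = _elevation(config)
    rng = _rng(config, _STREAM_ROADS)
    if config.road_count == 0:
        return []
    xs, ys = config.grid.cell_centers()
    w = np.exp(-elev / 300.0).ravel()
    w /= w.sum()
    roads = []
    for _ in range(config.road_count):
        n_pts = rng.integers(3, 6)
        idx = rng.choice(elev.size, size=n_pts, replace=False, p=w)
        pts = np.column_stack([xs.ravel()[idx], ys.ravel()[idx]])
        # order way-points along their principal direction for a road-like shape
        d = pts - pts.mean(axis=0)
        axis = np.linalg.svd(d, full_matrices=False)[2][0]
        pts = pts[np.argsort(d @ axis)]
        roads.append(LineString(pts))
    return roads


def distance_to_roads(spec: GridSpec, roads: list[LineString]) -> np.ndarray:
    """Per-cell distance (map units) from cell centre to the nearest road."""
    if not roads:
        return np.full(spec.shape, np.inf)
    xs, ys = spec.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    d = shapely.distance(pts, shapely.union_all(roads))
    return d.reshape(spec.shape)


# per-period urban growth multipliers (fraction of the saturated urban field)
_URBAN_GROWTH = (0.25, 0.45, 0.70, 1.00)


def generate_landscape(config: ScenarioConfig,
                       roads: list[LineString] | None = None) -> list[EnvStack]:
    """One EnvStack per period.

    Elevation and aspect are fixed; climate layers are smooth functions of
    elevation plus spatial noise (MAT falls with a 6.5 °C/km lapse rate);
    urban cover grows monotonically over periods, concentrated near roads
    and at low elevation; forest is the complement of urban minus a fixed
    disturbance field, clamped to [0, 1].
    """
    spec = config.grid
    elev = _elevation(config)
    if roads is None:
        roads = generate_roads(config)

    crng = _rng(config, _STREAM_CLIMATE)
    mat_noise = _smooth_field(crng, spec.shape)
    map_noise = _smooth_field(crng, spec.shape)
    nffd_noise = _smooth_field(crng, spec.shape)
    eref_noise = _smooth_field(crng, spec.shape)
    aspect = crng.uniform(0.0, 360.0, spec.shape)

    mat = 21.0 - 6.5 * elev / 1000.0 + 1.5 * mat_noise
    map_ = 1600.0 + 0.15 * elev + 180.0 * map_noise  # wetter uplands
    nffd = 330.0 - 0.03 * elev + 18.0 * nffd_noise
    eref = 900.0 - 0.10 * elev + 80.0 * eref_noise

    urng = _rng(config, _STREAM_URBAN)
    d_road = distance_to_roads(spec, roads)
    road_scale = 8.0 * spec.cell_size
    # saturated (end-state) urban field in [0, 1]
    base = np.exp(-np.where(np.isfinite(d_road), d_road, 1e9) / road_scale)
    base = base * np.exp(-elev / 500.0)
    base = base + 0.05 * np.abs(_smooth_field(urng, spec.shape))
    base = np.clip(base / base.max() if base.max() > 0 else base, 0.0, 1.0)
    disturbance = 0.1 * np.abs(_smooth_field(urng, spec.shape))

    growth = np.interp(np.arange(len(config.periods)),
                       np.linspace(0, len(config.periods) - 1, len(_URBAN_GROWTH)),
                       _URBAN_GROWTH)

    stacks = []
    for t, period in enumerate(config.periods):
        urban = np.clip(growth[t] * base, 0.0, 1.0)
        forest = np.clip(1.0 - urban - disturbance, 0.0, 1.0)
        layers = {
            "MAT": mat, "MAP": map_, "NFFD": nffd, "Eref": eref,
            "elevation": elev, "aspect": aspect,
            "forest": forest, "urban": urban,
        }
        stacks.append(EnvStack(period=period, layers={k: v.copy() for k, v in layers.items()},
                               spec=spec))
    return stacks


def true_suitability(stack: EnvStack, niche: TrueNiche,
                     beta: float | None = None,
                     periods: tuple[str, ...] = DEFAULT_PERIODS) -> np.ndarray:
    """Ground-truth suitability in [0, 1]:

    ``s = exp(−(elev−elev_opt)²/2σ_e²) · exp(−(MAT−mat_opt)²/2σ_m²) · exp(−β·urban)``

    where β is the period's human-pressure sensitivity (``niche.human_beta``
    indexed by the stack's period, or an explicit ``beta``).
    """
    if beta is None:
        beta = niche.human_beta[periods.index(stack.period)]
    elev, mat, urban = stack["elevation"], stack["MAT"], stack["urban"]
    s = (np.exp(-((elev - niche.elev_opt) ** 2) / (2 * niche.elev_sd**2))
         * np.exp(-((mat - niche.mat_opt) ** 2) / (2 * niche.mat_sd**2))
         * np.exp(-beta * urban))
    return s


def sample_occurrences(suitability: np.ndarray, n: int, seed,
                       spec: GridSpec, period: str = "") -> OccurrenceSet:
    """Draw n distinct cells with probability ∝ suitability; points at cell
    centres. Mirrors the post-thinning structure of real occurrence data
    (at most one record per cell)."""
    s = np.asarray(suitability, dtype=float).ravel()
    positive = s > 0
    if n == 0:
        return OccurrenceSet(period=period, points=np.empty((0, 2)))
    if positive.sum() < n:
        raise ValueError(
            f"requested {n} occurrences but only {int(positive.sum())} cells have "
            "positive suitability")
    if s.sum() <= 0:
        raise ValueError("suitability sums to zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(s.size, size=n, replace=False, p=s / s.sum())
    xs, ys = spec.cell_centers()
    pts = np.column_stack([xs.ravel()[idx], ys.ravel()[idx]])
    return OccurrenceSet(period=period, points=pts)


def generate_polygons(config: ScenarioConfig, k: int, strategy: str = "tile") -> list[Polygon]:
    """k test polygons standing in for reserves/prefectures.

    ``tile``: k disjoint rectangles covering the whole grid exactly.
    ``random``: k seeded random rectangles (may overlap).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    spec = config.grid
    x0, y0 = spec.origin
    W, H = spec.n_cols * spec.cell_size, spec.n_rows * spec.cell_size
    if strategy == "tile":
        r = max(i for i in range(1, int(np.sqrt(k)) + 1) if k % i == 0)
        c = k // r
        xs = x0 + W * np.arange(c + 1) / c
        ys = y0 + H * np.arange(r + 1) / r
        return [box(xs[j], ys[i], xs[j + 1], ys[i + 1])
                for i in range(r) for j in range(c)]
    if strategy == "random":
        rng = _rng(config, _STREAM_ROADS + 100)
        polys = []
        for _ in range(k):
            cx, cy = rng.uniform(x0, x0 + W), rng.uniform(y0, y0 + H)
            w, h = rng.uniform(0.1, 0.4) * W, rng.uniform(0.1, 0.4) * H
            polys.append(box(max(x0, cx - w / 2), max(y0, cy - h / 2),
                             min(x0 + W, cx + w / 2), min(y0 + H, cy + h / 2)))
        return polys
    raise ValueError(f"unknown strategy {strategy!r}")


class Scenario:
    """A fully realised synthetic study: stacks, roads, occurrences and the
    true suitability surfaces, all deterministic in the config."""

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.roads = generate_roads(config)
        self.stacks = generate_landscape(config, roads=self.roads)
        self.true_suitability = [
            true_suitability(stack, config.niche, beta=config.beta(t))
            for t, stack in enumerate(self.stacks)
        ]
        self.occurrences = [
            sample_occurrences(self.true_suitability[t], config.occurrences_per_period[t],
                               seed=np.random.SeedSequence(entropy=(config.seed, _STREAM_OCC + t)),
                               spec=config.grid, period=p)
            for t, p in enumerate(config.periods)
        ]


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate the complete synthetic study for a config."""
    return Scenario(config)
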