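"""Environmental-space (PCA-env) niche construction and overlap.

The realized niche of each period is represented as a kernel-smoothed
occupancy surface on a regular grid in the space of the first two
principal components of the (standardised) environmental variables,
calibrated over *all* periods' available cells. Occurrence density is
divided by environmental availability density so that occupancy reflects
preference, not merely what the landscape offers. Niches are compared with
Schoener's D, and each period's partial niche is tested against the total
niche by comparing its D with the D of random same-size subsamples of the
pooled occurrences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .types import EnvStack

logger = logging.getLogger(__name__)

__all__ = [
    "EnvSpacePCA",
    "fit_env_space",
    "density_surface",
    "occupancy",
    "schoeners_d",
    "NicheGrid",
    "build_niche_grid",
    "OverlapTest",
    "partial_vs_total_test",
]

_EPS = 1e-12


class EnvSpacePCA(TransformerMixin, BaseEstimator):
    """Two-axis PCA of standardised environmental variables.

    Variables are centred and scaled to unit sd over the supplied
    (pooled, all-period) availability sample; the first two eigenvectors
    of the correlation matrix define the environmental space. Sign
    convention: the largest-magnitude loading on each axis is positive, so
    axes are reproducible across runs and platforms.

    Attributes
    ----------
    mean_, scale_ : per-variable standardisation constants
    components_ : (2, p) loadings
    explained_variance_ratio_ : fractions of total variance, axis1 ≥ axis2
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = validate_data(self, X, ensure_min_features=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        if np.any(self.scale_ == 0):
            bad = np.nonzero(self.scale_ == 0)[0].tolist()
            raise ValueError(f"constant variable(s) at column(s) {bad}; "
                             "drop them (e.g. via VIF selection) before the PCA")
        Z = (X - self.mean_) / self.scale_
        cov = Z.T @ Z / len(Z)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.n_components]
        comps = evecs[:, order].T
        # orient: largest-|loading| entry positive per axis
        for i, row in enumerate(comps):
            if row[np.argmax(np.abs(row))] < 0:
                comps[i] = -row
        self.components_ = comps
        self.eigenvalues_ = evals[order]
        self.explained_variance_ratio_ = evals[order] / evals.sum()
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return ((X - self.mean_) / self.scale_) @ self.components_.T


def fit_env_space(stacks: list[EnvStack], variables: list[str]) -> EnvSpacePCA:
    """Calibrate the PCA-env over the pooled valid cells of all periods."""
    pooled = np.vstack([s.table(variables) for s in stacks])
    return EnvSpacePCA().fit(pooled)


def _nrd_bandwidth(x: np.ndarray) -> float:
    """Normal-reference (Silverman) bandwidth for one axis."""
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(x[0]), 1.0) * 0.1 if n else 1.0
    return 0.9 * spread * n ** (-1 / 5) if n > 1 else spread


def density_surface(scores: np.ndarray, bounds: tuple[tuple[float, float], tuple[float, float]],
                    R: int = 100, bandwidth: tuple[float, float] | None = None) -> np.ndarray:
    """Gaussian kernel density of points on an R×R lattice, normalised to sum 1.

    The kernel is a product of per-axis Gaussians with normal-reference
    bandwidths (or explicit ones); evaluation is exact (no binning).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 0:
        raise ValueError("density_surface needs at least one point")
    (x_min, x_max), (y_min, y_max) = bounds
    gx = np.linspace(x_min, x_max, R)
    gy = np.linspace(y_min, y_max, R)
    if bandwidth is None:
        bandwidth = (_nrd_bandwidth(scores[:, 0]), _nrd_bandwidth(scores[:, 1]))
    hx, hy = (max(b, _EPS) for b in bandwidth)
    # separable kernel: (R, n) per axis, density = Kx @ Ky^T summed over points
    kx = np.exp(-0.5 * ((gx[:, None] - scores[None, :, 0]) / hx) ** 2)
    ky = np.exp(-0.5 * ((gy[:, None] - scores[None, :, 1]) / hy) ** 2)
    z = kx @ ky.T  # (R_x, R_y); axis 0 = first PCA axis
    total = z.sum()
    if total <= 0:
        raise ValueError("all density mass fell outside the bounds")
    return z / total


def occupancy(z_occ: np.ndarray, z_env: np.ndarray,
              availability_floor: float = 1e-4) -> np.ndarray:
    """Availability-corrected occupancy: occurrence density divided by
    environmental availability where available, renormalised to sum 1.

    Cells whose availability is below ``availability_floor`` times the
    availability maximum count as unavailable and contribute zero (logged
    if they held occurrence mass). The relative floor matters: the ratio
    z_occ/z_env is numerically explosive in the far kernel tails where
    both densities are vanishing, and without the floor a handful of
    margin cells can swallow most of the occupancy mass.
    """
    z_occ = np.asarray(z_occ, dtype=float)
    z_env = np.asarray(z_env, dtype=float)
    if z_occ.shape != z_env.shape:
        raise ValueError("occurrence and availability grids differ in shape")
    avail = z_env > max(z_env.max() * availability_floor, _EPS)
    lost = z_occ[~avail].sum()
    if lost > 1e-2:
        logger.warning("%.3g occurrence density mass falls outside available "
                       "environmental space and is zeroed", lost)
    z_raw = np.where(avail, z_occ / np.where(avail, z_env, 1.0), 0.0)
    total = z_raw.sum()
    if total <= 0:
        raise ValueError("occurrences lie entirely outside the available environmental space")
    return z_raw / total


def schoeners_d(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's D = 1 − ½ Σ|z1 − z2| between two normalised occupancy
    surfaces; 0 = disjoint niches, 1 = identical."""
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError("surfaces differ in shape")
    for i, z in enumerate((z1, z2), 1):
        if abs(z.sum() - 1.0) > 1e-6:
            raise ValueError(f"surface {i} is not normalised (sum={z.sum():.6g})")
    return float(1.0 - 0.5 * np.abs(z1 - z2).sum())


@dataclass
class NicheGrid:
    """Gridded, availability-corrected occupancy in 2-D environmental space."""

    resolution: int
    bounds: tuple[tuple[float, float], tuple[float, float]]
    z_occ: np.ndarray
    z_env: np.ndarray
    z: np.ndarray


def build_niche_grid(occ_scores: np.ndarray, env_scores: np.ndarray,
                     bounds=None, R: int = 100) -> NicheGrid:
    """Assemble the occupancy surface for one occurrence set.

    ``bounds`` should span the availability of *all* periods so that
    surfaces are comparable; by default they are taken from ``env_scores``
    with a 5 % margin.
    """
    env_scores = np.atleast_2d(env_scores)
    if bounds is None:
        bounds = scores_bounds(env_scores)
    z_env = density_surface(env_scores, bounds, R)
    z_occ = density_surface(occ_scores, bounds, R)
    z = occupancy(z_occ, z_env)
    return NicheGrid(resolution=R, bounds=bounds, z_occ=z_occ, z_env=z_env, z=z)


def scores_bounds(scores: np.ndarray, margin: float = 0.05):
    """Axis bounds covering the scores with a proportional margin."""
    scores = np.atleast_2d(scores)
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    pad = (hi - lo) * margin
    pad = np.where(pad == 0, 1.0, pad)
    return ((lo[0] - pad[0], hi[0] + pad[0]), (lo[1] - pad[1], hi[1] + pad[1]))


@dataclass
class OverlapTest:
    """Partial-vs-total niche comparison for one period."""

    period: str
    d_obs: float
    null_d: np.ndarray
    p_value: float

    @property
    def significant(self) -> bool:
        """True when the period niche is *less* similar to the total niche
        than random subsamples (one-tailed, 0.05)."""
        return round(self.p_value, 2) < 0.05


def partial_vs_total_test(pool_scores: np.ndarray, period_scores: np.ndarray,
                          env_scores: np.ndarray, B: int = 100, seed=0,
                          R: int = 100, period: str = "",
                          bounds=None) -> OverlapTest:
    """Compare a period's partial niche with the total niche.

    d_obs is Schoener's D between the period occupancy surface and the
    total (pooled-occurrence) surface. The null distribution is the D of B
    random subsamples of the pooled occurrences with the period's sample
    size. p = (1 + #{null ≤ d_obs}) / (B + 1), one-tailed: small p means
    the period's niche resembles the total niche *less* than sampling
    noise alone would produce.
    """
    pool_scores = np.atleast_2d(pool_scores)
    period_scores = np.atleast_2d(period_scores)
    n = len(period_scores)
    if n == 0:
        raise ValueError("period has no occurrences")
    if n > len(pool_scores):
        raise ValueError("period sample exceeds the pooled sample")
    if bounds is None:
        bounds = scores_bounds(np.atleast_2d(env_scores))
    z_env = density_surface(np.atleast_2d(env_scores), bounds, R)

    def _occ_surface(scores):
        return occupancy(density_surface(scores, bounds, R), z_env)

    z_total = _occ_surface(pool_scores)
    d_obs = schoeners_d(_occ_surface(period_scores), z_total)
    rng = np.random.default_rng(seed)
    null_d = np.empty(B)
    for b in range(B):
        idx = rng.choice(len(pool_scores), size=n, replace=False)
        null_d[b] = schoeners_d(_occ_surface(pool_scores[idx]), z_total)
    p = (1.0 + np.sum(null_d <= d_obs)) / (B + 1.0)
    return OverlapTest(period=period, d_obs=float(d_obs), null_d=null_d,
                       p_value=float(p))
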