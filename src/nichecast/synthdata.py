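"""Synthetic landscapes, niches, occurrence samples, and future scenarios.

The generator is the test bed for the whole pipeline: it builds
spatially smooth, cross-correlated predictor surfaces with nodata
margins; defines a known "true niche" as a logistic function of linear
and quadratic terms in a subset of predictors; samples presence points
proportionally to true suitability (optionally through a sampling-bias
surface); and perturbs the base stack into future-scenario members.

Surface construction: each variable is a linear blend of empirically
orthonormalized base fields — Gaussian-filtered white noise plus one
deterministic north–south gradient field — mixed through the Cholesky
factor of the requested correlation matrix, so the empirical
cross-correlation over valid cells matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geo_io import EnvStack, GridGeometry, OccurrenceSet, SuitabilityMap

__all__ = [
    "NicheSpec",
    "ScenarioSpec",
    "default_geometry",
    "generate_env_stack",
    "true_suitability",
    "sample_occurrences",
    "make_scenarios",
]


@dataclass
class NicheSpec:
    """A known logistic niche over linear + quadratic predictor terms.

    True suitability at a cell with predictor values ``x`` is
    ``expit(intercept + sum_j a_j x_j + sum_j b_j x_j**2)`` over the
    active variables.
    """

    linear_coefs: Mapping[str, float]
    quad_coefs: Mapping[str, float]
    intercept: float = 0.0

    @property
    def active_vars(self) -> list[str]:
        return sorted(set(self.linear_coefs) | set(self.quad_coefs))


@dataclass
class ScenarioSpec:
    """One future scenario (e.g. ``SSP126-2050s``) with several GCM members.

    Each member stack is ``base + shift + smooth zero-mean noise`` where
    the noise scale emulates disagreement between climate models.
    """

    label: str
    gcm_labels: Sequence[str]
    shift: Mapping[str, float]
    noise_sd: float = 0.0
    seed: int = 0
    smoothness: float = 5.0


def default_geometry(
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size_deg: float = 2.5 / 60.0,
    origin_lon: float = 100.0,
    origin_lat: float = 40.0,
    nodata_margin: int = 2,
) -> GridGeometry:
    """Grid with a nodata margin emulating rasters cropped to a study area."""
    mask = None
    if nodata_margin > 0:
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        m = nodata_margin
        mask[:m, :] = True
        mask[-m:, :] = True
        mask[:, :m] = True
        mask[:, -m:] = True
    return GridGeometry(n_rows, n_cols, cell_size_deg, origin_lon, origin_lat, mask)


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if smoothness > 0:
        noise = gaussian_filter(noise, sigma=smoothness, mode="reflect")
    return noise


def generate_env_stack(
    geometry: GridGeometry,
    n_vars: int = 6,
    correlation_target: np.ndarray | None = None,
    smoothness: float = 5.0,
    seed: int = 0,
    names: Sequence[str] | None = None,
    gradient_weight: float = 0.5,
) -> EnvStack:
    """Generate smooth correlated predictor surfaces on a grid.

    Parameters
    ----------
    correlation_target
        Symmetric positive-definite correlation matrix the variables
        should exhibit over valid cells; identity if omitted.
    smoothness
        Gaussian filter length scale in cells; larger means smoother
        surfaces with longer-range spatial autocorrelation.
    gradient_weight
        Weight (in [0, 1)) of the deterministic north–south gradient in
        the first base field, giving every variable a latitudinal trend
        through the correlation mixing.
    """
    if names is None:
        names = [f"bio{j + 1:02d}" for j in range(n_vars)]
    if len(names) != n_vars:
        raise ValueError("names must have length n_vars")
    if correlation_target is None:
        correlation_target = np.eye(n_vars)
    correlation_target = np.asarray(correlation_target, dtype=float)
    if correlation_target.shape != (n_vars, n_vars):
        raise ValueError("correlation_target must be n_vars x n_vars")
    if not np.allclose(correlation_target, correlation_target.T, atol=1e-10):
        raise ValueError("correlation_target must be symmetric")
    try:
        chol = np.linalg.cholesky(correlation_target)
    except np.linalg.LinAlgError:
        raise ValueError("correlation_target must be positive definite") from None

    rng = np.random.default_rng(seed)
    valid = geometry.valid_mask
    n_valid = int(valid.sum())
    if n_valid <= n_vars:
        raise ValueError("grid too small for the requested number of variables")

    _, lat = geometry.cell_centers()
    gradient = -(lat - lat.mean())  # increases southward, like temperature
    bases = np.empty((n_vars, geometry.n_rows, geometry.n_cols))
    for j in range(n_vars):
        f = _smooth_field(rng, geometry.shape, smoothness)
        if j == 0 and gradient_weight > 0:
            g = gradient / max(gradient[valid].std(), 1e-12)
            f = np.sqrt(gradient_weight) * g + np.sqrt(1 - gradient_weight) * (
                f / max(f[valid].std(), 1e-12)
            )
        bases[j] = f

    # empirically whiten the base fields over valid cells so the mixed
    # outputs carry exactly the requested correlation
    B = bases[:, valid]
    B = B - B.mean(axis=1, keepdims=True)
    B = B / B.std(axis=1, keepdims=True)
    gram = (B @ B.T) / n_valid
    white = np.linalg.solve(np.linalg.cholesky(gram), B)
    mixed = chol @ white

    layers: dict[str, np.ndarray] = {}
    for j, name in enumerate(names):
        arr = np.full(geometry.shape, np.nan)
        arr[valid] = mixed[j]
        layers[name] = arr
    return EnvStack(geometry, layers)


def true_suitability(stack: EnvStack, niche: NicheSpec) -> SuitabilityMap:
    """Evaluate the true logistic niche on a stack; nodata propagates."""
    missing = [v for v in niche.active_vars if v not in stack.layers]
    if missing:
        raise KeyError(f"niche variables not in stack: {missing}")
    eta = np.full(stack.geometry.shape, float(niche.intercept))
    for name, a in niche.linear_coefs.items():
        eta = eta + a * stack.layers[name]
    for name, b in niche.quad_coefs.items():
        eta = eta + b * stack.layers[name] ** 2
    values = expit(eta)
    values[~stack.valid_mask] = np.nan
    return SuitabilityMap(stack.geometry, values)


def sample_occurrences(
    truth: SuitabilityMap,
    n: int,
    bias_map: np.ndarray | None = None,
    seed: int = 0,
    species: str = "synthetic-species",
) -> OccurrenceSet:
    """Sample presence points with probability proportional to suitability.

    Cells are drawn with replacement (duplicates are intentional — the
    thinning stage must have work to do) with weight
    ``truth * bias``, then each point is placed uniformly inside its
    cell.  Nodata cells are never sampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = truth.geometry
    mask = truth.valid_mask
    weights = np.where(mask, truth.values, 0.0)
    if bias_map is not None:
        bias_map = np.asarray(bias_map, dtype=float)
        if bias_map.shape != geom.shape:
            raise ValueError("bias_map shape does not match grid")
        weights = weights * np.where(np.isfinite(bias_map), bias_map, 0.0)
    rows, cols = np.nonzero(mask)
    w = weights[rows, cols]
    total = w.sum()
    if not total > 0:
        raise ValueError("suitability (x bias) is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(rows), size=n, replace=True, p=w / total)
    u = rng.random((n, 2))
    cs = geom.cell_size_deg
    lon = geom.origin_lon + (cols[picks] + u[:, 0]) * cs
    lat = geom.origin_lat - (rows[picks] + u[:, 1]) * cs
    return OccurrenceSet.from_points(lon, lat, species=species, source="synthetic")


def make_scenarios(base: EnvStack, spec: ScenarioSpec) -> list[EnvStack]:
    """Perturb a base stack into one member stack per GCM label.

    Each member is ``base + shift + smooth zero-mean noise`` with the
    noise field drawn from a seed derived deterministically from
    ``spec.seed`` and the member index.
    """
    missing = [v for v in base.names if v not in spec.shift]
    if missing:
        raise ValueError(f"shift does not cover variables: {missing}")
    members = []
    valid = base.valid_mask
    for i, _label in enumerate(spec.gcm_labels):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        layers = {}
        for name, arr in base.layers.items():
            out = arr + spec.shift[name]
            if spec.noise_sd > 0:
                f = _smooth_field(rng, base.geometry.shape, spec.smoothness)
                f = (f - f[valid].mean()) / max(f[valid].std(), 1e-12)
                out = out + spec.noise_sd * f
            layers[name] = out
        members.append(EnvStack(base.geometry, layers))
    return members
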