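"""Synthetic environmental layers, scenarios, occurrences and MPA masks.

Everything here is seeded and deterministic, and every generated product has
a known ground truth so the downstream modelling stages can be validated
end to end without external data.

Construction notes
------------------
* Spatial autocorrelation comes from Gaussian-kernel smoothing of white
  noise (kernel sd = 3 cells), rescaled so the smoothed field keeps the
  requested marginal standard deviation.
* Temperature mean falls linearly with latitude at 0.5 degC per degree;
  long-term extremes are ``mean -/+ (6 + |noise|)`` so ltmin < mean < ltmax
  holds cell-wise by construction.
* Bathymetry deepens smoothly away from the western grid edge (the synthetic
  coastline), so the <=20 m / <=5 m depth rules carve a coastal ribbon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .data_io import (
    TEMPERATURE_VARIABLES,
    VARIABLES,
    EnvLayerStack,
    GridSpec,
    OccurrenceSet,
)
from .errors import ConfigError, DataError

SCENARIO_NAMES = ("SSP1-1.9", "SSP2-4.5", "SSP5-8.5")
PERIODS = ("2030s", "2060s", "2090s")

#: End-of-century surface warming per scenario (degC) and the fraction of it
#: realized by each period. Severity ordering SSP1-1.9 < SSP2-4.5 < SSP5-8.5
#: and monotone growth across periods are guaranteed by these tables.
_WARMING_2090S = {"SSP1-1.9": 1.0, "SSP2-4.5": 2.5, "SSP5-8.5": 4.5}
_PERIOD_FRACTION = {"2030s": 0.4, "2060s": 0.7, "2090s": 1.0}

SMOOTHING_SD_CELLS = 3.0
MAX_DEPTH_M = 20.0
TURBID_MAX_DEPTH_M = 5.0


@dataclass(frozen=True)
class ScenarioSpec:
    """Named scenario x period with per-variable additive offsets."""

    scenario_name: str
    period: str
    offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario_name not in SCENARIO_NAMES:
            raise ConfigError(f"unknown scenario {self.scenario_name!r}")
        if self.period not in PERIODS:
            raise ConfigError(f"unknown period {self.period!r}")


def default_scenario(scenario_name: str, period: str) -> ScenarioSpec:
    """Build the stock offset table for one scenario x period.

    Warming is applied to all three temperature layers; salinity freshens
    and nitrate declines mildly in proportion to the warming.
    """
    if scenario_name not in _WARMING_2090S:
        raise ConfigError(f"unknown scenario {scenario_name!r}")
    if period not in _PERIOD_FRACTION:
        raise ConfigError(f"unknown period {period!r}")
    dt = _WARMING_2090S[scenario_name] * _PERIOD_FRACTION[period]
    offsets = {v: dt for v in TEMPERATURE_VARIABLES}
    offsets["salinity_mean"] = -0.1 * dt
    offsets["salinity_ltmin"] = -0.15 * dt
    offsets["salinity_ltmax"] = -0.05 * dt
    offsets["nitrate_mean"] = -0.2 * dt
    offsets["velocity_mean"] = 0.0
    offsets["productivity_mean"] = -0.05 * dt
    return ScenarioSpec(scenario_name=scenario_name, period=period, offsets=offsets)


def default_scenarios() -> list[ScenarioSpec]:
    return [default_scenario(s, p) for s in SCENARIO_NAMES for p in PERIODS]


def _smooth_noise(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Spatially autocorrelated Gaussian field with marginal sd ~= *sd*."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=SMOOTHING_SD_CELLS, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return sd * smooth


def generate_env_stack(
    grid: GridSpec, seed: int, noise_sd: float = 1.0
) -> EnvLayerStack:
    """All nine environmental layers on *grid* with an all-valid mask.

    Depth masking is applied separately (see
    :func:`generate_bathymetry_and_mask` and :func:`apply_mask`).
    """
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    _, lat = grid.lon_lat_mesh()

    def noise(sd_scale=1.0):
        return _smooth_noise(rng, grid.shape, noise_sd * sd_scale)

    # Deterministic gradient components; see module docstring.
    temp_mean = 30.0 - 0.5 * (lat - 30.0) + noise()
    spread = 6.0 + np.abs(noise(0.5))
    layers = {
        "temperature_mean": temp_mean,
        "temperature_ltmin": temp_mean - spread,
        "temperature_ltmax": temp_mean + spread,
    }
    sal_mean = 33.5 + 0.05 * (lat - 38.0) + noise(0.3)
    sal_spread = 1.5 + np.abs(noise(0.2))
    layers["salinity_mean"] = sal_mean
    layers["salinity_ltmin"] = sal_mean - sal_spread
    layers["salinity_ltmax"] = sal_mean + sal_spread
    # Velocity: nonnegative, patchy, mean ~0.35 m/s.
    layers["velocity_mean"] = np.abs(0.35 + noise(0.25))
    # Nuisance layers partly correlated with the drivers so variable
    # screening has realistic work to do.
    layers["productivity_mean"] = np.abs(
        5.0 + 0.1 * (lat - 38.0) + 0.3 * (temp_mean - temp_mean.mean()) + noise(0.8)
    )
    layers["nitrate_mean"] = np.abs(
        8.0 - 0.15 * (temp_mean - temp_mean.mean()) + noise(1.2)
    )
    assert set(layers) == set(VARIABLES)
    mask = np.ones(grid.shape, dtype=bool)
    return EnvLayerStack(grid=grid, layers=layers, mask=mask)


def apply_scenario(stack: EnvLayerStack, spec: ScenarioSpec) -> EnvLayerStack:
    """Additive per-variable offsets; grid and mask unchanged."""
    layers = {}
    for name, arr in stack.layers.items():
        layers[name] = arr + spec.offsets.get(name, 0.0)
    return stack.with_layers(layers)


def generate_bathymetry(grid: GridSpec, seed: int) -> np.ndarray:
    """Depth (m, positive down) deepening eastward from the western edge."""
    rng = np.random.default_rng(seed)
    col = np.broadcast_to(np.arange(grid.n_cols, dtype=float), grid.shape)
    ramp = 30.0 * col / max(grid.n_cols - 1, 1)
    wobble = _smooth_noise(rng, grid.shape, 4.0)
    return np.maximum(ramp + wobble, 0.0)


def generate_bathymetry_and_mask(
    grid: GridSpec,
    seed: int,
    turbid_region: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth grid plus the coastal validity mask.

    Cells deeper than 20 m are masked everywhere; inside *turbid_region*
    (``(west, south, east, north)`` in degrees) the limit tightens to 5 m.
    Returns ``(depth, mask)`` with mask True where cells remain valid.
    """
    depth = generate_bathymetry(grid, seed)
    mask = depth <= MAX_DEPTH_M
    if turbid_region is not None:
        w, s, e, n = turbid_region
        lon, lat = grid.lon_lat_mesh()
        inside = (lon >= w) & (lon <= e) & (lat >= s) & (lat <= n)
        mask &= ~inside | (depth <= TURBID_MAX_DEPTH_M)
    return depth, mask


def apply_mask(stack: EnvLayerStack, mask: np.ndarray) -> EnvLayerStack:
    """Intersect the stack's validity mask with *mask*."""
    new_mask = stack.mask & np.asarray(mask, dtype=bool)
    return EnvLayerStack(
        grid=stack.grid,
        layers={k: v.copy() for k, v in stack.layers.items()},
        mask=new_mask,
    )


@dataclass(frozen=True)
class TrueSuitabilitySurface:
    """Known-truth suitability: logistic of a quadratic form in the drivers.

    ``eta = intercept + sum_v [lin_v * x_v + quad_v * x_v**2]`` evaluated on
    (optionally capped) driver layers; suitability = ``1/(1+exp(-eta))``.
    The cap implements a saturating response (values above the cap are as
    good as the cap).
    """

    driver_variables: tuple[str, ...]
    intercept: float
    linear: dict[str, float]
    quadratic: dict[str, float]
    caps: dict[str, float] = field(default_factory=dict)

    def evaluate(self, stack: EnvLayerStack) -> np.ndarray:
        """Suitability in [0,1] on the stack's grid (NaN where masked)."""
        eta = np.full(stack.grid.shape, self.intercept, dtype=float)
        for v in self.driver_variables:
            x = stack.layers[v]
            if v in self.caps:
                x = np.minimum(x, self.caps[v])
            eta = eta + self.linear.get(v, 0.0) * x + self.quadratic.get(v, 0.0) * x**2
        from scipy.special import expit

        out = expit(eta)
        out[~stack.mask] = np.nan
        return out


def default_surface(
    ltmin_optimum: float = 14.0,
    ltmin_breadth: float = 2.5,
    velocity_cap: float = 0.7,
    velocity_gain: float = 6.0,
    intercept_shift: float = -0.5,
) -> TrueSuitabilitySurface:
    """Stock truth: quadratic optimum in winter temperature plus a
    saturating increase in current velocity up to *velocity_cap* m/s."""
    a = 1.0 / ltmin_breadth**2
    return TrueSuitabilitySurface(
        driver_variables=("temperature_ltmin", "velocity_mean"),
        intercept=intercept_shift - a * ltmin_optimum**2,
        linear={
            "temperature_ltmin": 2 * a * ltmin_optimum,
            "velocity_mean": velocity_gain,
        },
        quadratic={"temperature_ltmin": -a, "velocity_mean": 0.0},
        caps={"velocity_mean": velocity_cap},
    )


def default_taxa() -> dict[str, TrueSuitabilitySurface]:
    """Four demo taxa with staggered thermal optima."""
    return {
        "taxonA": default_surface(ltmin_optimum=12.0),
        "taxonB": default_surface(ltmin_optimum=14.0, velocity_gain=7.0),
        "taxonC": default_surface(ltmin_optimum=16.0, ltmin_breadth=3.0),
        "taxonD": default_surface(ltmin_optimum=18.0, velocity_gain=5.0),
    }


def sample_occurrences(
    surface: TrueSuitabilitySurface,
    stack: EnvLayerStack,
    n: int,
    seed: int,
    species: str = "synthetic",
    past_fraction: float = 0.25,
) -> OccurrenceSet:
    """Draw *n* presence records from the truth surface.

    Cell selection is multinomial with probability proportional to
    suitability over unmasked cells; coordinates are jittered uniformly
    within the chosen cell; years are drawn so both eras are represented
    (approximately *past_fraction* of records pre-2000).
    """
    if n < 1:
        raise ConfigError(f"n must be positive, got {n}")
    rng = np.random.default_rng(seed)
    suit = surface.evaluate(stack)
    grid = stack.grid
    rows, cols = np.nonzero(stack.mask)
    weights = suit[rows, cols]
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise DataError("degenerate surface: no unmasked cell with positive suitability")
    p = weights / total
    idx = rng.choice(len(rows), size=n, replace=True, p=p)
    half = grid.cell_size / 2
    lon = grid.lons()[cols[idx]] + rng.uniform(-half, half, size=n)
    lat = grid.lats()[rows[idx]] + rng.uniform(-half, half, size=n)
    is_past = rng.random(n) < past_fraction
    # Guarantee both eras appear whenever n >= 2.
    if n >= 2:
        if not is_past.any():
            is_past[0] = True
        if is_past.all():
            is_past[0] = False
    year = np.where(
        is_past, rng.integers(1950, 2000, size=n), rng.integers(2000, 2023, size=n)
    )
    df = pd.DataFrame({"lon": lon, "lat": lat, "year": year})
    return OccurrenceSet(species=species, records=df)


def generate_mpa_mask(
    grid: GridSpec,
    seed: int,
    coverage_fraction: float,
    valid_mask: np.ndarray | None = None,
    return_polygons: bool = False,
):
    """0/1 raster of contiguous rectangular protected patches.

    Patches are shapely boxes rasterized by cell-center containment and
    accumulated until the realized coverage of *valid_mask* cells reaches
    *coverage_fraction* (guaranteed within +-20 % relative).
    """
    from shapely.geometry import box

    if not 0 < coverage_fraction < 1:
        raise ConfigError(
            f"coverage_fraction must be in (0,1), got {coverage_fraction}"
        )
    if valid_mask is None:
        valid_mask = np.ones(grid.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n_valid = int(valid_mask.sum())
    if n_valid == 0:
        raise DataError("no valid cells to protect")
    rng = np.random.default_rng(seed)
    out = np.zeros(grid.shape, dtype=np.uint8)
    rows, cols = np.nonzero(valid_mask)
    lons, lats = grid.lons(), grid.lats()
    cs = grid.cell_size
    target = coverage_fraction * n_valid
    polygons = []
    for _ in range(10_000):
        covered = int((out[valid_mask] == 1).sum())
        if covered >= target:
            break
        # Patch half-size shrinks as we approach the target to limit overshoot.
        remaining = max(target - covered, 1.0)
        max_half = max(1, min(4, int(np.sqrt(remaining) / 2)))
        k = rng.integers(len(rows))
        half_w = int(rng.integers(1, max_half + 1))
        half_h = int(rng.integers(1, max_half + 1))
        clon, clat = lons[cols[k]], lats[rows[k]]
        poly = box(
            clon - (half_w + 0.5) * cs,
            clat - (half_h + 0.5) * cs,
            clon + (half_w + 0.5) * cs,
            clat + (half_h + 0.5) * cs,
        )
        polygons.append(poly)
        r0 = max(rows[k] - half_h, 0)
        r1 = min(rows[k] + half_h + 1, grid.n_rows)
        c0 = max(cols[k] - half_w, 0)
        c1 = min(cols[k] + half_w + 1, grid.n_cols)
        out[r0:r1, c0:c1] = 1
    out[~valid_mask] = 0
    if return_polygons:
        return out, polygons
    return out
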