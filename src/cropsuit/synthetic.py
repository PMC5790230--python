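"""Synthetic landscapes with known niche, technology and productivity truth.

Every downstream stage (ensemble niche modelling, novelty detection,
geographically weighted regression and variation partitioning) is exercised
against landscapes generated here, where the true suitability surface, the
truly predictive technology covariates and the spatially varying regression
coefficients are all known by construction.

The generative model:

* each climate variable is a deterministic latitudinal/longitudinal gradient
  plus kernel-smoothed seeded Gaussian noise; the future layer adds a
  per-variable trend (and optionally a smoothed perturbation);
* true suitability is a product-Gaussian niche,
  ``s = exp(-0.5 * sum_j ((x_j - center_j) / width_j)**2)``;
* presences are independent Bernoulli draws with probability
  ``scale * s`` per cell;
* the eleven technology covariates are affine functions of one latent
  "development" gradient plus independent noise, so a known subset carries
  signal;
* productivity is ``y(u) = b0(u) + b_suit(u) * s(u) + sum_k g_k(u) * tech_k(u)
  + e`` with affine-in-coordinates coefficient surfaces and Gaussian noise.

One master seed streams into named sub-seeds (climate, occurrence, technology,
noise) so stages can be re-randomized independently while the whole landscape
stays bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvStack, GridSpec
from .tables import TECH_VARIABLES

__all__ = [
    "FieldSpec",
    "CoefSurface",
    "LandscapeConfig",
    "SyntheticLandscape",
    "generate_climate",
    "true_suitability",
    "sample_occurrences",
    "generate_technology",
    "generate_productivity",
    "generate_landscape",
    "synthetic_supplementary_table",
]

_STAGES = ("climate", "occurrence", "technology", "noise")


@dataclass(frozen=True)
class FieldSpec:
    """One climate variable: base value, lon/lat gradients, noise amplitude."""

    base: float
    lat_slope: float = 0.0
    lon_slope: float = 0.0
    noise_amp: float = 0.0


@dataclass(frozen=True)
class CoefSurface:
    """Affine-in-coordinates coefficient surface b(u) = base + a*lat + b*lon."""

    base: float
    lat_slope: float = 0.0
    lon_slope: float = 0.0

    def __call__(self, lon, lat):
        return self.base + self.lat_slope * np.asarray(lat) + self.lon_slope * np.asarray(lon)


def _default_grid() -> GridSpec:
    # 20 x 20 cells of 0.5 deg covering lon [-60, -50], lat [-10, 0]
    return GridSpec(origin_lon=-60.0, origin_lat=0.0, cell_size=0.5, n_rows=20, n_cols=20)


def _default_fields() -> dict[str, FieldSpec]:
    return {
        "mean_annual_temp": FieldSpec(base=25.0, lat_slope=0.4, noise_amp=1.0),
        "temp_annual_range": FieldSpec(base=12.0, lat_slope=-0.5, noise_amp=1.0),
        "precip_wettest_month": FieldSpec(base=250.0, lat_slope=5.0, noise_amp=20.0),
        "precip_driest_month": FieldSpec(base=40.0, lat_slope=2.0, noise_amp=8.0),
        "precip_warmest_quarter": FieldSpec(base=500.0, lat_slope=10.0, noise_amp=40.0),
        "soil_ph": FieldSpec(base=5.5, noise_amp=0.3),
    }


@dataclass(frozen=True)
class LandscapeConfig:
    """Full recipe for one synthetic landscape; the seed determines everything."""

    grid: GridSpec = field(default_factory=_default_grid)
    seed: int = 0
    fields: dict[str, FieldSpec] = field(default_factory=_default_fields)
    niche_center: dict[str, float] = field(
        default_factory=lambda: {
            "mean_annual_temp": 23.0,
            "temp_annual_range": 14.5,
            "precip_wettest_month": 225.0,
            "precip_driest_month": 30.0,
            "precip_warmest_quarter": 450.0,
            "soil_ph": 5.5,
        }
    )
    niche_width: dict[str, float] = field(
        default_factory=lambda: {
            "mean_annual_temp": 1.5,
            "temp_annual_range": 1.8,
            "precip_wettest_month": 36.0,
            "precip_driest_month": 12.0,
            "precip_warmest_quarter": 72.0,
            "soil_ph": 0.5,
        }
    )
    climate_trend: dict[str, float] = field(
        default_factory=lambda: {
            "mean_annual_temp": 2.0,
            "temp_annual_range": 1.0,
            "precip_wettest_month": -20.0,
            "precip_driest_month": -5.0,
            "precip_warmest_quarter": -50.0,
            "soil_ph": 0.0,  # soil is held constant across periods
        }
    )
    future_perturbation_sd: float = 0.0
    smoothness: float = 2.0  # gaussian kernel radius, in cells
    presence_rate_scale: float = 1.0
    tech_loading: dict[str, float] = field(
        default_factory=lambda: {name: 0.4 + 0.05 * i for i, name in enumerate(TECH_VARIABLES)}
    )
    tech_noise_sd: float = 1.0
    intercept_surface: CoefSurface = CoefSurface(base=2.0)
    suitability_surface: CoefSurface = CoefSurface(base=1.0, lat_slope=0.1)
    tech_surfaces: dict[str, CoefSurface] = field(
        default_factory=lambda: {
            "workers": CoefSurface(base=0.4),
            "machinery_family": CoefSurface(base=0.3, lat_slope=0.02),
            "agrochemicals": CoefSurface(base=0.3),
        }
    )
    noise_sd: float = 0.1

    def validate(self) -> None:
        if any(w <= 0 for w in self.niche_width.values()):
            raise ValueError("niche widths must be positive")
        if self.noise_sd < 0 or self.tech_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0 < self.presence_rate_scale <= 1):
            raise ValueError("presence_rate_scale must lie in (0, 1]")
        if self.smoothness >= min(self.grid.n_rows, self.grid.n_cols):
            raise ValueError("smoothness kernel radius exceeds the grid")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Named, independent random stream derived from the master seed."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STAGES.index(stage),))
        return np.random.default_rng(ss)


@dataclass
class SyntheticLandscape:
    """A fully generated landscape with its ground truth attached."""

    config: LandscapeConfig
    current_env: EnvStack
    future_env: EnvStack
    suitability: np.ndarray  # true suitability in [0, 1], grid-shaped
    presence_cells: np.ndarray  # (n, 2) row/col
    technology: dict[str, np.ndarray]  # 11 grid-shaped covariates
    productivity: np.ndarray  # grid-shaped, tons/hectare

    @property
    def grid(self) -> GridSpec:
        return self.config.grid


def _smooth_noise(rng: np.random.Generator, grid: GridSpec, radius: float) -> np.ndarray:
    """Unit-variance kernel-smoothed white noise field."""
    white = rng.standard_normal(grid.shape)
    if radius <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=radius, mode="nearest")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_climate(config: LandscapeConfig) -> tuple[EnvStack, EnvStack]:
    """Current and future environmental stacks from the landscape recipe."""
    config.validate()
    rng = config.stage_rng("climate")
    grid = config.grid
    lon, lat = grid.cell_centers()
    current, future = {}, {}
    for name, spec in config.fields.items():
        base = spec.base + spec.lat_slope * lat + spec.lon_slope * lon
        layer = base + spec.noise_amp * _smooth_noise(rng, grid, config.smoothness)
        current[name] = layer
        trend = config.climate_trend.get(name, 0.0)
        fut = layer + trend
        if config.future_perturbation_sd > 0 and trend != 0.0:
            fut = fut + config.future_perturbation_sd * _smooth_noise(rng, grid, config.smoothness)
        future[name] = fut
    return EnvStack(grid, current), EnvStack(grid, future)


def true_suitability(env: EnvStack, center: dict[str, float], width: dict[str, float]) -> np.ndarray:
    """Product-Gaussian niche suitability in [0, 1], 1 exactly at the center."""
    missing = set(center) - set(env.variable_names)
    if missing or set(center) != set(width):
        raise ValueError(f"niche variables do not match environment: missing {sorted(missing)}")
    q = np.zeros(env.grid.shape)
    for name, c in center.items():
        q += ((env[name] - c) / width[name]) ** 2
    return np.exp(-0.5 * q)


def sample_occurrences(
    suitability: np.ndarray,
    rng: np.random.Generator,
    presence_rate_scale: float = 1.0,
) -> np.ndarray:
    """Bernoulli presence cells: P(presence) = scale * suitability per cell.

    Returns an (n, 2) array of (row, col) presence indices.
    """
    if not (0 < presence_rate_scale <= 1):
        raise ValueError("presence_rate_scale must lie in (0, 1]")
    s = np.asarray(suitability, dtype=float)
    if np.nanmin(s) < 0 or np.nanmax(s) > 1:
        raise ValueError("suitability must lie in [0, 1]")
    p = presence_rate_scale * np.nan_to_num(s)
    draws = rng.random(s.shape) < p
    return np.argwhere(draws)


def generate_technology(config: LandscapeConfig) -> dict[str, np.ndarray]:
    """Technology covariates on a latent development gradient.

    The latent gradient increases away from the equator (agricultural
    development concentrated in the south of the domain) plus a smooth random
    component; each covariate is ``loading * latent + noise``.
    """
    config.validate()
    rng = config.stage_rng("technology")
    grid = config.grid
    _, lat = grid.cell_centers()
    latent = -lat / 10.0 + 0.5 * _smooth_noise(rng, grid, config.smoothness)
    latent = (latent - latent.mean()) / latent.std()
    tech = {}
    for name in TECH_VARIABLES:
        loading = config.tech_loading.get(name, 0.0)
        tech[name] = loading * latent + config.tech_noise_sd * rng.standard_normal(grid.shape)
    return tech


def generate_productivity(
    config: LandscapeConfig,
    suitability: np.ndarray,
    technology: dict[str, np.ndarray],
) -> np.ndarray:
    """Productivity with spatially varying coefficients plus seeded noise."""
    config.validate()
    grid = config.grid
    lon, lat = grid.cell_centers()
    y = config.intercept_surface(lon, lat) + config.suitability_surface(lon, lat) * suitability
    for name, surface in config.tech_surfaces.items():
        y = y + surface(lon, lat) * technology[name]
    if config.noise_sd > 0:
        rng = config.stage_rng("noise")
        y = y + config.noise_sd * rng.standard_normal(grid.shape)
    return y


def generate_landscape(config: LandscapeConfig | None = None, seed: int | None = None) -> SyntheticLandscape:
    """Generate the full landscape; ``seed`` overrides the config's seed."""
    config = config or LandscapeConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    config.validate()
    current, future = generate_climate(config)
    suit = true_suitability(current, config.niche_center, config.niche_width)
    presences = sample_occurrences(
        suit, config.stage_rng("occurrence"), config.presence_rate_scale
    )
    tech = generate_technology(config)
    prod = generate_productivity(config, suit, tech)
    return SyntheticLandscape(
        config=config,
        current_env=current,
        future_env=future,
        suitability=suit,
        presence_cells=presences,
        technology=tech,
        productivity=prod,
    )


#: default per-bin municipality counts for the synthetic census table:
#: productivity bin (lo, hi] -> number of municipalities. The upper three
#: bins carry the headline counts of the reference census extract; the lower
#: bins complete the right-skewed distribution to 2,304 producers.
DEFAULT_BIN_COUNTS = {
    (0.5, 1.0): 171,
    (1.0, 1.5): 500,
    (1.5, 2.0): 700,
    (2.0, 2.5): 597,
    (2.5, 3.0): 329,
    (3.0, 3.5): 7,
}


def synthetic_supplementary_table(
    seed: int = 0,
    bin_counts: dict[tuple[float, float], int] | None = None,
    n_foreign: int = 189,
    years: tuple[int, int] = (1994, 2010),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic stand-in for a per-municipality census supplementary table.

    Builds a yearly production/harvested-area table whose *average*
    productivity distribution reproduces prescribed per-bin municipality
    counts (half-open ``(lo, hi]`` bins), plus an occurrence table listing
    the coordinates of every producing municipality together with
    ``n_foreign`` producers outside the country (with no yearly census
    columns). The default counts give 2,304 municipalities and 2,493
    occurrence records.

    This is generated data for exercising the counting and binning
    machinery, not a reproduction of any real census extract.

    Returns ``(municipalities, occurrences)``.
    """
    rng = np.random.default_rng(seed)
    counts = bin_counts or DEFAULT_BIN_COUNTS
    year_list = list(range(years[0], years[1] + 1))
    n_years = len(year_list)

    targets = []
    for (lo, hi), count in counts.items():
        # strictly inside (lo, hi]: keep clear of the open lower edge
        targets.append(rng.uniform(lo + 1e-6, hi, count))
    targets = np.concatenate(targets)
    rng.shuffle(targets)
    n = len(targets)

    # per-year productivity jitter centred exactly so the average over years
    # equals each municipality's target value
    jitter = rng.uniform(-0.1, 0.1, size=(n, n_years))
    jitter -= jitter.mean(axis=1, keepdims=True)
    yearly = np.clip(targets[:, None] * (1.0 + jitter), 1e-9, None)
    # re-centre after clipping (clipping is almost never active)
    yearly += (targets[:, None] - yearly.mean(axis=1, keepdims=True))
    area = rng.uniform(50, 5000, size=(n, n_years))
    production = yearly * area

    lon = rng.uniform(-73.0, -35.0, n)
    lat = rng.uniform(-33.0, 5.0, n)
    munis = pd.DataFrame({"id": np.arange(n), "lon": lon, "lat": lat})
    for j, year in enumerate(year_list):
        munis[f"production_{year}"] = production[:, j]
        munis[f"area_{year}"] = area[:, j]

    f_lon = rng.uniform(-70.0, -55.0, n_foreign)
    f_lat = rng.uniform(-40.0, 10.0, n_foreign)
    occurrences = pd.DataFrame(
        {
            "lon": np.concatenate([lon, f_lon]),
            "lat": np.concatenate([lat, f_lat]),
            "domestic": np.concatenate([np.ones(n, bool), np.zeros(n_foreign, bool)]),
        }
    )
    return munis, occurrences
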