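"""Seeded synthetic inputs with known truth for every pipeline stage.

The generators emulate the structure of the real inputs — a high-resolution
reference analysis, coarse climate-model members per scenario, and point
observations — while keeping the injected components (bias map, variance
inflation, per-scenario trends, fine-scale spatial pattern) available as
explicit truth so recovery can be asserted:

* reference (fine grid, historical window): large-scale smooth pattern +
  stationary fine-scale pattern + seasonal sinusoid + linear trend + AR(1)
  monthly noise;
* member (coarse grid, historical + projection): the large-scale signal at
  coarse nodes + an additive bias map + AR(1) noise with inflated variance +
  the scenario trend taking over after the historical window (continuous in
  time), with an independent noise stream per (member, scenario);
* observations: reference values at grid nodes plus Gaussian noise, with a
  configurable fraction jittered off-node beyond the matching tolerance to
  exercise rejection.

All generators are pure functions of (config, seed): repeated calls are
bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evaluation import ObsRecord
from .grids import Grid, GriddedField
from .timeutils import fractional_years, monthly_range

DEFAULT_SCENARIO_TRENDS = {"ssp126": 0.10, "ssp245": 0.20, "ssp585": 0.40}  # units / decade


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic experiments.

    Desk-scale defaults: a 24x24 fine grid at nominal 1/12 degree with
    coarsening factor 6 (4x4 coarse cells at 0.5 degree, mirroring the
    product/working resolution ratio), monthly 1993-2100 with a 1993-2020
    historical window; AR(1) noise with coefficient 0.6 and standard
    deviation 0.5 units; per-scenario trends of 0.1/0.2/0.4 units per decade
    spanning a low-mitigation to high-forcing spread.
    """

    fine_shape: tuple[int, int] = (24, 24)
    fine_resolution: float = 1.0 / 12.0
    lat0: float = 54.0
    lon0: float = 2.0
    coarsen_factor: int = 6
    hist_years: tuple[int, int] = (1993, 2020)
    proj_end_year: int = 2100
    variable: str = "temperature"
    units: str = "degC"
    depth_label: str = "surface"
    base_value: float = 12.0
    large_scale_amplitude: float = 3.0
    fine_scale_amplitude: float = 1.0
    seasonal_amplitude: float = 2.0
    ar1_coef: float = 0.6
    noise_std: float = 0.5
    reference_trend: float = 0.10  # units per decade over the historical window
    member_bias: float = 2.0  # additive offset, constant or gradient pattern
    bias_pattern: str = "constant"  # "constant" | "gradient"
    variance_inflation: float = 1.5
    scenario_trends: dict = dc_field(default_factory=lambda: dict(DEFAULT_SCENARIO_TRENDS))
    land_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ValidationError("AR(1) coefficient must lie in [0, 1)")
        if self.noise_std < 0:
            raise ValidationError("noise std must be non-negative")
        ny, nx = self.fine_shape
        f = self.coarsen_factor
        if ny % f or nx % f:
            raise ValidationError("coarsening factor must divide the fine grid shape")
        if self.hist_years[0] >= self.hist_years[1] or self.hist_years[1] >= self.proj_end_year:
            raise ValidationError("need hist start < hist end < projection end")


@dataclass
class SyntheticTruth:
    """Realized injected components, reproducible from (config, seed)."""

    fine_pattern: np.ndarray
    bias_map: np.ndarray  # on the coarse grid
    scenario_trends: dict
    reference_trend: float
    variance_inflation: float
    noise_std: float


def _rng(config: SyntheticConfig, *tags: str) -> np.random.Generator:
    keys = [config.seed % (2**31)] + [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(keys))


def _fine_grid(config: SyntheticConfig) -> Grid:
    ny, nx = config.fine_shape
    res = config.fine_resolution
    lats = config.lat0 + res * (np.arange(ny) + 0.5)
    lons = config.lon0 + res * (np.arange(nx) + 0.5)
    mask = np.ones((ny, nx), dtype=bool)
    if config.land_fraction > 0:
        # connected land blob in the south-west corner
        n_land = int(round(config.land_fraction * ny * nx))
        iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        dist = np.hypot(iy, ix)
        order = np.argsort(dist.ravel(), kind="stable")[:n_land]
        mask.ravel()[order] = False
    return Grid(lats, lons, mask)


def coarse_grid(config: SyntheticConfig) -> Grid:
    fine = _fine_grid(config)
    f = config.coarsen_factor
    ny, nx = config.fine_shape
    lats = fine.lats.reshape(ny // f, f).mean(axis=1)
    lons = fine.lons.reshape(nx // f, f).mean(axis=1)
    mask = fine.mask.reshape(ny // f, f, nx // f, f).any(axis=(1, 3))
    return Grid(lats, lons, mask)


def _large_scale(config: SyntheticConfig, lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Smooth pattern resolvable at the coarse resolution."""
    lat_ext = config.fine_shape[0] * config.fine_resolution
    lon_ext = config.fine_shape[1] * config.fine_resolution
    ynorm = (lats - config.lat0) / lat_ext
    xnorm = (lons - config.lon0) / lon_ext
    return config.base_value + config.large_scale_amplitude * (
        (ynorm[:, None] - 0.5) + 0.5 * np.sin(np.pi * xnorm[None, :])
    )


def _fine_scale(config: SyntheticConfig) -> np.ndarray:
    """Stationary sub-grid pattern with zero mean per coarse block."""
    ny, nx = config.fine_shape
    f = config.coarsen_factor
    iy = np.arange(ny)
    ix = np.arange(nx)
    pat = np.sin(2 * np.pi * iy[:, None] * 2.0 / f) * np.cos(2 * np.pi * ix[None, :] * 3.0 / f)
    pat = pat + 0.4 * np.sin(2 * np.pi * (iy[:, None] + ix[None, :]) * 1.0 / f)
    return config.fine_scale_amplitude * pat


def _seasonal(config: SyntheticConfig, times: np.ndarray) -> np.ndarray:
    months = pd.DatetimeIndex(times).month.values
    return config.seasonal_amplitude * np.cos(2 * np.pi * (months - 8) / 12.0)


def _ar1_noise(rng: np.random.Generator, shape: tuple, coef: float, std: float) -> np.ndarray:
    """AR(1) noise in time with stationary standard deviation ``std``."""
    nt = shape[0]
    out = np.empty(shape)
    if std == 0:
        out[:] = 0.0
        return out
    innov_std = std * np.sqrt(1.0 - coef**2)
    out[0] = rng.normal(0.0, std, size=shape[1:])
    eps = rng.normal(0.0, innov_std, size=(nt - 1,) + shape[1:])
    for t in range(1, nt):
        out[t] = coef * out[t - 1] + eps[t - 1]
    return out


def _trend_component(
    config: SyntheticConfig, times: np.ndarray, scenario: str | None
) -> np.ndarray:
    """Piecewise-linear trend: the historical slope up to the end of the
    historical window, then the scenario slope (continuous join)."""
    frac = fractional_years(times)
    t0 = config.hist_years[0]
    t_break = config.hist_years[1] + 1  # trend switches after the last historical year
    hist_slope = config.reference_trend / 10.0  # per year
    out = hist_slope * (frac - t0)
    if scenario is not None:
        if scenario not in config.scenario_trends:
            raise ValidationError(
                f"unknown scenario {scenario!r}; expected one of {sorted(config.scenario_trends)}"
            )
        scen_slope = config.scenario_trends[scenario] / 10.0
        after = frac > t_break
        out = np.where(
            after, hist_slope * (t_break - t0) + scen_slope * (frac - t_break), out
        )
    return out


def _bias_map(config: SyntheticConfig, grid: Grid) -> np.ndarray:
    if config.bias_pattern == "constant":
        return np.full(grid.shape, config.member_bias)
    if config.bias_pattern == "gradient":
        ramp = np.linspace(0.5, 1.5, grid.shape[1])
        return config.member_bias * np.ones(grid.shape) * ramp[None, :]
    raise ValidationError(f"unknown bias pattern {config.bias_pattern!r}")


def make_reference(config: SyntheticConfig) -> tuple[GriddedField, SyntheticTruth]:
    """Fine-grid historical reference field plus the injected truth."""
    grid = _fine_grid(config)
    times = monthly_range(config.hist_years[0], 1, config.hist_years[1], 12)
    large = _large_scale(config, grid.lats, grid.lons)
    fine = _fine_scale(config)
    seasonal = _seasonal(config, times)
    trend = _trend_component(config, times, scenario=None)
    rng = _rng(config, "reference")
    noise = _ar1_noise(rng, (times.size,) + grid.shape, config.ar1_coef, config.noise_std)
    values = (
        (large + fine)[None, :, :]
        + seasonal[:, None, None]
        + trend[:, None, None]
        + noise
    )
    field = GriddedField(
        grid=grid,
        variable=config.variable,
        units=config.units,
        depth_label=config.depth_label,
        times=times,
        values=values,
        attrs={"source": "synthetic reference"},
    )
    truth = SyntheticTruth(
        fine_pattern=fine,
        bias_map=_bias_map(config, coarse_grid(config)),
        scenario_trends=dict(config.scenario_trends),
        reference_trend=config.reference_trend,
        variance_inflation=config.variance_inflation,
        noise_std=config.noise_std,
    )
    return field, truth


def make_member(
    config: SyntheticConfig, member_id: str, scenario: str
) -> tuple[GriddedField, SyntheticTruth]:
    """Coarse-grid member covering historical + projection for a scenario."""
    if scenario not in config.scenario_trends:
        raise ValidationError(
            f"unknown scenario {scenario!r}; expected one of {sorted(config.scenario_trends)}"
        )
    grid = coarse_grid(config)
    times = monthly_range(config.hist_years[0], 1, config.proj_end_year, 12)
    large = _large_scale(config, grid.lats, grid.lons)
    seasonal = _seasonal(config, times)
    trend = _trend_component(config, times, scenario=scenario)
    bias = _bias_map(config, grid)
    rng = _rng(config, "member", member_id, scenario)
    member_std = config.noise_std * np.sqrt(config.variance_inflation)
    noise = _ar1_noise(rng, (times.size,) + grid.shape, config.ar1_coef, member_std)
    values = (
        (large + bias)[None, :, :]
        + seasonal[:, None, None]
        + trend[:, None, None]
        + noise
    )
    field = GriddedField(
        grid=grid,
        variable=config.variable,
        units=config.units,
        depth_label=config.depth_label,
        times=times,
        values=values,
        attrs={"source": "synthetic member", "member_id": member_id, "scenario": scenario},
    )
    truth = SyntheticTruth(
        fine_pattern=_fine_scale(config),
        bias_map=bias,
        scenario_trends=dict(config.scenario_trends),
        reference_trend=config.reference_trend,
        variance_inflation=config.variance_inflation,
        noise_std=config.noise_std,
    )
    return field, truth


def make_observations(
    reference: GriddedField,
    n: int,
    noise_std: float = 0.2,
    seed: int = 0,
    depth: float = 5.0,
    off_node_fraction: float = 0.0,
    off_node_distance_m: float = 150.0,
) -> list[ObsRecord]:
    """Point observations sampled from the reference at grid nodes.

    ``off_node_fraction`` of the records are displaced ``off_node_distance_m``
    metres in latitude (default 150 m, beyond the 100 m matching tolerance)
    so matching rejection paths can be exercised.
    """
    if n < 1:
        raise ValidationError("need at least one observation")
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), zlib.crc32(b"obs")]))
    valid = reference.grid.mask & np.any(np.isfinite(reference.values), axis=0)
    gy, gx = np.nonzero(valid)
    picks = rng.integers(0, gy.size, size=n)
    tidx = rng.integers(0, reference.times.size, size=n)
    noise = rng.normal(0.0, noise_std, size=n) if noise_std > 0 else np.zeros(n)
    n_off = int(round(off_node_fraction * n))
    off = np.zeros(n, dtype=bool)
    if n_off:
        off[rng.choice(n, size=n_off, replace=False)] = True
    dlat = off_node_distance_m / 111_195.0  # metres -> degrees latitude
    records = []
    for i in range(n):
        iy, ix = gy[picks[i]], gx[picks[i]]
        lat = reference.grid.lats[iy] + (dlat if off[i] else 0.0)
        records.append(
            ObsRecord(
                lon=float(reference.grid.lons[ix]),
                lat=float(lat),
                depth=depth,
                time=pd.Timestamp(reference.times[tidx[i]]),
                value=float(reference.values[tidx[i], iy, ix] + noise[i]),
                source="synthetic",
            )
        )
    return records


def make_ensemble_suite(
    config: SyntheticConfig,
    n_models: int = 2,
    realizations_per_model: int = 2,
    scenarios: tuple[str, ...] = ("ssp126", "ssp245", "ssp585"),
) -> tuple[dict[str, list[tuple[str, GriddedField]]], SyntheticTruth]:
    """Full factorial member set: scenario -> [(member_id, field), ...]."""
    if n_models < 1:
        raise ValidationError("need at least one model")
    if not scenarios:
        raise ValidationError("need at least one scenario")
    suite: dict[str, list[tuple[str, GriddedField]]] = {}
    truth = None
    for scenario in scenarios:
        members = []
        for m in range(n_models):
            for r in range(realizations_per_model):
                member_id = f"model{m + 1}_r{r + 1}"
                field, truth = make_member(config, member_id, scenario)
                members.append((member_id, field))
        suite[scenario] = members
    return suite, truth


def expected_scenario_change(
    config: SyntheticConfig,
    scenario: str,
    future_period: tuple[int, int],
    present_period: tuple[int, int],
) -> float:
    """Closed-form change injected by the piecewise trend (no noise):
    mean trend over the future slice minus mean trend over the present."""
    def slice_mean(period):
        times = monthly_range(period[0], 1, period[1], 12)
        return _trend_component(config, times, scenario=scenario).mean()

    return float(slice_mean(future_period) - slice_mean(present_period))
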