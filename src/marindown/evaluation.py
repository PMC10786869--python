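"""Skill assessment against gridded climatologies and point observations.

Gridded skill uses three metrics on each seasonal climatology field —
the ratio of spatial means alpha, the ratio of spatial standard deviations
beta, and the spatial Pearson correlation rho — combined into the Liu-mean
efficiency score

    LSE = 1 - sqrt((rho * alpha - 1)^2 + (beta - 1)^2),

which is 1 for a perfect comparison and decreases (without bound, no
clamping) as correlation, bias or spread degrade. Temperature is scored on
the Kelvin scale: the ratio-of-means alpha is ill-behaved near 0 degC.

Point observations are matched to the nearest grid node within a horizontal
great-circle tolerance (default 100 m) and a vertical tolerance (default
1 m). Timestamps are deliberately not matched: all observations in the
comparison period are pooled against the model's climatological
distribution at the matched cells, so the comparison is agnostic with
respect to seasonality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DomainError, ValidationError
from .grids import EARTH_RADIUS_M, GriddedField, _lonlat_to_xyz
from .timeutils import select_period, year_month

logger = logging.getLogger(__name__)

SEASONS = {"DJF": (12, 1, 2), "MAM": (3, 4, 5), "JJA": (6, 7, 8), "SON": (9, 10, 11)}
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class SkillScore:
    alpha: float
    beta: float
    rho: float
    lse: float
    season: str


@dataclass
class ObsRecord:
    lon: float
    lat: float
    depth: float
    time: object
    value: float
    source: str = "synthetic"

    def __post_init__(self):
        if not (np.isfinite(self.lon) and np.isfinite(self.lat)):
            raise ValidationError("observation coordinates must be finite")
        if self.depth < 0:
            raise ValidationError("observation depth must be non-negative")


@dataclass
class MatchedPairs:
    """Observation/model pairs passing the proximity criteria.

    ``model_values`` holds the period climatological mean at each matched
    cell; ``model_samples`` pools every monthly model value at the matched
    cells within the comparison period (the distribution the observations
    are compared against).
    """

    obs_values: np.ndarray
    obs_depths: np.ndarray
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    model_values: np.ndarray
    model_samples: np.ndarray
    product_depth: float

    def __len__(self) -> int:
        return self.obs_values.size


def seasonal_climatology(field: GriddedField, period: tuple[int, int]) -> dict[str, GriddedField]:
    """Mean field per meteorological season (DJF/MAM/JJA/SON) over
    calendar years ``period`` (inclusive)."""
    y0, y1 = int(period[0]), int(period[1])
    sel = select_period(field.times, y0, y1)
    years, months = year_month(field.times)
    out = {}
    for season, season_months in SEASONS.items():
        msel = sel & np.isin(months, season_months)
        if not msel.any():
            raise ValidationError(f"period {period} has no {season} months")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-land columns
            clim = np.nanmean(field.values[msel], axis=0)
        out[season] = field.copy_with(
            times=field.times[msel][:1],
            values=clim[None, :, :],
            attrs={**field.attrs, "season": season, "climatology_period": f"{y0}-{y1}"},
        )
    return out


def lse(rho: float, alpha: float, beta: float) -> float:
    """Liu-mean efficiency: 1 - sqrt((rho*alpha - 1)^2 + (beta - 1)^2)."""
    if not (np.isfinite(rho) and np.isfinite(alpha) and np.isfinite(beta)):
        raise ValidationError("lse requires finite rho, alpha, beta")
    return float(1.0 - np.sqrt((rho * alpha - 1.0) ** 2 + (beta - 1.0) ** 2))


def _metrics(model: np.ndarray, obs: np.ndarray, weights: np.ndarray | None) -> tuple[float, float, float]:
    if weights is None:
        weights = np.ones_like(obs)
    w = weights / weights.sum()
    m_mean = float(np.dot(w, model))
    o_mean = float(np.dot(w, obs))
    m_std = float(np.sqrt(np.dot(w, (model - m_mean) ** 2)))
    o_std = float(np.sqrt(np.dot(w, (obs - o_mean) ** 2)))
    if o_mean == 0.0 or o_std == 0.0:
        raise DomainError("observed field has zero mean or zero spatial variance")
    cov = float(np.dot(w, (model - m_mean) * (obs - o_mean)))
    if m_std == 0.0:
        raise DomainError("model field has zero spatial variance")
    return m_mean / o_mean, m_std / o_std, cov / (m_std * o_std)


def _season_skill(model: GriddedField, obs: GriddedField, season: str, cos_lat_weights: bool) -> SkillScore:
    mv = model.values[0]
    ov = obs.values[0]
    ok = np.isfinite(mv) & np.isfinite(ov)
    if ok.sum() < 3:
        raise DomainError("fewer than 3 jointly valid cells")
    if model.variable == "temperature":
        mv = mv + KELVIN_OFFSET
        ov = ov + KELVIN_OFFSET
    weights = None
    if cos_lat_weights:
        weights = np.cos(np.radians(model.grid.lats))[:, None] * np.ones(model.grid.shape)
        weights = weights[ok]
    alpha, beta, rho = _metrics(mv[ok], ov[ok], weights)
    return SkillScore(alpha=alpha, beta=beta, rho=rho, lse=lse(rho, alpha, beta), season=season)


def spatial_skill(
    model_clim: dict[str, GriddedField] | GriddedField,
    obs_clim: dict[str, GriddedField] | GriddedField,
    period: tuple[int, int] | None = None,
    cos_lat_weights: bool = False,
) -> dict[str, SkillScore]:
    """Seasonal skill scores plus the season-averaged summary.

    Accepts either seasonal-climatology dicts (from
    :func:`seasonal_climatology`) or raw fields with a ``period`` from which
    the climatologies are computed. Temperature is scored in Kelvin. The
    ``mean`` entry averages each metric arithmetically over the four
    seasons.
    """
    if isinstance(model_clim, GriddedField):
        if period is None:
            raise ValidationError("period is required when passing raw fields")
        model_clim = seasonal_climatology(model_clim, period)
        obs_clim = seasonal_climatology(obs_clim, period)
    scores = {
        season: _season_skill(model_clim[season], obs_clim[season], season, cos_lat_weights)
        for season in SEASONS
    }
    avg = {
        metric: float(np.mean([getattr(scores[s], metric) for s in SEASONS]))
        for metric in ("alpha", "beta", "rho", "lse")
    }
    scores["mean"] = SkillScore(season="mean-of-seasons", **avg)
    return scores


def match_observations(
    obs: list[ObsRecord],
    product: GriddedField,
    product_depth: float,
    h_tol: float = 100.0,
    v_tol: float = 1.0,
    period: tuple[int, int] | None = None,
) -> MatchedPairs:
    """Pair observations with the nearest ocean grid node.

    A record matches iff its great-circle distance to the nearest valid node
    is <= ``h_tol`` metres and its depth is within ``v_tol`` metres of
    ``product_depth``. Records outside ``period`` (calendar years) are
    dropped before matching. Output is independent of record order.
    """
    if not obs:
        raise ValidationError("no observation records supplied")
    vals = product.values
    if period is not None:
        sel = select_period(product.times, *map(int, period))
        vals = vals[sel]
        years = pd.DatetimeIndex([pd.Timestamp(r.time) for r in obs]).year.values
        keep = (years >= int(period[0])) & (years <= int(period[1]))
        obs = [r for r, k in zip(obs, keep) if k]
        if not obs:
            logger.warning("no observations fall inside the comparison period")
            return _empty_pairs(product_depth)

    valid = product.grid.mask & np.any(np.isfinite(vals), axis=0)
    if not valid.any():
        raise DomainError("product has no valid cells")
    gy, gx = np.nonzero(valid)
    tree = cKDTree(_lonlat_to_xyz(product.grid.lons[gx], product.grid.lats[gy]))

    lons = np.array([r.lon for r in obs])
    lats = np.array([r.lat for r in obs])
    depths = np.array([r.depth for r in obs])
    values = np.array([r.value for r in obs])
    chord, idx = tree.query(_lonlat_to_xyz(lons, lats), k=1)
    dist = EARTH_RADIUS_M * 2 * np.arcsin(np.minimum(1.0, chord / 2.0))
    matched = (dist <= h_tol) & (np.abs(depths - product_depth) <= v_tol)
    if not matched.any():
        logger.warning("no observations matched within %.0f m / %.1f m tolerances", h_tol, v_tol)
        return _empty_pairs(product_depth)

    rows = gy[idx[matched]]
    cols = gx[idx[matched]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-land columns
        clim_mean = np.nanmean(vals, axis=0)
    cells = sorted(set(zip(rows.tolist(), cols.tolist())))
    samples = np.concatenate([vals[:, r, c] for r, c in cells])
    samples = samples[np.isfinite(samples)]
    return MatchedPairs(
        obs_values=values[matched],
        obs_depths=depths[matched],
        cell_rows=rows,
        cell_cols=cols,
        model_values=clim_mean[rows, cols],
        model_samples=samples,
        product_depth=product_depth,
    )


def _empty_pairs(product_depth: float) -> MatchedPairs:
    empty = np.array([])
    return MatchedPairs(empty, empty, empty.astype(int), empty.astype(int), empty, empty, product_depth)


@dataclass
class DistributionSummary:
    value_bins: np.ndarray
    obs_value_freq: np.ndarray
    model_value_freq: np.ndarray
    depth_bins: np.ndarray
    obs_depth_freq: np.ndarray
    overlap: float  # overlap coefficient of the value histograms, in [0, 1]


def distribution_summary(pairs: MatchedPairs, n_bins: int = 20) -> DistributionSummary:
    """Binned observed-vs-model value distributions and their overlap.

    The overlap coefficient is the shared area of the two normalized value
    histograms on a common binning: 1 for identical samples, 0 for disjoint
    value ranges.
    """
    if len(pairs) == 0 or pairs.model_samples.size == 0:
        raise ValidationError("no matched pairs to summarize")
    combined = np.concatenate([pairs.obs_values, pairs.model_samples])
    edges = np.histogram_bin_edges(combined, bins=n_bins)
    obs_freq, _ = np.histogram(pairs.obs_values, bins=edges)
    mod_freq, _ = np.histogram(pairs.model_samples, bins=edges)
    p = obs_freq / obs_freq.sum()
    q = mod_freq / mod_freq.sum()
    overlap = float(np.minimum(p, q).sum())
    depth_edges = np.histogram_bin_edges(pairs.obs_depths, bins=min(n_bins, max(1, len(pairs))))
    depth_freq, _ = np.histogram(pairs.obs_depths, bins=depth_edges)
    return DistributionSummary(
        value_bins=edges,
        obs_value_freq=obs_freq,
        model_value_freq=mod_freq,
        depth_bins=depth_edges,
        obs_depth_freq=depth_freq,
        overlap=overlap,
    )


def skill_table(scores_by_product: dict[str, dict[str, SkillScore]]) -> pd.DataFrame:
    """Long-format skill table (product x season x metric)."""
    rows = []
    for product, scores in scores_by_product.items():
        for season, sc in scores.items():
            rows.append(
                {"product": product, "season": season, "alpha": sc.alpha,
                 "beta": sc.beta, "rho": sc.rho, "lse": sc.lse}
            )
    return pd.DataFrame(rows)


def read_observations(path) -> list[ObsRecord]:
    """Read point observations from delimited text
    (columns lon, lat, depth, time, value[, source])."""
    df = pd.read_csv(path)
    required = {"lon", "lat", "depth", "time", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing observation columns {sorted(missing)}")
    return [
        ObsRecord(
            lon=float(r.lon), lat=float(r.lat), depth=float(r.depth),
            time=pd.Timestamp(r.time), value=float(r.value),
            source=str(getattr(r, "source", "unknown")),
        )
        for r in df.itertuples()
    ]


def write_observations(obs: list[ObsRecord], path) -> None:
    pd.DataFrame(
        {
            "lon": [r.lon for r in obs],
            "lat": [r.lat for r in obs],
            "depth": [r.depth for r in obs],
            "time": [pd.Timestamp(r.time).isoformat() for r in obs],
            "value": [r.value for r in obs],
            "source": [r.source for r in obs],
        }
    ).to_csv(path, index=False)
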