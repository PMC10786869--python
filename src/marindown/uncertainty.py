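"""Time-slice change maps, three-source uncertainty, and basin series.

Changes are future-slice mean minus present-slice mean of the ensemble
mean. Each change is compared with three uncertainty ranges via the ratio
|change| / uncertainty; a change is considered significant where the ratio
exceeds 1:

* scenario uncertainty — min-max range across the per-scenario ensemble-mean
  changes;
* model uncertainty — min-max range across per-realization changes under the
  baseline scenario;
* internal variability — max minus min of the detrended annual-mean series
  of the baseline ensemble mean, the trend being removed with a centred
  21-year running mean (residuals only where the full window fits).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grids import GriddedField
from .timeutils import select_period, year_month

logger = logging.getLogger(__name__)

PRESENT_PERIOD = (1995, 2014)
MID_TERM = (2041, 2060)
LONG_TERM = (2081, 2100)
RUNNING_MEAN_YEARS = 21


@dataclass
class ChangeAssessment:
    change: GriddedField
    internal_var: GriddedField
    model_unc: GriddedField
    scenario_unc: GriddedField
    ratio_internal: GriddedField
    ratio_model: GriddedField
    ratio_scenario: GriddedField
    horizon: tuple[int, int]
    baseline: tuple[int, int]


@dataclass
class BasinSeries:
    times: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray


def _period_mean(field: GriddedField, period: tuple[int, int]) -> np.ndarray:
    sel = select_period(field.times, int(period[0]), int(period[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-land columns
        return np.nanmean(field.values[sel], axis=0)


def change_map(
    ensemble_mean: GriddedField,
    future_period: tuple[int, int],
    present_period: tuple[int, int] = PRESENT_PERIOD,
) -> GriddedField:
    """Per-cell time-mean(future) − time-mean(present)."""
    fut = _period_mean(ensemble_mean, future_period)
    pres = _period_mean(ensemble_mean, present_period)
    return ensemble_mean.copy_with(
        times=ensemble_mean.times[:1],
        values=(fut - pres)[None, :, :],
        attrs={
            **ensemble_mean.attrs,
            "change_future": f"{future_period[0]}-{future_period[1]}",
            "change_present": f"{present_period[0]}-{present_period[1]}",
        },
    )


def minmax_range(fields: list[GriddedField]) -> GriddedField:
    """Per-cell max − min across a list of fields on one grid."""
    if not fields:
        raise ValidationError("minmax_range needs at least one field")
    first = fields[0]
    for f in fields[1:]:
        if not f.grid.same_coords(first.grid):
            raise ValidationError("fields must share one grid")
        if f.values.shape != first.values.shape:
            raise ValidationError("fields must share one shape")
    stack = np.stack([f.values for f in fields], axis=0)
    rng = stack.max(axis=0) - stack.min(axis=0)
    return first.copy_with(values=rng)


def annual_means(field: GriddedField) -> tuple[np.ndarray, np.ndarray]:
    """Calendar-year means; years with fewer than 12 months are dropped.

    Returns (years, values) with values shaped (year, lat, lon).
    """
    years, _ = year_month(field.times)
    uniq = np.unique(years)
    keep, out = [], []
    for y in uniq:
        sel = years == y
        if sel.sum() < 12:
            continue
        keep.append(y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-land columns
            out.append(np.nanmean(field.values[sel], axis=0))
    if not keep:
        raise ValidationError("no complete calendar years in the series")
    return np.asarray(keep), np.stack(out, axis=0)


def internal_variability(
    ensemble_mean: GriddedField, window: int = RUNNING_MEAN_YEARS
) -> GriddedField:
    """Max − min of running-mean-detrended annual means, per cell.

    The centred running mean of ``window`` years is evaluated only on the
    interior where the full window fits (the first and last
    ``window // 2`` years carry no residual), so a purely linear trend
    leaves exactly zero residual.
    """
    years, ann = annual_means(ensemble_mean)
    n = years.size
    if n < window:
        raise ValidationError(f"need at least {window} complete years, have {n}")
    half = window // 2
    kernel = np.ones(window) / window
    ny, nx = ensemble_mean.grid.shape
    flat = ann.reshape(n, -1)
    run = np.apply_along_axis(lambda col: np.convolve(col, kernel, mode="valid"), 0, flat)
    resid = flat[half : n - half] - run
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rng = np.nanmax(resid, axis=0) - np.nanmin(resid, axis=0)
    rng = rng.reshape(ny, nx)
    return ensemble_mean.copy_with(
        times=ensemble_mean.times[:1],
        values=rng[None, :, :],
        attrs={**ensemble_mean.attrs, "internal_variability_window_years": window},
    )


def significance_ratio(
    change: GriddedField, uncertainty: GriddedField
) -> tuple[GriddedField, np.ndarray]:
    """|change| / uncertainty plus a boolean significance mask (ratio > 1).

    Cells with zero uncertainty are missing in the ratio (with a warning
    when the change there is nonzero); the mask is False there.
    """
    if not change.grid.same_coords(uncertainty.grid):
        raise ValidationError("change and uncertainty must share one grid")
    c = change.values
    u = uncertainty.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(u > 0, np.abs(c) / np.where(u > 0, u, 1.0), np.nan)
    degenerate = (u == 0) & (c != 0) & np.isfinite(c)
    if degenerate.any():
        logger.warning(
            "%d cells have nonzero change but zero uncertainty; ratio set missing",
            int(degenerate.sum()),
        )
    mask = np.where(np.isfinite(ratio), ratio > 1.0, False)
    out = change.copy_with(values=ratio, units="1",
                           attrs={**change.attrs, "ratio": "abs(change)/uncertainty"})
    return out, mask


def basin_series(stats, mask: np.ndarray) -> BasinSeries:
    """Unweighted basin-mean series of the ensemble mean with the
    2.5/97.5-percentile envelope averaged over the same cells."""
    mask = np.asarray(mask, dtype=bool)
    base = stats.mean
    if mask.shape != base.grid.shape:
        raise ValidationError("basin mask shape must match the grid")
    effective = mask & base.grid.mask
    if not effective.any():
        raise ValidationError("basin mask selects no valid ocean cells")

    def _avg(field: GriddedField) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-land columns
            return np.nanmean(field.values[:, effective], axis=1)

    return BasinSeries(times=base.times, mean=_avg(base), lo=_avg(stats.p2_5), hi=_avg(stats.p97_5))


def assess_changes(
    scenario_ensemble_means: dict[str, GriddedField],
    baseline_member_fields: list[GriddedField],
    baseline_scenario: str,
    horizon: tuple[int, int],
    present_period: tuple[int, int] = PRESENT_PERIOD,
    window: int = RUNNING_MEAN_YEARS,
) -> ChangeAssessment:
    """Full three-source assessment for one horizon.

    ``scenario_ensemble_means`` maps scenario label to that scenario's
    ensemble-mean field; ``baseline_member_fields`` are the individual
    downscaled realizations under the baseline scenario.
    """
    if baseline_scenario not in scenario_ensemble_means:
        raise ValidationError(f"baseline scenario {baseline_scenario!r} missing from ensemble means")
    base_mean = scenario_ensemble_means[baseline_scenario]
    change = change_map(base_mean, horizon, present_period)

    scen_changes = [
        change_map(f, horizon, present_period) for f in scenario_ensemble_means.values()
    ]
    scenario_unc = minmax_range(scen_changes)
    if len(scenario_ensemble_means) == 1:
        logger.warning("single scenario: scenario uncertainty range is identically 0")

    member_changes = [change_map(f, horizon, present_period) for f in baseline_member_fields]
    model_unc = minmax_range(member_changes)

    internal = internal_variability(base_mean, window=window)

    ratio_i, _ = significance_ratio(change, internal)
    ratio_m, _ = significance_ratio(change, model_unc)
    ratio_s, _ = significance_ratio(change, scenario_unc)
    return ChangeAssessment(
        change=change,
        internal_var=internal,
        model_unc=model_unc,
        scenario_unc=scenario_unc,
        ratio_internal=ratio_i,
        ratio_model=ratio_m,
        ratio_scenario=ratio_s,
        horizon=horizon,
        baseline=present_period,
    )
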