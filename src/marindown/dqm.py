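"""Detrended quantile mapping (DQM): bias correction and downscaling.

The correction is trained per cell (and, by default, per calendar month)
between a model historical series and a reference historical series:

1. a scaling factor equalizes the historical means (additive offset, or
   ratio for strictly positive variables);
2. both series are detrended with an ordinary-least-squares linear fit
   against time in fractional years (mean-preserving: only the slope
   component is removed);
3. per-quantile adjustment factors are the differences (or ratios) between
   the detrended reference and detrended scaled-model quantiles at a fixed
   probability grid.

Application to any series (historical or projection): scale it, remove its
own OLS linear trend while re-centering on the trained historical level
(so projected values land inside the trained quantile range), correct each
value by the adjustment interpolated at its position within the trained
model quantiles (constant beyond the outermost quantiles), and add the
removed trend back. Removing and re-adding the series' own trend is what
makes the mapping "detrended": the model's long-term climate-change signal
passes through the correction untouched while the distribution of the
variability around it is aligned with the reference.

For multiplicative mode the detrending is ratio-to-trend-line (values are
divided by the normalized fitted line), which keeps corrected
concentrations positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .grids import GriddedField, idw_extrapolate, regrid_bilinear
from .timeutils import fractional_years, select_period, year_month

DEFAULT_N_QUANTILES = 100


@dataclass
class Series:
    """Per-cell monthly time series; NaN marks missing."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "ns")):
            raise ValidationError("times must be strictly increasing")


@dataclass(frozen=True)
class TrendModel:
    """OLS linear trend: value ≈ intercept + slope·(t − ref) with t in
    fractional years and ref the mean fit time, so the intercept equals the
    fitted sample mean and removing only the slope component preserves it."""

    slope: float  # variable units per year
    intercept: float
    ref_frac: float  # fractional-year origin (mean time of the fit sample)

    def line(self, frac_years: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * (frac_years - self.ref_frac)

    def anomaly(self, frac_years: np.ndarray) -> np.ndarray:
        """The removable component: slope·(t − ref)."""
        return self.slope * (frac_years - self.ref_frac)


def _fit_trend_arrays(frac: np.ndarray, values: np.ndarray) -> TrendModel:
    ok = np.isfinite(values)
    if not ok.any():
        raise ValidationError("cannot fit a trend to an all-missing series")
    t = frac[ok]
    v = values[ok]
    if np.unique(t).size < 2:
        raise ValidationError("cannot fit a trend: fewer than 2 distinct time points")
    tm = t.mean()
    dt = t - tm
    slope = float(np.dot(dt, v - v.mean()) / np.dot(dt, dt))
    return TrendModel(slope=slope, intercept=float(v.mean()), ref_frac=float(tm))


def fit_linear_trend(series: Series) -> TrendModel:
    """Ordinary-least-squares linear trend of a monthly series.

    The residuals ``values - anomaly(times)`` have zero OLS slope by
    construction. At least 24 non-missing months are recommended for a
    stable estimate; the hard requirement is two distinct valid time points.
    """
    return _fit_trend_arrays(fractional_years(series.times), series.values)


def quantile_probs(n_quantiles: int) -> np.ndarray:
    """Equally spaced probability grid (k+0.5)/n, e.g. 0.005..0.995 for 100."""
    if n_quantiles < 2:
        raise ValidationError("n_quantiles must be at least 2")
    return (np.arange(n_quantiles) + 0.5) / n_quantiles


@dataclass
class DQMTransform:
    """Trained per-cell quantile correction (see module docstring).

    ``model_center`` is the mean of the detrended, scaled training series —
    the level the detrended projection is re-centered on before the
    quantile adjustment is looked up.
    """

    mode: str  # "additive" | "multiplicative"
    scaling: float
    probs: np.ndarray
    adjustments: np.ndarray
    model_quantiles: np.ndarray  # detrended scaled-model quantiles at probs
    model_center: float
    training_window: tuple  # (first, last) training timestamps
    month: object = "all"  # calendar month 1..12 or "all"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.adjustments = np.asarray(self.adjustments, dtype=float)
        self.model_quantiles = np.asarray(self.model_quantiles, dtype=float)
        if self.mode not in ("additive", "multiplicative"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if np.any(np.diff(self.probs) <= 0):
            raise ValidationError("probs must be strictly increasing")
        if np.any(np.diff(self.model_quantiles) < 0):
            raise ValidationError("model_quantiles must be non-decreasing")

    def correct(self, detrended: np.ndarray) -> np.ndarray:
        """Quantile-wise adjustment of detrended, scaled, re-centered values.

        The adjustment is linearly interpolated at the value's position
        within the trained model quantiles and held constant beyond the
        outermost trained quantiles.
        """
        adj = np.interp(detrended, self.model_quantiles, self.adjustments)
        if self.mode == "additive":
            return detrended + adj
        return detrended * adj


def _month_selector(months: np.ndarray, month) -> np.ndarray:
    if month == "all":
        return np.ones(months.shape, dtype=bool)
    month = int(month)
    if not 1 <= month <= 12:
        raise ValidationError(f"month must be 1..12 or 'all', got {month}")
    return months == month


def _fit_dqm_arrays(
    m_frac: np.ndarray,
    m_vals: np.ndarray,
    r_frac: np.ndarray,
    r_vals: np.ndarray,
    n_quantiles: int,
    mode: str,
    month,
    window: tuple,
) -> DQMTransform:
    probs = quantile_probs(n_quantiles)
    mok, rok = np.isfinite(m_vals), np.isfinite(r_vals)
    if not mok.any() or not rok.any():
        raise ValidationError("training series are all-missing")
    m_mean = m_vals[mok].mean()
    r_mean = r_vals[rok].mean()

    if mode == "additive":
        scaling = r_mean - m_mean
        scaled = m_vals + scaling
    elif mode == "multiplicative":
        if np.any(m_vals[mok] <= 0) or np.any(r_vals[rok] <= 0):
            raise DomainError("multiplicative mode requires strictly positive training data")
        scaling = r_mean / m_mean
        scaled = m_vals * scaling
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    m_trend = _fit_trend_arrays(m_frac, scaled)
    r_trend = _fit_trend_arrays(r_frac, r_vals)
    if mode == "additive":
        m_det = scaled - m_trend.anomaly(m_frac)
        r_det = r_vals - r_trend.anomaly(r_frac)
    else:
        m_line = m_trend.line(m_frac)
        r_line = r_trend.line(r_frac)
        if np.any(m_line[mok] <= 0) or np.any(r_line[rok] <= 0):
            raise DomainError("fitted trend line crosses zero; multiplicative detrending undefined")
        m_det = scaled * (m_trend.intercept / m_line)
        r_det = r_vals * (r_trend.intercept / r_line)

    mq = np.quantile(m_det[mok], probs, method="linear")
    rq = np.quantile(r_det[rok], probs, method="linear")
    mq = np.maximum.accumulate(mq)  # guard against fp non-monotonicity
    adjustments = rq - mq if mode == "additive" else rq / mq
    return DQMTransform(
        mode=mode,
        scaling=float(scaling),
        probs=probs,
        adjustments=adjustments,
        model_quantiles=mq,
        model_center=float(m_det[mok].mean()),
        training_window=window,
        month=month,
    )


def fit_dqm(
    model_hist: Series,
    ref_hist: Series,
    n_quantiles: int = DEFAULT_N_QUANTILES,
    mode: str = "additive",
    month="all",
) -> DQMTransform:
    """Train a DQM transform between historical model and reference series."""
    _, m_months = year_month(model_hist.times)
    _, r_months = year_month(ref_hist.times)
    msel = _month_selector(m_months, month)
    rsel = _month_selector(r_months, month)
    if not msel.any() or not rsel.any():
        raise ValidationError(f"no samples in calendar month {month}")
    window = (model_hist.times[msel][0], model_hist.times[msel][-1])
    return _fit_dqm_arrays(
        fractional_years(model_hist.times)[msel],
        model_hist.values[msel],
        fractional_years(ref_hist.times)[rsel],
        ref_hist.values[rsel],
        n_quantiles,
        mode,
        month,
        window,
    )


def _fit_trend_or_flat(frac: np.ndarray, values: np.ndarray) -> TrendModel:
    """OLS trend, degrading to a flat line when a segment is too short."""
    ok = np.isfinite(values)
    t = frac[ok]
    if np.unique(t).size < 2:
        return TrendModel(slope=0.0, intercept=float(values[ok].mean()), ref_frac=float(t.mean()))
    return _fit_trend_arrays(frac, values)


def _apply_segment(transform: DQMTransform, frac: np.ndarray, v: np.ndarray) -> np.ndarray:
    ok = np.isfinite(v)
    if not ok.any():
        return np.full_like(v, np.nan)
    c = transform.model_center
    if transform.mode == "additive":
        scaled = v + transform.scaling
        trend = _fit_trend_or_flat(frac, scaled)
        line = trend.line(frac)
        det = scaled - line + c
        out = transform.correct(det) + line - c
    else:
        if np.any(v[ok] <= 0):
            raise DomainError("multiplicative transform applied to non-positive values")
        scaled = v * transform.scaling
        trend = _fit_trend_or_flat(frac, scaled)
        line = trend.line(frac)
        if np.any(line[ok] <= 0):
            raise DomainError("fitted trend line crosses zero; multiplicative detrending undefined")
        det = scaled * (c / line)
        out = transform.correct(det) * (line / c)
    return np.where(ok, out, np.nan)


def _apply_dqm_arrays(
    transform: DQMTransform, frac: np.ndarray, v: np.ndarray, boundary_frac: float | None
) -> np.ndarray:
    """Correct a series, treating the part inside the training window and
    the part beyond it as separate segments.

    Each segment is detrended with its own OLS line so the training-window
    part reproduces the trained alignment exactly while the projection part
    keeps its own climate-change trend.
    """
    out = np.full_like(v, np.nan)
    if boundary_frac is None:
        return _apply_segment(transform, frac, v)
    hist = frac <= boundary_frac + 1e-9
    for seg in (hist, ~hist):
        if seg.any() and np.isfinite(v[seg]).any():
            out[seg] = _apply_segment(transform, frac[seg], v[seg])
        elif seg.any():
            out[seg] = np.nan
    return out


def apply_dqm(transform: DQMTransform, projection: Series) -> Series:
    """Apply a trained DQM transform to a series (historical or projection).

    Scale, remove the series' own OLS trend (re-centered on the trained
    historical level), adjust each value by the trained quantile correction,
    re-add the trend. The part of the series inside the transform's
    training window and the part beyond it are detrended as separate
    segments, each with its own fitted line. Output times equal input
    times; missing in, missing out. Only the transform's calendar month is
    corrected; other months pass through unchanged.
    """
    _, months = year_month(projection.times)
    sel = _month_selector(months, transform.month)
    if not sel.any():
        raise ValidationError("projection has no samples in the transform's calendar month")
    frac = fractional_years(projection.times)
    boundary = fractional_years(np.asarray([transform.training_window[1]], dtype="datetime64[ns]"))[0]
    out_all = projection.values.copy()
    out_all[sel] = _apply_dqm_arrays(transform, frac[sel], projection.values[sel], boundary)
    return Series(times=projection.times, values=out_all)


# ---------------------------------------------------------------------------
# gridded drivers
# ---------------------------------------------------------------------------


def _resolve_training(times_a, times_b, training_window):
    """Boolean selectors for the shared training years on two time axes."""
    ya, _ = year_month(times_a)
    yb, _ = year_month(times_b)
    if training_window is None:
        y0 = max(ya.min(), yb.min())
        y1 = min(ya.max(), yb.max())
        if y0 > y1:
            raise ValidationError("model and reference series do not overlap in time")
    else:
        y0, y1 = int(training_window[0]), int(training_window[1])
    sa = select_period(times_a, y0, y1)
    sb = select_period(times_b, y0, y1)
    return sa, sb


def _correct_grid(
    model: GriddedField,
    ref: GriddedField,
    cell_mask: np.ndarray,
    n_quantiles: int,
    mode: str,
    per_month: bool,
    training_window,
) -> np.ndarray:
    """Per-cell fit-and-apply over a grid; returns the corrected values."""
    train_m, train_r = _resolve_training(model.times, ref.times, training_window)
    m_frac = fractional_years(model.times)
    r_frac = fractional_years(ref.times)
    _, m_months = year_month(model.times)
    _, r_months = year_month(ref.times)
    month_list = list(range(1, 13)) if per_month else ["all"]
    selectors = [
        (
            _month_selector(m_months, month),
            train_m & _month_selector(m_months, month),
            train_r & _month_selector(r_months, month),
            month,
        )
        for month in month_list
    ]
    out = model.values.copy()
    ny, nx = model.grid.shape
    for iy in range(ny):
        for ix in range(nx):
            if not cell_mask[iy, ix]:
                continue
            mv = model.values[:, iy, ix]
            rv = ref.values[:, iy, ix]
            if not np.isfinite(mv[train_m]).any() or not np.isfinite(rv[train_r]).any():
                continue
            for full_sel, fit_m, fit_r, month in selectors:
                tr = _fit_dqm_arrays(
                    m_frac[fit_m], mv[fit_m], r_frac[fit_r], rv[fit_r],
                    n_quantiles, mode, month,
                    (model.times[fit_m][0], model.times[fit_m][-1]),
                )
                boundary = m_frac[fit_m][-1]
                out[full_sel, iy, ix] = _apply_dqm_arrays(
                    tr, m_frac[full_sel], mv[full_sel], boundary
                )
    return out


def bias_correct(
    model: GriddedField,
    ref_coarse: GriddedField,
    n_quantiles: int = DEFAULT_N_QUANTILES,
    mode: str = "additive",
    per_month: bool = True,
    training_window: tuple[int, int] | None = None,
) -> GriddedField:
    """Per-cell DQM bias correction at the coarse working resolution.

    Each ocean cell is corrected independently (per calendar month by
    default) against the reference series at the same cell, training on
    ``training_window`` (calendar years, inclusive; default: the full
    model/reference overlap). Land cells and cells with an all-missing
    reference are passed through unchanged.
    """
    if not model.grid.same_coords(ref_coarse.grid):
        raise ValidationError("model and reference must share the coarse grid")
    cell_mask = model.grid.mask & ref_coarse.grid.mask
    out = _correct_grid(model, ref_coarse, cell_mask, n_quantiles, mode, per_month, training_window)
    result = model.copy_with(values=out)
    result.attrs = {**model.attrs, "bias_correction": "DQM", "dqm_mode": mode}
    return result


def downscale(
    bias_corrected_coarse: GriddedField,
    ref_fine: GriddedField,
    n_quantiles: int = DEFAULT_N_QUANTILES,
    mode: str = "additive",
    per_month: bool = True,
    training_window: tuple[int, int] | None = None,
) -> GriddedField:
    """Statistical downscaling of a bias-corrected coarse field.

    The coarse field is bilinearly regridded to the fine reference grid
    (coastal gaps filled by inverse-distance extrapolation), then a DQM
    transform is trained per fine cell between the regridded historical
    series and the fine reference series and applied to the full series.
    The fine reference is never degraded, so its sub-grid spatial structure
    is transferred onto the projection.
    """
    regridded = regrid_bilinear(bias_corrected_coarse, ref_fine.grid)
    regridded = idw_extrapolate(regridded)
    out = _correct_grid(
        regridded, ref_fine, ref_fine.grid.mask, n_quantiles, mode, per_month, training_window
    )
    result = regridded.copy_with(values=out)
    result.attrs = {**bias_corrected_coarse.attrs, "downscaling": "DQM", "dqm_mode": mode}
    return result
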