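"""Monthly time-axis helpers.

All fields in this package live on a uniform monthly axis. Timestamps are
``numpy.datetime64`` month starts; model calendars (noleap, 360-day) collapse
losslessly onto this index at monthly resolution, so a single representation
serves every input. Fractional years place each month at its midpoint,
``year + (month - 0.5) / 12``, which keeps ordinary-least-squares trend fits
symmetric within a calendar year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError


def monthly_range(start_year: int, start_month: int, end_year: int, end_month: int) -> np.ndarray:
    """Inclusive monthly axis of month-start timestamps."""
    idx = pd.date_range(
        start=f"{start_year}-{start_month:02d}-01",
        end=f"{end_year}-{end_month:02d}-01",
        freq="MS",
    )
    return idx.values


def year_month(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Calendar (year, month) integer arrays for a monthly axis."""
    idx = pd.DatetimeIndex(times)
    return idx.year.values, idx.month.values


def fractional_years(times: np.ndarray) -> np.ndarray:
    """Month-midpoint decimal years, e.g. Jan 2000 -> 2000.0417."""
    years, months = year_month(times)
    return years + (months - 0.5) / 12.0


def check_monthly(times: np.ndarray) -> None:
    """Require a strictly increasing axis with exact monthly spacing."""
    if len(times) == 0:
        raise ValidationError("time axis is empty")
    idx = pd.DatetimeIndex(times)
    if len(idx) == 1:
        return
    code = idx.year.values * 12 + idx.month.values
    step = np.diff(code)
    if not np.all(step == 1):
        raise ValidationError("time axis must be strictly increasing with monthly spacing")


def select_period(times: np.ndarray, start_year: int, end_year: int) -> np.ndarray:
    """Boolean selector for calendar years ``start_year..end_year`` inclusive."""
    years, _ = year_month(times)
    sel = (years >= start_year) & (years <= end_year)
    if not sel.any():
        raise ValidationError(
            f"period {start_year}-{end_year} does not overlap the time axis "
            f"({pd.DatetimeIndex(times)[0].year}-{pd.DatetimeIndex(times)[-1].year})"
        )
    return sel
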