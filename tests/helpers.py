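"""Independent brute-force oracles and small constructors shared by tests."""

from __future__ import annotations

import math

import numpy as np

from marindown.grids import Grid, GriddedField
from marindown.timeutils import monthly_range

EARTH_RADIUS_M = 6371.0e3


def make_grid(lats, lons, mask=None) -> Grid:
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if mask is None:
        mask = np.ones((lats.size, lons.size), dtype=bool)
    return Grid(lats, lons, np.asarray(mask, dtype=bool))


def make_field(values, lats=None, lons=None, mask=None, start=(2000, 1), variable="temperature",
               units="degC") -> GriddedField:
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None, :, :]
    nt, ny, nx = values.shape
    if lats is None:
        lats = np.arange(ny, dtype=float)
    if lons is None:
        lons = np.arange(nx, dtype=float)
    end_total = start[0] * 12 + (start[1] - 1) + nt - 1
    times = monthly_range(start[0], start[1], end_total // 12, end_total % 12 + 1)
    return GriddedField(
        grid=make_grid(lats, lons, mask),
        variable=variable,
        units=units,
        depth_label="surface",
        times=times,
        values=values,
    )


def haversine_m(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance oracle, scalar, written independently."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return EARTH_RADIUS_M * 2 * math.asin(min(1.0, math.sqrt(a)))


def idw_oracle(src_lons, src_lats, src_vals, lon, lat, k=8, power=2.0) -> float:
    """Brute-force inverse-distance estimate at one point (loop + sort)."""
    dists = [haversine_m(sl, sp, lon, lat) for sl, sp in zip(src_lons, src_lats)]
    order = sorted(range(len(dists)), key=lambda i: dists[i])[: min(k, len(dists))]
    if dists[order[0]] == 0.0:
        return float(src_vals[order[0]])
    num = den = 0.0
    for i in order:
        w = dists[i] ** (-power)
        num += w * src_vals[i]
        den += w
    return num / den


def quantile_oracle(sorted_vals: np.ndarray, p: float) -> float:
    """Linear-interpolation empirical quantile at inclusive plotting
    positions k/(n-1), written independently of numpy.quantile."""
    n = sorted_vals.size
    if n == 1:
        return float(sorted_vals[0])
    pos = p * (n - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    w = pos - lo
    return float((1 - w) * sorted_vals[lo] + w * sorted_vals[hi])


def ols_fit(frac: np.ndarray, vals: np.ndarray) -> tuple[float, float]:
    """Independent OLS (slope, value-at-mean-time) via polyfit."""
    slope, icept = np.polyfit(frac, vals, 1)
    return float(slope), float(slope * frac.mean() + icept)


def dqm_oracle(
    m_frac: np.ndarray,
    m_hist: np.ndarray,
    r_frac: np.ndarray,
    r_hist: np.ndarray,
    p_frac: np.ndarray,
    proj: np.ndarray,
    n_quantiles: int,
) -> np.ndarray:
    """Brute-force additive detrended quantile mapping, loops throughout.

    Train: offset equalizing means, per-series OLS detrend (slope only),
    empirical quantiles at probabilities (k+0.5)/n, additive adjustments.
    Apply: offset, detrend the projection re-centred on the trained model
    level, interpolate the adjustment at each value's position within the
    trained model quantiles (constant beyond the tails), re-add the trend.
    """
    offset = r_hist.mean() - m_hist.mean()
    scaled_hist = m_hist + offset
    ms, mc = ols_fit(m_frac, scaled_hist)
    rs, rc = ols_fit(r_frac, r_hist)
    m_det = np.sort(scaled_hist - ms * (m_frac - m_frac.mean()))
    r_det = np.sort(r_hist - rs * (r_frac - r_frac.mean()))
    probs = [(k + 0.5) / n_quantiles for k in range(n_quantiles)]
    mq = [quantile_oracle(m_det, p) for p in probs]
    rq = [quantile_oracle(r_det, p) for p in probs]
    adj = [r - m for r, m in zip(rq, mq)]
    center = m_det.mean()

    scaled = proj + offset
    ps, _ = ols_fit(p_frac, scaled)
    line = scaled.mean() + ps * (p_frac - p_frac.mean())
    det = scaled - line + center
    out = np.empty_like(det)
    for i, x in enumerate(det):
        if x <= mq[0]:
            a = adj[0]
        elif x >= mq[-1]:
            a = adj[-1]
        else:
            j = 0
            while not (mq[j] <= x <= mq[j + 1]):
                j += 1
            if mq[j + 1] == mq[j]:
                a = adj[j]
            else:
                w = (x - mq[j]) / (mq[j + 1] - mq[j])
                a = (1 - w) * adj[j] + w * adj[j + 1]
        out[i] = x + a
    return out + line - center
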