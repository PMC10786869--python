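"""Spatial and vertical plumbing shared by every pipeline stage.

Rectilinear latitude-longitude grids with an ocean mask, monthly gridded
fields, and depth-level stacks, plus the regridding operations the
downscaling chain needs: bilinear interpolation with valid-node weight
renormalization, block-mean coarsening, inverse-distance-weighted coastal
extrapolation, linear depth interpolation and seafloor extraction.

Conventions
-----------
* Longitudes are degrees east in [-180, 180); no antimeridian wraparound.
* Missing values are NaN. Land cells (``mask`` False) are always missing;
  ocean cells may be transiently missing (e.g. after regridding near a
  coastline) until filled by :func:`idw_extrapolate`.
* Distances are great-circle on a spherical Earth of radius 6371 km.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DomainError, ValidationError
from .timeutils import check_monthly

EARTH_RADIUS_M = 6371.0e3


def _check_increasing(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 1 or arr.size < 1:
        raise ValidationError(f"{name} must be a non-empty 1-D array")
    if arr.size > 1 and not np.all(np.diff(arr) > 0):
        raise ValidationError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class Grid:
    """Rectilinear lat-lon grid with a boolean ocean mask (True = ocean)."""

    lats: np.ndarray
    lons: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        lats = np.asarray(self.lats, dtype=float)
        lons = np.asarray(self.lons, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        _check_increasing(lats, "lats")
        _check_increasing(lons, "lons")
        if np.any(lons >= 180.0) or np.any(lons < -180.0):
            raise ValidationError("lons must lie in [-180, 180)")
        if mask.shape != (lats.size, lons.size):
            raise ValidationError(
                f"mask shape {mask.shape} does not match lats×lons {(lats.size, lons.size)}"
            )
        object.__setattr__(self, "lats", lats)
        object.__setattr__(self, "lons", lons)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.lats.size, self.lons.size

    @property
    def resolution(self) -> float:
        """Nominal grid spacing in degrees (median over both axes)."""
        steps = []
        if self.lats.size > 1:
            steps.append(np.median(np.diff(self.lats)))
        if self.lons.size > 1:
            steps.append(np.median(np.diff(self.lons)))
        return float(np.median(steps)) if steps else float("nan")

    def same_coords(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lats, other.lats)
            and np.allclose(self.lons, other.lons)
        )


@dataclass
class GriddedField:
    """Monthly values on one grid at one depth level.

    ``values`` has shape (time, lat, lon); NaN marks missing. Land cells are
    forced missing at construction.
    """

    grid: Grid
    variable: str
    units: str
    depth_label: str
    times: np.ndarray
    values: np.ndarray
    attrs: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        check_monthly(self.times)
        nt = self.times.size
        if self.values.shape != (nt,) + self.grid.shape:
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"(time, lat, lon) = {(nt,) + self.grid.shape}"
            )
        if not self.units:
            raise ValidationError("units string must be non-empty")
        # land is always missing
        self.values = np.where(self.grid.mask[None, :, :], self.values, np.nan)

    def copy_with(self, **kw) -> "GriddedField":
        return dataclasses.replace(self, **kw)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class DepthProfileStack:
    """Monthly values on (time, depth, lat, lon) with per-cell bathymetry."""

    grid: Grid
    variable: str
    units: str
    depth_levels: np.ndarray
    times: np.ndarray
    values: np.ndarray
    bathymetry: np.ndarray

    def __post_init__(self):
        self.depth_levels = np.asarray(self.depth_levels, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        _check_increasing(self.depth_levels, "depth_levels")
        check_monthly(self.times)
        expected = (self.times.size, self.depth_levels.size) + self.grid.shape
        if self.values.shape != expected:
            raise ValidationError(f"values shape {self.values.shape}, expected {expected}")
        if self.bathymetry.shape != self.grid.shape:
            raise ValidationError("bathymetry shape must match the grid")
        # cells below the local seafloor and land columns are missing; the
        # first level below the seafloor is kept so the bottom value can be
        # bracketed, deeper levels are flagged
        prev = np.concatenate([[-np.inf], self.depth_levels[:-1]])
        below = prev[None, :, None, None] >= self.bathymetry[None, None, :, :]
        self.values = np.where(below, np.nan, self.values)
        self.values = np.where(self.grid.mask[None, None, :, :], self.values, np.nan)


# ---------------------------------------------------------------------------
# horizontal operations
# ---------------------------------------------------------------------------


def _axis_weights(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bracketing lower index, linear weight toward the upper node, and an
    in-range flag for each target coordinate along one axis."""
    hi = np.clip(np.searchsorted(src, tgt, side="right"), 1, src.size - 1)
    lo = hi - 1
    w = (tgt - src[lo]) / (src[hi] - src[lo])
    inside = (tgt >= src[0]) & (tgt <= src[-1])
    return lo, w, inside


def regrid_bilinear(field: GriddedField, target: Grid) -> GriddedField:
    """Bilinear interpolation onto ``target``.

    Weights are renormalized over the valid subset of the four enclosing
    source nodes; a target node with no valid enclosing node, outside the
    source bounding box, or on target land becomes missing.
    """
    src = field.grid
    if src.lats.size < 2 or src.lons.size < 2:
        raise ValidationError("source grid needs at least 2 points per axis")
    jlo, wy, in_lat = _axis_weights(src.lats, target.lats)
    ilo, wx, in_lon = _axis_weights(src.lons, target.lons)
    if not (in_lat.any() and in_lon.any()):
        raise DomainError("target grid is disjoint from the source domain")

    v = field.values  # (nt, ny, nx)
    nt = v.shape[0]
    ny_t, nx_t = target.shape
    num = np.zeros((nt, ny_t, nx_t))
    den = np.zeros((nt, ny_t, nx_t))
    JY = jlo[:, None]
    JX = ilo[None, :]
    WY = wy[:, None]
    WX = wx[None, :]
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        w = (WY if dy else 1.0 - WY) * (WX if dx else 1.0 - WX)
        vals = v[:, JY + dy, JX + dx]
        ok = np.isfinite(vals)
        num += np.where(ok, vals, 0.0) * w[None, :, :]
        den += ok * w[None, :, :]

    with np.errstate(invalid="ignore"):
        out = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), np.nan)
    inside = in_lat[:, None] & in_lon[None, :]
    out = np.where(inside[None, :, :], out, np.nan)
    return GriddedField(
        grid=target,
        variable=field.variable,
        units=field.units,
        depth_label=field.depth_label,
        times=field.times,
        values=out,
        attrs=dict(field.attrs),
    )


def coarsen(field: GriddedField, factor: int) -> GriddedField:
    """Block-average onto a grid ``factor`` times coarser.

    Each coarse cell is the unweighted mean of its non-missing fine children;
    an all-missing block stays missing. Coarse node coordinates are the block
    means of the fine coordinates.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("factor must be a positive integer")
    factor = int(factor)
    ny, nx = field.grid.shape
    if ny % factor or nx % factor:
        raise ValidationError(
            f"factor {factor} does not divide the grid shape {(ny, nx)}"
        )
    nyc, nxc = ny // factor, nx // factor
    lats = field.grid.lats.reshape(nyc, factor).mean(axis=1)
    lons = field.grid.lons.reshape(nxc, factor).mean(axis=1)
    blocks_mask = field.grid.mask.reshape(nyc, factor, nxc, factor)
    cmask = blocks_mask.any(axis=(1, 3))
    nt = field.times.size
    blocks = field.values.reshape(nt, nyc, factor, nxc, factor)
    with np.errstate(invalid="ignore"):
        cnt = np.isfinite(blocks).sum(axis=(2, 4))
        tot = np.nansum(blocks, axis=(2, 4))
        out = np.where(cnt > 0, tot / np.where(cnt > 0, cnt, 1), np.nan)
    return GriddedField(
        grid=Grid(lats, lons, cmask),
        variable=field.variable,
        units=field.units,
        depth_label=field.depth_label,
        times=field.times,
        values=out,
        attrs=dict(field.attrs),
    )


def refine_nearest(field: GriddedField, factor: int) -> GriddedField:
    """Nearest-neighbour upsample: each fine cell copies its coarse parent.

    Fine node coordinates subdivide each coarse step uniformly (cell-centre
    convention), so ``coarsen(refine_nearest(f, k), k)`` returns ``f`` on
    valid cells.
    """
    if factor < 1 or int(factor) != factor:
        raise ValidationError("factor must be a positive integer")
    factor = int(factor)

    def _subdivide(coords: np.ndarray) -> np.ndarray:
        step = coords[1] - coords[0] if coords.size > 1 else 1.0
        offs = (np.arange(factor) - (factor - 1) / 2.0) * (step / factor)
        return (coords[:, None] + offs[None, :]).ravel()

    lats = _subdivide(field.grid.lats)
    lons = _subdivide(field.grid.lons)
    mask = np.repeat(np.repeat(field.grid.mask, factor, axis=0), factor, axis=1)
    vals = np.repeat(np.repeat(field.values, factor, axis=1), factor, axis=2)
    return GriddedField(
        grid=Grid(lats, lons, mask),
        variable=field.variable,
        units=field.units,
        depth_label=field.depth_label,
        times=field.times,
        values=vals,
        attrs=dict(field.attrs),
    )


def _lonlat_to_xyz(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    lam = np.radians(lons)
    phi = np.radians(lats)
    return np.column_stack(
        (np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi))
    )


def great_circle_distance(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres (haversine, spherical Earth)."""
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = (
        np.sin((phi2 - phi1) / 2) ** 2
        + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
    )
    return EARTH_RADIUS_M * 2 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def idw_extrapolate(
    field: GriddedField,
    target: Grid | None = None,
    n_neighbors: int = 8,
    power: float = 2.0,
) -> GriddedField:
    """Inverse-distance-weighted fill onto ``target`` (default: same grid).

    Ocean target nodes that lack a valid value receive the weighted average
    of the ``n_neighbors`` nearest valid source points with weights
    d^(-power) on great-circle distance; a node coincident with a source
    point copies it; already-valid nodes are untouched. A source cell counts
    as valid when it is finite at every time step.
    """
    if target is None:
        target = field.grid
    src = field.grid
    valid = src.mask & np.all(np.isfinite(field.values), axis=0)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise DomainError("idw_extrapolate needs at least one valid source point")

    same_grid = target.same_coords(src)
    nt = field.times.size
    if same_grid:
        out = field.values.copy()
        need = target.mask & ~valid
    else:
        out = np.full((nt,) + target.shape, np.nan)
        need = target.mask.copy()
    rows, cols = np.nonzero(need)
    if rows.size:
        sy, sx = np.nonzero(valid)
        src_xyz = _lonlat_to_xyz(src.lons[sx], src.lats[sy])
        tree = cKDTree(src_xyz)
        tgt_xyz = _lonlat_to_xyz(target.lons[cols], target.lats[rows])
        k = min(n_neighbors, n_valid)
        chord, idx = tree.query(tgt_xyz, k=k)
        chord = np.atleast_2d(chord.reshape(rows.size, k))
        idx = idx.reshape(rows.size, k)
        # chord length on the unit sphere -> great-circle metres
        dist = EARTH_RADIUS_M * 2 * np.arcsin(np.minimum(1.0, chord / 2.0))
        series = field.values[:, sy[idx], sx[idx]]  # (nt, n_need, k)
        coincident = dist[:, 0] < 1e-6
        with np.errstate(divide="ignore"):
            w = np.where(dist > 0, dist, np.inf) ** (-power)
        wsum = w.sum(axis=1)
        # coincident nodes copy the source directly; their weights can be
        # all-zero, so keep the division well-defined there
        safe = np.where(wsum > 0, wsum, 1.0)
        filled = np.einsum("tnk,nk->tn", series, w) / safe[None, :]
        filled[:, coincident] = series[:, coincident, 0]
        out[:, rows, cols] = filled
    return GriddedField(
        grid=target,
        variable=field.variable,
        units=field.units,
        depth_label=field.depth_label,
        times=field.times,
        values=out,
        attrs=dict(field.attrs),
    )


# ---------------------------------------------------------------------------
# vertical operations
# ---------------------------------------------------------------------------


def interp_to_depth(stack: DepthProfileStack, z: float, depth_label: str | None = None) -> GriddedField:
    """Linear interpolation of a depth stack to a fixed depth ``z`` (metres).

    No vertical extrapolation: ``z`` must lie within the stack's level range.
    Cells whose bathymetry is shallower than ``z`` are missing.
    """
    levels = stack.depth_levels
    if z < levels[0] or z > levels[-1]:
        raise DomainError(
            f"depth {z} m outside the level range [{levels[0]}, {levels[-1]}] m"
        )
    hi = int(np.clip(np.searchsorted(levels, z, side="right"), 1, levels.size - 1))
    lo = hi - 1
    w = (z - levels[lo]) / (levels[hi] - levels[lo])
    if w == 0.0:
        out = stack.values[:, lo].copy()
    elif w == 1.0:
        out = stack.values[:, hi].copy()
    else:
        out = (1 - w) * stack.values[:, lo] + w * stack.values[:, hi]
    out = np.where(stack.bathymetry[None, :, :] >= z, out, np.nan)
    return GriddedField(
        grid=stack.grid,
        variable=stack.variable,
        units=stack.units,
        depth_label=depth_label or f"{z:g}m",
        times=stack.times,
        values=out,
    )


def extract_bottom(stack: DepthProfileStack) -> GriddedField:
    """Value at the local seafloor: per-cell linear interpolation to the
    bathymetry depth, clamped to the deepest valid level where bathymetry
    exceeds the column's valid range. All-missing columns stay missing."""
    levels = stack.depth_levels
    nt = stack.times.size
    ny, nx = stack.grid.shape
    out = np.full((nt, ny, nx), np.nan)
    finite_col = np.all(np.isfinite(stack.values), axis=0)  # (nz, ny, nx)
    for iy in range(ny):
        for ix in range(nx):
            if not stack.grid.mask[iy, ix]:
                continue
            good = np.nonzero(finite_col[:, iy, ix])[0]
            if good.size == 0:
                continue
            lv = levels[good]
            zb = float(np.clip(stack.bathymetry[iy, ix], lv[0], lv[-1]))
            hi = int(np.clip(np.searchsorted(lv, zb, side="right"), 1, lv.size - 1)) if lv.size > 1 else 0
            if lv.size == 1:
                out[:, iy, ix] = stack.values[:, good[0], iy, ix]
                continue
            lo = hi - 1
            w = (zb - lv[lo]) / (lv[hi] - lv[lo])
            col_lo = stack.values[:, good[lo], iy, ix]
            col_hi = stack.values[:, good[hi], iy, ix]
            out[:, iy, ix] = (1 - w) * col_lo + w * col_hi
    return GriddedField(
        grid=stack.grid,
        variable=stack.variable,
        units=stack.units,
        depth_label="seafloor",
        times=stack.times,
        values=out,
    )
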