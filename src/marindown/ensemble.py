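"""Equal-weight ensemble statistics and the distributable NetCDF product.

Every downscaled realization holds equal weight; realizations of the same
model are deliberately not down-weighted (weighting by model independence
and performance is out of scope). The spread statistics are the population
standard deviation and the 2.5/50/97.5 percentiles across members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import xarray as xr

from ._version import __version__
from .errors import ValidationError
from .grids import Grid, GriddedField
from .io import NC_ENGINE, NC_FORMAT, TIME_ENCODING

logger = logging.getLogger(__name__)

PERCENTILES = (2.5, 50.0, 97.5)
STAT_NAMES = ("mean", "std", "p2_5", "p50", "p97_5")


@dataclass
class EnsembleStats:
    """Per-cell/per-time equal-weight ensemble statistics."""

    mean: GriddedField
    std: GriddedField
    p2_5: GriddedField
    p50: GriddedField
    p97_5: GriddedField
    n_members: int
    member_ids: list = dc_field(default_factory=list)

    def fields(self) -> dict[str, GriddedField]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def ensemble_statistics(members: list[GriddedField], member_ids: list | None = None) -> EnsembleStats:
    """Equal-weight mean, population std and 2.5/50/97.5 percentiles.

    Cells (and time steps) missing in any member are missing in every
    output, so the statistics always describe the full member set.
    """
    if not members:
        raise ValidationError("need at least one ensemble member")
    first = members[0]
    for m in members[1:]:
        if not m.grid.same_coords(first.grid):
            raise ValidationError("ensemble members must share one grid")
        if m.times.size != first.times.size or np.any(m.times != first.times):
            raise ValidationError("ensemble members must share one time axis")
        if m.variable != first.variable or m.units != first.units:
            raise ValidationError("ensemble members must share variable and units")
    stack = np.stack([m.values for m in members], axis=0)  # (member, t, y, x)
    all_ok = np.all(np.isfinite(stack), axis=0)

    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=0)
    pcts = np.percentile(stack, PERCENTILES, axis=0, method="linear")
    out = {}
    for name, arr in zip(STAT_NAMES, (mean, std, pcts[0], pcts[1], pcts[2])):
        arr = np.where(all_ok, arr, np.nan)
        out[name] = first.copy_with(values=arr, attrs=dict(first.attrs))
    if member_ids is None:
        member_ids = [m.attrs.get("member_id", f"member{i}") for i, m in enumerate(members)]
    return EnsembleStats(n_members=len(members), member_ids=list(member_ids), **out)


def stats_to_dataset(stats: EnsembleStats, provenance: dict | None = None) -> xr.Dataset:
    base = stats.mean
    data_vars = {}
    for name, f in stats.fields().items():
        data_vars[f"{base.variable}_{name}"] = (
            ("time", "lat", "lon"),
            f.values,
            {"units": base.units if name != "std" or True else base.units,
             "depth_label": base.depth_label,
             "cell_methods": f"realization: {name}"},
        )
    data_vars["mask"] = (("lat", "lon"), base.grid.mask.astype(np.int8), {"units": "1"})
    prov = dict(provenance or {})
    defaults = {"training_window": "unspecified", "config_hash": "unspecified"}
    for key, val in defaults.items():
        if key not in prov:
            logger.warning("provenance key %r missing; recording default %r", key, val)
            prov[key] = val
    attrs = {
        "Conventions": "CF-1.8",
        "software_version": __version__,
        "n_members": stats.n_members,
        "member_ids": ",".join(str(m) for m in stats.member_ids),
        **prov,
    }
    return xr.Dataset(
        data_vars,
        coords={
            "time": ("time", base.times),
            "lat": ("lat", base.grid.lats, {"units": "degrees_north", "standard_name": "latitude"}),
            "lon": ("lon", base.grid.lons, {"units": "degrees_east", "standard_name": "longitude"}),
        },
        attrs=attrs,
    )


def write_product(stats: EnsembleStats, path, provenance: dict | None = None) -> None:
    """Write the ensemble product as a CF-style classic NetCDF file."""
    ds = stats_to_dataset(stats, provenance)
    try:
        ds.to_netcdf(path, format=NC_FORMAT, engine=NC_ENGINE, encoding={"time": dict(TIME_ENCODING)})
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed to write ensemble product {path}: {exc}") from exc


def read_product(path) -> EnsembleStats:
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        ds = ds.load()
    stat_vars = [v for v in ds.data_vars if v != "mask"]
    variable = stat_vars[0].rsplit("_", 1)[0]
    # p2_5 / p97_5 contain an underscore of their own
    for v in stat_vars:
        for name in STAT_NAMES:
            if v.endswith("_" + name):
                variable = v[: -(len(name) + 1)]
    mask = ds["mask"].values.astype(bool)
    grid = Grid(ds["lat"].values, ds["lon"].values, mask)
    fields = {}
    for name in STAT_NAMES:
        da = ds[f"{variable}_{name}"]
        fields[name] = GriddedField(
            grid=grid,
            variable=variable,
            units=da.attrs.get("units", "1"),
            depth_label=str(da.attrs.get("depth_label", "surface")),
            times=ds["time"].values,
            values=da.values,
        )
    member_ids = str(ds.attrs.get("member_ids", "")).split(",") if ds.attrs.get("member_ids") else []
    return EnsembleStats(
        n_members=int(ds.attrs.get("n_members", len(member_ids) or 1)),
        member_ids=member_ids,
        **fields,
    )
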