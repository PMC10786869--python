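"""NetCDF serialization for gridded fields (CF conventions).

Files are written in classic NetCDF (64-bit-offset) format through xarray's
scipy backend, which keeps the on-disk product readable by any CF-aware
tool. ``_FillValue`` is honoured on read; a ``units`` attribute is required
on the data variable.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .errors import ValidationError
from .grids import Grid, GriddedField

NC_FORMAT = "NETCDF3_64BIT"
NC_ENGINE = "scipy"

# classic NetCDF has no int64; encode time as float days
TIME_ENCODING = {"dtype": "float64", "units": "days since 1900-01-01", "calendar": "standard"}


def field_to_dataset(field: GriddedField, attrs: dict | None = None) -> xr.Dataset:
    """CF-style Dataset with the field variable plus its ocean mask."""
    ds = xr.Dataset(
        {
            field.variable: (
                ("time", "lat", "lon"),
                field.values,
                {"units": field.units, "depth_label": field.depth_label},
            ),
            "mask": (
                ("lat", "lon"),
                field.grid.mask.astype(np.int8),
                {"long_name": "ocean mask (1 = ocean)", "units": "1"},
            ),
        },
        coords={
            "time": ("time", field.times),
            "lat": ("lat", field.grid.lats, {"units": "degrees_north", "standard_name": "latitude"}),
            "lon": ("lon", field.grid.lons, {"units": "degrees_east", "standard_name": "longitude"}),
        },
        attrs={"Conventions": "CF-1.8", **field.attrs, **(attrs or {})},
    )
    return ds


def write_field(field: GriddedField, path, attrs: dict | None = None) -> None:
    ds = field_to_dataset(field, attrs)
    enc = {"time": dict(TIME_ENCODING)}
    try:
        ds.to_netcdf(path, format=NC_FORMAT, engine=NC_ENGINE, encoding=enc)
    except OSError as exc:  # pragma: no cover - I/O environment dependent
        raise OSError(f"failed to write NetCDF file {path}: {exc}") from exc


def write_transform(transform, path) -> None:
    """Serialize a trained DQM transform for inspection or reuse."""
    import pandas as pd

    ds = xr.Dataset(
        {
            "adjustments": ("prob", transform.adjustments, {"long_name": "per-quantile correction"}),
            "model_quantiles": ("prob", transform.model_quantiles,
                                {"long_name": "detrended scaled-model quantiles"}),
        },
        coords={"prob": ("prob", transform.probs, {"long_name": "quantile probability"})},
        # "dqm_mode" rather than "mode": scipy's netcdf writer keeps global
        # attributes as instance attributes, and "mode" collides with the
        # file handle's own mode field
        attrs={
            "dqm_mode": transform.mode,
            "scaling": transform.scaling,
            "model_center": transform.model_center,
            "month": str(transform.month),
            "training_start": pd.Timestamp(transform.training_window[0]).isoformat(),
            "training_end": pd.Timestamp(transform.training_window[1]).isoformat(),
        },
    )
    ds.to_netcdf(path, format=NC_FORMAT, engine=NC_ENGINE)


def read_transform(path):
    import numpy as _np
    import pandas as pd

    from .dqm import DQMTransform

    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        ds = ds.load()
    month = ds.attrs["month"]
    return DQMTransform(
        mode=str(ds.attrs["dqm_mode"]),
        scaling=float(ds.attrs["scaling"]),
        probs=ds["prob"].values,
        adjustments=ds["adjustments"].values,
        model_quantiles=ds["model_quantiles"].values,
        model_center=float(ds.attrs["model_center"]),
        training_window=(
            _np.datetime64(pd.Timestamp(ds.attrs["training_start"])),
            _np.datetime64(pd.Timestamp(ds.attrs["training_end"])),
        ),
        month="all" if month == "all" else int(month),
    )


def read_field(path, variable: str | None = None) -> GriddedField:
    with xr.open_dataset(path, engine=NC_ENGINE) as ds:
        ds = ds.load()
    data_vars = [v for v in ds.data_vars if v != "mask"]
    if variable is None:
        if len(data_vars) != 1:
            raise ValidationError(
                f"{path}: expected a single data variable, found {data_vars}; pass variable="
            )
        variable = data_vars[0]
    if variable not in ds:
        raise ValidationError(f"{path}: variable {variable!r} not present")
    da = ds[variable]
    units = da.attrs.get("units")
    if not units:
        raise ValidationError(f"{path}: variable {variable!r} lacks a units attribute")
    if "mask" in ds:
        mask = ds["mask"].values.astype(bool)
    else:
        mask = np.any(np.isfinite(da.values), axis=0)
    grid = Grid(ds["lat"].values, ds["lon"].values, mask)
    global_attrs = {k: v for k, v in ds.attrs.items() if k != "Conventions"}
    return GriddedField(
        grid=grid,
        variable=variable,
        units=units,
        depth_label=str(da.attrs.get("depth_label", "surface")),
        times=ds["time"].values,
        values=da.values,
        attrs=global_attrs,
    )
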