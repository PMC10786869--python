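"""Config-driven orchestration: bias-correct -> downscale -> ensemble ->
evaluate -> uncertainty, with file-based stage boundaries and provenance.

Stages communicate only through files (NetCDF and delimited text), so each
stage is independently runnable and resumable. Every output carries the
config hash and software version as global attributes; given one config and
one set of inputs the run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from . import dqm, ensemble as ens, evaluation as ev, uncertainty as unc
from .errors import ValidationError
from .grids import GriddedField, coarsen
from .io import read_field, write_field
from .synthetic import SyntheticConfig, make_observations, make_reference, make_member
from .variables import variable_info

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "variable", "depth_label", "scenarios", "baseline_scenario",
    "reference_file", "member_files", "synthetic", "observations_file",
    "training_window", "present_period", "mid_period", "long_period",
    "n_quantiles", "mode", "per_month", "h_tol", "v_tol",
    "out_dir", "seed",
}

_SYNTH_KEYS = {"n_models", "realizations_per_model"} | set(SyntheticConfig.__dataclass_fields__)


@dataclass
class PipelineConfig:
    variable: str = "temperature"
    depth_label: str = "surface"
    scenarios: tuple = ("ssp126", "ssp245", "ssp585")
    baseline_scenario: str = "ssp245"
    reference_file: str | None = None
    member_files: dict = dc_field(default_factory=dict)  # scenario -> [paths]
    synthetic: dict | None = None
    observations_file: str | None = None
    training_window: tuple | None = None
    present_period: tuple = unc.PRESENT_PERIOD
    mid_period: tuple = unc.MID_TERM
    long_period: tuple = unc.LONG_TERM
    n_quantiles: int = dqm.DEFAULT_N_QUANTILES
    mode: str | None = None  # None -> variable default
    per_month: bool = True
    h_tol: float = 100.0
    v_tol: float = 1.0
    out_dir: str = "outputs"
    seed: int = 0

    @property
    def dqm_mode(self) -> str:
        return self.mode or variable_info(self.variable).dqm_mode

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw) -> PipelineConfig:
    """Parse and validate a YAML document (text, path content, or dict)."""
    if isinstance(raw, str):
        raw = yaml.safe_load(raw)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    errors = []
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    if "synthetic" in raw and raw["synthetic"]:
        bad = set(raw["synthetic"]) - _SYNTH_KEYS
        if bad:
            errors.append(f"unknown synthetic keys: {sorted(bad)}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    for key in ("scenarios", "training_window", "present_period", "mid_period", "long_period"):
        if key in cfg_kwargs and cfg_kwargs[key] is not None:
            cfg_kwargs[key] = tuple(cfg_kwargs[key])
    cfg = PipelineConfig(**cfg_kwargs)

    try:
        variable_info(cfg.variable)
    except ValidationError as exc:
        errors.append(str(exc))
    if not cfg.scenarios:
        errors.append("scenarios must be non-empty")
    if cfg.baseline_scenario not in cfg.scenarios:
        errors.append(
            f"baseline_scenario {cfg.baseline_scenario!r} not in scenarios {list(cfg.scenarios)}"
        )
    if cfg.n_quantiles < 2:
        errors.append("n_quantiles must be at least 2")
    for name, period in (
        ("present_period", cfg.present_period),
        ("mid_period", cfg.mid_period),
        ("long_period", cfg.long_period),
    ):
        if len(period) != 2 or period[0] > period[1]:
            errors.append(f"{name} must be (start_year, end_year) with start <= end")
    if cfg.present_period[1] >= cfg.mid_period[0] or cfg.mid_period[1] >= cfg.long_period[0]:
        errors.append("present/mid/long periods must be non-overlapping and ordered")
    if cfg.synthetic is None and cfg.reference_file is None:
        errors.append("either reference_file or a synthetic block is required")
    if cfg.synthetic is None and not cfg.member_files:
        errors.append("member_files is required when not running synthetically")
    if errors:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def _synthetic_config(cfg: PipelineConfig) -> SyntheticConfig:
    synth = dict(cfg.synthetic or {})
    synth.pop("n_models", None)
    synth.pop("realizations_per_model", None)
    synth.setdefault("seed", cfg.seed)
    synth.setdefault("variable", cfg.variable)
    synth.setdefault("units", variable_info(cfg.variable).units)
    synth.setdefault("depth_label", cfg.depth_label)
    synth.setdefault("proj_end_year", cfg.long_period[1])
    if "scenario_trends" in synth:
        synth["scenario_trends"] = dict(synth["scenario_trends"])
    for key in ("fine_shape", "hist_years"):
        if key in synth:
            synth[key] = tuple(synth[key])
    return SyntheticConfig(**synth)


def _load_members(cfg: PipelineConfig, out: Path) -> tuple[GriddedField, dict]:
    """Reference field and scenario -> [(member_id, field)] inputs."""
    if cfg.synthetic is not None:
        scfg = _synthetic_config(cfg)
        reference, _ = make_reference(scfg)
        write_field(reference, out / "reference.nc", {"config_hash": cfg.config_hash()})
        n_models = int((cfg.synthetic or {}).get("n_models", 2))
        n_real = int((cfg.synthetic or {}).get("realizations_per_model", 2))
        members = {}
        for scenario in cfg.scenarios:
            members[scenario] = [
                (f"model{m + 1}_r{r + 1}", make_member(scfg, f"model{m + 1}_r{r + 1}", scenario)[0])
                for m in range(n_models)
                for r in range(n_real)
            ]
        return reference, members
    reference = read_field(cfg.reference_file)
    members = {}
    for scenario in cfg.scenarios:
        paths = cfg.member_files.get(scenario, [])
        if not paths:
            raise ValidationError(f"no member files listed for scenario {scenario!r}")
        members[scenario] = [(Path(p).stem, read_field(p)) for p in paths]
    return reference, members


def downscale_member(
    member: GriddedField,
    reference: GriddedField,
    cfg: PipelineConfig,
) -> GriddedField:
    """Bias-correct at the member's resolution, then downscale to the
    reference grid (the four-step chain for one realization)."""
    ratio = member.grid.resolution / reference.grid.resolution
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 0.05:
        raise ValidationError(
            f"member/reference resolution ratio {ratio:.2f} is not an integer factor"
        )
    ref_coarse = coarsen(reference, factor)
    if not ref_coarse.grid.same_coords(member.grid):
        raise ValidationError("coarsened reference grid does not match the member grid")
    corrected = dqm.bias_correct(
        member, ref_coarse,
        n_quantiles=cfg.n_quantiles, mode=cfg.dqm_mode,
        per_month=cfg.per_month, training_window=cfg.training_window,
    )
    return dqm.downscale(
        corrected, reference,
        n_quantiles=cfg.n_quantiles, mode=cfg.dqm_mode,
        per_month=cfg.per_month, training_window=cfg.training_window,
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full chain and return the output directory.

    Products: ``members/<scenario>_<id>.nc`` (downscaled realizations),
    ``ensemble/<scenario>.nc`` (statistics), ``evaluation/skill.csv``,
    ``uncertainty/<horizon>.nc`` maps and ``basin_series.csv``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": cfg.config_hash(), "software_version": __version__}
    t_start = time.time()
    reference, raw_members = _load_members(cfg, out)
    logger.info("inputs ready (%.1f s)", time.time() - t_start)

    member_dir = out / "members"
    member_dir.mkdir(exist_ok=True)
    downscaled: dict[str, list[tuple[str, GriddedField]]] = {}
    for scenario, members in raw_members.items():
        fields = []
        for member_id, member in members:
            t0 = time.time()
            try:
                field = downscale_member(member, reference, cfg)
            except Exception as exc:
                raise RuntimeError(
                    f"downscaling stage failed for {scenario}/{member_id}: {exc}"
                ) from exc
            field.attrs.update({"member_id": member_id, "scenario": scenario, **prov})
            write_field(field, member_dir / f"{scenario}_{member_id}.nc")
            fields.append((member_id, field))
            logger.info("downscaled %s/%s (%.1f s)", scenario, member_id, time.time() - t0)
        downscaled[scenario] = fields

    ens_dir = out / "ensemble"
    ens_dir.mkdir(exist_ok=True)
    stats_by_scenario = {}
    for scenario, fields in downscaled.items():
        stats = ens.ensemble_statistics([f for _, f in fields], [mid for mid, _ in fields])
        tw = cfg.training_window or "full-overlap"
        ens.write_product(
            stats, ens_dir / f"{scenario}.nc",
            {**prov, "scenario": scenario, "training_window": str(tw)},
        )
        stats_by_scenario[scenario] = stats

    eval_dir = out / "evaluation"
    eval_dir.mkdir(exist_ok=True)
    eval_period = (
        max(cfg.present_period[0], int(pd.DatetimeIndex(reference.times).year.min())),
        min(cfg.present_period[1], int(pd.DatetimeIndex(reference.times).year.max())),
    )
    scores = {}
    for scenario, stats in stats_by_scenario.items():
        scores[f"ensemble_{scenario}"] = ev.spatial_skill(stats.mean, reference, period=eval_period)
    ev.skill_table(scores).to_csv(eval_dir / "skill.csv", index=False)
    if cfg.observations_file:
        obs = ev.read_observations(cfg.observations_file)
        base_stats = stats_by_scenario[cfg.baseline_scenario]
        pairs = ev.match_observations(
            obs, base_stats.mean, product_depth=5.0,
            h_tol=cfg.h_tol, v_tol=cfg.v_tol, period=eval_period,
        )
        if len(pairs):
            summary = ev.distribution_summary(pairs)
            pd.DataFrame(
                {"bin_left": summary.value_bins[:-1], "bin_right": summary.value_bins[1:],
                 "obs_freq": summary.obs_value_freq, "model_freq": summary.model_value_freq}
            ).to_csv(eval_dir / "obs_distribution.csv", index=False)
            (eval_dir / "obs_overlap.txt").write_text(f"{summary.overlap:.4f}\n")

    unc_dir = out / "uncertainty"
    unc_dir.mkdir(exist_ok=True)
    scen_means = {s: st.mean for s, st in stats_by_scenario.items()}
    baseline_fields = [f for _, f in downscaled[cfg.baseline_scenario]]
    for label, horizon in (("mid_term", cfg.mid_period), ("long_term", cfg.long_period)):
        assessment = unc.assess_changes(
            scen_means, baseline_fields, cfg.baseline_scenario,
            horizon=horizon, present_period=cfg.present_period,
        )
        _write_assessment(assessment, unc_dir / f"{label}.nc", prov)
    basin = unc.basin_series(
        stats_by_scenario[cfg.baseline_scenario],
        stats_by_scenario[cfg.baseline_scenario].mean.grid.mask,
    )
    pd.DataFrame(
        {"time": pd.DatetimeIndex(basin.times), "mean": basin.mean, "p2_5": basin.lo, "p97_5": basin.hi}
    ).to_csv(unc_dir / "basin_series.csv", index=False)
    logger.info("pipeline complete (%.1f s)", time.time() - t_start)
    return out


def _write_assessment(assessment: unc.ChangeAssessment, path: Path, prov: dict) -> None:
    import xarray as xr

    from .io import NC_ENGINE, NC_FORMAT, field_to_dataset

    layers = {
        "change": assessment.change,
        "internal_variability": assessment.internal_var,
        "model_uncertainty": assessment.model_unc,
        "scenario_uncertainty": assessment.scenario_unc,
        "ratio_internal": assessment.ratio_internal,
        "ratio_model": assessment.ratio_model,
        "ratio_scenario": assessment.ratio_scenario,
    }
    first = assessment.change
    data_vars = {
        name: (("lat", "lon"), f.values[0], {"units": f.units}) for name, f in layers.items()
    }
    ds = xr.Dataset(
        data_vars,
        coords={
            "lat": ("lat", first.grid.lats, {"units": "degrees_north"}),
            "lon": ("lon", first.grid.lons, {"units": "degrees_east"}),
        },
        attrs={
            "Conventions": "CF-1.8",
            "horizon": f"{assessment.horizon[0]}-{assessment.horizon[1]}",
            "baseline": f"{assessment.baseline[0]}-{assessment.baseline[1]}",
            **prov,
        },
    )
    ds.to_netcdf(path, format=NC_FORMAT, engine=NC_ENGINE)


def write_synthetic_inputs(cfg: PipelineConfig, out_dir) -> Path:
    """Materialize the synthetic reference, members, and observations as
    files (the `synth` stage)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scfg = _synthetic_config(cfg)
    reference, truth = make_reference(scfg)
    write_field(reference, out / "reference.nc", {"config_hash": cfg.config_hash()})
    n_models = int((cfg.synthetic or {}).get("n_models", 2))
    n_real = int((cfg.synthetic or {}).get("realizations_per_model", 2))
    for scenario in cfg.scenarios:
        for m in range(n_models):
            for r in range(n_real):
                member_id = f"model{m + 1}_r{r + 1}"
                field, _ = make_member(scfg, member_id, scenario)
                write_field(field, out / f"member_{scenario}_{member_id}.nc")
    obs = make_observations(reference, n=200, noise_std=0.2, seed=cfg.seed)
    ev.write_observations(obs, out / "observations.csv")
    sidecar = {
        "scenario_trends": truth.scenario_trends,
        "reference_trend": truth.reference_trend,
        "variance_inflation": truth.variance_inflation,
        "noise_std": truth.noise_std,
        "bias_map_mean": float(np.mean(truth.bias_map)),
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=2))
    return out
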