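"""End-to-end pipeline: synth -> ensemble -> exdet -> gwr -> report.

Stages hand data to each other through plain files in the run directory (ESRI
ASCII grids and CSV tables), so every stage is independently runnable and
testable; a JSON manifest records the configuration, per-stage outputs and
their content hashes. Re-running with the same configuration and seed
reproduces all hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import exdet as xd
from . import gwr as gw
from .grids import read_ascii_grid, read_env_stack, write_ascii_grid, write_env_stack
from .synthetic import LandscapeConfig, generate_landscape
from .tables import TECH_VARIABLES, read_cell_table, write_cell_table, z_transform

log = logging.getLogger("cropsuit")

__all__ = ["RunConfig", "run_full", "stage_synth", "stage_enm", "stage_exdet", "stage_gwr", "stage_report"]

ENV_VARIABLES = (
    "mean_annual_temp",
    "temp_annual_range",
    "precip_wettest_month",
    "precip_driest_month",
    "precip_warmest_quarter",
    "soil_ph",
)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    methods: tuple[str, ...] = ens.DEFAULT_METHODS
    n_replicates: int = 50
    calibration_fraction: float = 0.75
    prevalence: float = 0.5
    future_scenarios: tuple[str, ...] = ("scenario_a",)
    bandwidth: float = 5.0
    exdet: bool = True
    forward_selection: bool = True
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "seed", "n_replicates", "calibration_fraction", "prevalence",
            "bandwidth", "exdet", "forward_selection",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "methods" in raw:
            kwargs["methods"] = tuple(raw["methods"])
        if "future_scenarios" in raw:
            kwargs["future_scenarios"] = tuple(raw["future_scenarios"])
        land = raw.get("landscape", {})
        land_kwargs = {k: land[k] for k in ("seed", "noise_sd", "presence_rate_scale", "smoothness") if k in land}
        if "grid" in land:
            from .grids import GridSpec

            land_kwargs["grid"] = GridSpec(**land["grid"])
        kwargs["landscape"] = LandscapeConfig(**land_kwargs)
        return cls(**kwargs)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"] = {
            "seed": self.landscape.seed,
            "grid": dataclasses.asdict(self.landscape.grid),
            "noise_sd": self.landscape.noise_sd,
            "presence_rate_scale": self.landscape.presence_rate_scale,
        }
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(outdir: str, relpath: str, stage: str, produced_by: str) -> str:
    path = os.path.join(outdir, relpath)
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage {stage!r} requires output of stage {produced_by!r}: missing {relpath}"
        )
    return path


def stage_synth(config: RunConfig, outdir) -> dict[str, str]:
    """Generate the synthetic landscape and write all stage inputs."""
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "env_current"), exist_ok=True)
    land = generate_landscape(dataclasses.replace(config.landscape, seed=config.seed))
    grid = land.grid
    outputs = {}
    outputs.update(
        {f"current:{k}": v for k, v in write_env_stack(land.current_env, os.path.join(outdir, "env_current")).items()}
    )
    for scen in config.future_scenarios:
        d = os.path.join(outdir, f"env_{scen}")
        os.makedirs(d, exist_ok=True)
        outputs.update({f"{scen}:{k}": v for k, v in write_env_stack(land.future_env, d).items()})

    occ_path = os.path.join(outdir, "occurrences.csv")
    lon, lat = grid.cell_center(land.presence_cells[:, 0], land.presence_cells[:, 1])
    write_cell_table(pd.DataFrame({"lon": lon, "lat": lat}), occ_path)
    outputs["occurrences"] = occ_path

    lon_all, lat_all = grid.cell_centers()
    base = {"lon": lon_all.ravel(), "lat": lat_all.ravel()}
    tech_path = os.path.join(outdir, "technology.csv")
    write_cell_table(
        pd.DataFrame({**base, **{k: v.ravel() for k, v in land.technology.items()}}), tech_path
    )
    outputs["technology"] = tech_path

    prod_path = os.path.join(outdir, "productivity.csv")
    write_cell_table(pd.DataFrame({**base, "productivity": land.productivity.ravel()}), prod_path)
    outputs["productivity"] = prod_path

    truth_path = os.path.join(outdir, "true_suitability.asc")
    write_ascii_grid(truth_path, land.suitability, grid)
    outputs["true_suitability"] = truth_path
    log.info("synth: %d presences on a %dx%d grid", len(land.presence_cells), *grid.shape)
    return outputs


def _read_envs(config: RunConfig, outdir: str, stage: str):
    cur_dir = _require(outdir, "env_current", stage, "synth")
    current = read_env_stack({v: os.path.join(cur_dir, f"{v}.asc") for v in ENV_VARIABLES})
    futures = {}
    for scen in config.future_scenarios:
        d = _require(outdir, f"env_{scen}", stage, "synth")
        futures[scen] = read_env_stack({v: os.path.join(d, f"{v}.asc") for v in ENV_VARIABLES})
    return current, futures


def stage_enm(config: RunConfig, outdir) -> dict[str, str]:
    """Run the ensemble protocol; write frequency, consensus and delta grids."""
    outdir = str(outdir)
    current, futures = _read_envs(config, outdir, "enm")
    occ = read_cell_table(_require(outdir, "occurrences.csv", "enm", "synth"))
    from .tables import OccurrenceSet

    occset = OccurrenceSet.from_points(occ[["lon", "lat"]].to_numpy(), current.grid)

    model = ens.EnsembleSuitabilityModel(
        methods=config.methods,
        n_replicates=config.n_replicates,
        calibration_fraction=config.calibration_fraction,
        prevalence=config.prevalence,
        random_state=config.seed,
    ).fit(occset.presence_cells, current, futures)

    outputs = {}
    freq_dir = os.path.join(outdir, "frequency")
    os.makedirs(freq_dir, exist_ok=True)
    for fm in model.frequency_maps_:
        path = os.path.join(freq_dir, f"{fm.method}__{fm.climate_model}.asc")
        write_ascii_grid(path, fm.frequency, current.grid)
        outputs[f"frequency:{fm.method}:{fm.climate_model}"] = path

    cur_path = os.path.join(outdir, "suitability_current.asc")
    write_ascii_grid(cur_path, model.suitability_current_.values, current.grid)
    outputs["suitability_current"] = cur_path

    deltas = {}
    for scen, smap in model.suitability_future_.items():
        fpath = os.path.join(outdir, f"suitability_{scen}.asc")
        write_ascii_grid(fpath, smap.values, current.grid)
        outputs[f"suitability:{scen}"] = fpath
        delta, summary = ens.suitability_delta(model.suitability_current_, smap)
        dpath = os.path.join(outdir, f"suitability_delta_{scen}.asc")
        write_ascii_grid(dpath, delta, current.grid)
        outputs[f"delta:{scen}"] = dpath
        deltas[scen] = summary

    manifest = {
        "tss_table": {f"{m}|{s}": v for (m, s), v in model.tss_table_.items()},
        "n_fitted_models": model.n_fitted_models_,
        "n_presences": int(occset.n_presences),
        "delta_summaries": deltas,
    }
    mpath = os.path.join(outdir, "enm_summary.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["enm_summary"] = mpath
    return outputs


def stage_exdet(config: RunConfig, outdir) -> dict[str, str]:
    """Novelty of each future scenario relative to the training climates."""
    outdir = str(outdir)
    current, futures = _read_envs(config, outdir, "exdet")
    occ = read_cell_table(_require(outdir, "occurrences.csv", "exdet", "synth"))
    from .tables import OccurrenceSet

    occset = OccurrenceSet.from_points(occ[["lon", "lat"]].to_numpy(), current.grid)
    # reference = the model training domain: presence cells plus one seeded
    # pseudo-absence draw from the background
    valid_cells = np.argwhere(current.valid_mask())
    pres = {tuple(c) for c in occset.presence_cells}
    background = np.array([c for c in valid_cells if tuple(c) not in pres])
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(101,)))
    pa = ens.sample_pseudo_absences(background, occset.presence_cells, config.prevalence, rng)
    ref_cells = np.vstack([occset.presence_cells, pa])
    detector = xd.ExDet().fit(current.as_matrix(ref_cells))

    outputs = {}
    summaries = {}
    for scen, env in futures.items():
        nt1, nt2, classes, summary = xd.classify_projection(env, detector, ENV_VARIABLES)
        for name, arr in (("nt1", nt1), ("nt2", nt2), ("class", classes.astype(float))):
            path = os.path.join(outdir, f"exdet_{name}_{scen}.asc")
            write_ascii_grid(path, arr, env.grid)
            outputs[f"exdet:{name}:{scen}"] = path
        summaries[scen] = summary
    spath = os.path.join(outdir, "exdet_summary.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    outputs["exdet_summary"] = spath
    return outputs


def stage_gwr(config: RunConfig, outdir) -> dict[str, str]:
    """Three GWRs + OLS baseline + variation partitioning on the joined table."""
    outdir = str(outdir)
    prod = read_cell_table(_require(outdir, "productivity.csv", "gwr", "synth"))
    tech = read_cell_table(_require(outdir, "technology.csv", "gwr", "synth"))
    suit_grid, grid = read_ascii_grid(_require(outdir, "suitability_current.asc", "gwr", "enm"))

    df = prod.merge(tech, on=["lon", "lat"], validate="one_to_one")
    coords = df[["lon", "lat"]].to_numpy()
    suit, inside = gw.municipality_suitability(suit_grid, grid, coords)
    n_dropped = int((~inside).sum())
    if n_dropped:
        log.info("gwr: %d locations outside the suitability grid dropped", n_dropped)
    df = df.loc[inside].reset_index(drop=True)
    coords = coords[inside]
    suit = suit[inside]

    y = z_transform(df["productivity"].to_numpy())
    s = z_transform(suit)
    tech_cols = [c for c in TECH_VARIABLES if c in df.columns]
    T = np.column_stack([z_transform(df[c].to_numpy()) for c in tech_cols])

    if config.forward_selection:
        selected = gw.forward_select(y, T, names=tech_cols)
        if not selected:  # keep the nested-model comparison well defined
            selected = [tech_cols[0]]
    else:
        selected = tech_cols
    Ts = T[:, [tech_cols.index(c) for c in selected]]

    def fit(X):
        return gw.GWRegressor(bandwidth=config.bandwidth).fit(X, y, coords)

    X_all = np.column_stack([s[:, None], Ts])
    gwr_all, gwr_suit, gwr_tec = fit(X_all), fit(s[:, None]), fit(Ts)
    ols_all = gw.fit_ols(X_all, y)
    F, pval = gw.gwr_vs_ols_ftest(gwr_all, ols_all)
    part = gw.variation_partition(
        gwr_all.adj_r2_, gwr_suit.adj_r2_, gwr_tec.adj_r2_,
        local_all=gwr_all.local_r2_, local_suit=gwr_suit.local_r2_, local_tec=gwr_tec.local_r2_,
    )

    local = pd.DataFrame(
        {
            "lon": coords[:, 0],
            "lat": coords[:, 1],
            "intercept": gwr_all.coef_local_[:, 0],
            "beta_suitability": gwr_all.coef_local_[:, 1],
            **{
                f"beta_{c}": gwr_all.coef_local_[:, 2 + j] for j, c in enumerate(selected)
            },
            "local_r2": gwr_all.local_r2_,
            "pure_climate": part.local["pure_climate"],
            "pure_technology": part.local["pure_technology"],
            "shared": part.local["shared"],
        }
    )
    lpath = os.path.join(outdir, "gwr_local.csv")
    write_cell_table(local, lpath)

    stats = {
        "n": gwr_all.n_,
        "selected_technology": selected,
        "adj_r2": {"all": gwr_all.adj_r2_, "suit": gwr_suit.adj_r2_, "tec": gwr_tec.adj_r2_,
                   "ols_all": ols_all.adj_r2},
        "partition": {
            "pure_climate": part.pure_climate,
            "pure_technology": part.pure_technology,
            "shared": part.shared,
        },
        "aicc": {"gwr_all": gwr_all.aicc_, "ols_all": ols_all.aicc},
        "f_test": {"F": F, "p_value": pval},
        "effective_params": gwr_all.v1_,
        "n_dropped_outside_grid": n_dropped,
    }
    spath = os.path.join(outdir, "gwr_global.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    return {"gwr_local": lpath, "gwr_global": spath}


def stage_report(config: RunConfig, outdir) -> dict[str, str]:
    """Condense the run's headline numbers into one CSV + JSON report."""
    outdir = str(outdir)
    with open(_require(outdir, "gwr_global.json", "report", "gwr"), encoding="utf-8") as fh:
        gwr_stats = json.load(fh)
    with open(_require(outdir, "enm_summary.json", "report", "enm"), encoding="utf-8") as fh:
        enm_stats = json.load(fh)
    report = {
        "partition": gwr_stats["partition"],
        "adj_r2": gwr_stats["adj_r2"],
        "f_test": gwr_stats["f_test"],
        "delta_summaries": enm_stats["delta_summaries"],
        "n_fitted_models": enm_stats["n_fitted_models"],
    }
    exdet_path = os.path.join(outdir, "exdet_summary.json")
    if os.path.exists(exdet_path):
        with open(exdet_path, encoding="utf-8") as fh:
            report["exdet"] = json.load(fh)
    jpath = os.path.join(outdir, "report.json")
    with open(jpath, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    rows = [
        {"quantity": "adj_r2_all", "value": gwr_stats["adj_r2"]["all"]},
        {"quantity": "adj_r2_suit", "value": gwr_stats["adj_r2"]["suit"]},
        {"quantity": "adj_r2_tec", "value": gwr_stats["adj_r2"]["tec"]},
        {"quantity": "pure_climate", "value": gwr_stats["partition"]["pure_climate"]},
        {"quantity": "pure_technology", "value": gwr_stats["partition"]["pure_technology"]},
        {"quantity": "shared", "value": gwr_stats["partition"]["shared"]},
        {"quantity": "F_gwr_vs_ols", "value": gwr_stats["f_test"]["F"]},
    ]
    for scen, summ in enm_stats["delta_summaries"].items():
        rows.append({"quantity": f"fraction_losing_{scen}", "value": summ["fraction_losing"]})
    cpath = os.path.join(outdir, "report.csv")
    write_cell_table(pd.DataFrame(rows), cpath)
    return {"report_json": jpath, "report_csv": cpath}


def run_full(config: RunConfig, outdir) -> dict:
    """Run every stage in order and return the manifest (also written)."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    stages = [("synth", stage_synth), ("enm", stage_enm)]
    if config.exdet:
        stages.append(("exdet", stage_exdet))
    stages += [("gwr", stage_gwr), ("report", stage_report)]
    manifest: dict = {"config": config.echo(), "stages": {}, "skipped": []}
    if not config.exdet:
        manifest["skipped"].append("exdet")
    for name, fn in stages:
        log.info("running stage %s", name)
        try:
            outputs = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "outputs": {k: os.path.relpath(p, outdir) for k, p in outputs.items()},
            "hashes": {os.path.relpath(p, outdir): _sha256(p) for p in outputs.values()},
        }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
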