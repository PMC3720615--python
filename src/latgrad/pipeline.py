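"""End-to-end orchestration of the latitudinal-gradient analysis.

One configuration file drives the whole chain:

    synth (optional) -> grid -> metrics [per group] -> smooth models
        -> residual correlograms -> richness correlograms
        -> Pearson + model-II comparison

All randomness flows from a single master seed, split per stage with
``numpy.random.SeedSequence``, so a config plus seed pins every output
byte.  A manifest records package version, seeds, a hash of the config,
and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_correlograms, pearson_r
from .gam import fit_smooth, residuals as gam_residuals
from .grid import build_grid, rasterize, read_ranges, richness, write_grid_outputs
from .phylo import (assemble_cell_metrics, match_species, mean_root_distance,
                    quartile_split, read_newick, root_distances)
from .spatial import correlogram
from .synthetic import ScenarioConfig, generate_scenario, write_fixture

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "grid": {"cell_km": 100.0, "bbox": None, "occupancy_rule": "area"},
    "gam": {"family": "gaussian", "k": 10, "lambda_rule": "gcv"},
    "spatial": {"n_classes": 10, "n_perm": 200, "rule": "equal_width",
                "max_cells": 3000},
    "compare": {"method": "rma", "direction": "subset_on_total"},
}


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    # data mode: paths ...
    ranges_path: str | None = None
    tree_path: str | None = None
    groups_path: str | None = None
    # ... or synthetic mode
    scenario: ScenarioConfig | None = None
    grid: dict = field(default_factory=lambda: dict(_DEFAULTS["grid"]))
    gam: dict = field(default_factory=lambda: dict(_DEFAULTS["gam"]))
    spatial: dict = field(default_factory=lambda: dict(_DEFAULTS["spatial"]))
    compare: dict = field(default_factory=lambda: dict(_DEFAULTS["compare"]))


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


_KNOWN_TOP_KEYS = {"out_dir", "seed", "ranges", "tree", "groups", "scenario",
                   "grid", "gam", "spatial", "compare"}


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    All problems are collected and reported together in a single
    :class:`ConfigError`; unknown keys produce warnings only.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    for key in raw:
        if key not in _KNOWN_TOP_KEYS:
            logger.warning("unknown config key %r ignored", key)

    has_paths = "ranges" in raw or "tree" in raw
    has_scenario = "scenario" in raw
    if has_paths and has_scenario:
        errors.append("config must contain either input paths or a scenario, not both")
    if not has_paths and not has_scenario:
        errors.append("config must contain input paths (ranges, tree) or a scenario")
    if has_paths:
        for key in ("ranges", "tree"):
            if key not in raw:
                errors.append(f"missing required key {key!r} in data mode")
    if "out_dir" not in raw:
        errors.append("missing required key 'out_dir'")

    scenario = None
    if has_scenario:
        try:
            sc = dict(raw["scenario"] or {})
            if "bbox" in sc:
                sc["bbox"] = tuple(sc["bbox"])
            scenario = ScenarioConfig(**sc)
        except (TypeError, ValueError) as exc:
            errors.append(f"scenario: {exc}")

    blocks = {}
    for block in ("grid", "gam", "spatial", "compare"):
        merged = dict(_DEFAULTS[block])
        merged.update(raw.get(block) or {})
        blocks[block] = merged
    if blocks["grid"]["cell_km"] is None or blocks["grid"]["cell_km"] <= 0:
        errors.append("grid.cell_km must be positive")
    if blocks["spatial"]["n_perm"] < 1:
        errors.append("spatial.n_perm must be >= 1")
    if blocks["spatial"]["n_classes"] < 1:
        errors.append("spatial.n_classes must be >= 1")
    if blocks["gam"]["family"] not in ("gaussian", "poisson"):
        errors.append("gam.family must be 'gaussian' or 'poisson'")
    if blocks["compare"]["method"] not in ("rma", "ma"):
        errors.append("compare.method must be 'rma' or 'ma'")
    if blocks["grid"]["bbox"] is not None and len(blocks["grid"]["bbox"]) != 4:
        errors.append("grid.bbox must have 4 entries (lon_min, lon_max, lat_min, lat_max)")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        out_dir=raw["out_dir"],
        seed=int(raw.get("seed", 0)),
        ranges_path=raw.get("ranges"),
        tree_path=raw.get("tree"),
        groups_path=raw.get("groups"),
        scenario=scenario,
        grid=blocks["grid"], gam=blocks["gam"],
        spatial=blocks["spatial"], compare=blocks["compare"],
    )


def _config_hash(config: RunConfig) -> str:
    def _enc(o):
        if isinstance(o, ScenarioConfig):
            return asdict(o)
        return str(o)
    payload = asdict(config)
    payload.pop("out_dir", None)  # hash the analysis, not the output location
    blob = json.dumps(payload, sort_keys=True, default=_enc)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["synth", "residual_correlogram", "richness_correlogram"]
    children = np.random.SeedSequence(master).spawn(len(names))
    return {nm: int(ss.generate_state(1)[0] % (2**31)) for nm, ss in zip(names, children)}


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis described by a config; returns the manifest.

    Stages fail loudly with the stage name; everything completed before
    the failure remains on disk, so a run can be resumed by stage-level
    CLI commands after the cause is fixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "package": "latgrad", "version": __version__,
        "config_hash": _config_hash(config),
        "master_seed": int(config.seed), "stage_seeds": seeds,
        "stages": {},
    }
    stage = "synth"
    try:
        if config.scenario is not None:
            scenario = config.scenario
            if scenario.seed != seeds["synth"]:
                scenario = ScenarioConfig(**{**asdict(scenario), "seed": seeds["synth"]})
            tree, ranges, truth = generate_scenario(scenario)
            fixture_dir = out / "synthetic"
            write_fixture(tree, ranges, truth, fixture_dir)
            bbox = scenario.bbox
            manifest["stages"]["synth"] = {"n_species": scenario.n_species}
        else:
            tree = read_newick(config.tree_path)
            ranges = read_ranges(config.ranges_path)
            bbox = config.grid["bbox"]
            if bbox is None:
                raise ValueError("grid.bbox is required when supplying range files")

        stage = "grid"
        grid = build_grid(tuple(bbox), cell_km=config.grid["cell_km"])
        pm = rasterize(ranges, grid, rule=config.grid["occupancy_rule"])
        write_grid_outputs(pm, out / "grid")
        manifest["stages"]["grid"] = {
            "n_cells": int(grid.n_cells), "n_occupied": int(pm.occupied.sum()),
            "n_species": len(pm.species),
        }

        stage = "metrics"
        groups = _read_groups(config.groups_path) if config.groups_path else None
        group_runs = {"all": None} if groups is None else {
            g: set(df["species"]) for g, df in groups.groupby("group")
        }
        rd = root_distances(tree)
        for gname, gspecies in group_runs.items():
            _run_group(gname, gspecies, pm, rd, config, seeds, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_groups(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"groups file lacks columns: {sorted(missing)}")
    return df


def _run_group(gname, gspecies, pm_full, rd, config, seeds, out, manifest):
    """Metrics, smooth models, correlograms and comparison for one group."""
    from .grid import PresenceMatrix

    gdir = out / ("analysis" if gname == "all" else f"analysis_{gname}")
    gdir.mkdir(parents=True, exist_ok=True)
    if gspecies is not None:
        cols = [i for i, sp in enumerate(pm_full.species) if sp in gspecies]
        pm = PresenceMatrix(grid=pm_full.grid,
                            species=[pm_full.species[i] for i in cols],
                            matrix=pm_full.matrix[:, cols])
    else:
        pm = pm_full

    rd_matched, report = match_species(rd, pm.species)
    if len(rd_matched) < 4:
        raise ValueError(f"group {gname!r}: fewer than 4 RD-matched species")
    rd_matched.rename_axis("species").to_csv(gdir / "rd_table.csv")
    (gdir / "drop_report.txt").write_text(report.summary() + "\n")
    cells = assemble_cell_metrics(pm, rd_matched)
    occupied = cells["richness"] > 0
    cells["occupied"] = occupied.astype(int)
    cells.to_csv(gdir / "cell_metrics.csv", index=False)

    # smooth models of richness and MRD against latitude (occupied cells)
    occ = cells[occupied]
    gam_rows, fitted_cols = [], {}
    for response in ("richness", "mrd"):
        sub = occ.dropna(subset=[response])
        fam = config.gam["family"] if response == "richness" else "gaussian"
        fit = fit_smooth(sub["latitude_deg"], sub[response], family=fam,
                         k=config.gam["k"], lambda_rule=config.gam["lambda_rule"])
        gam_rows.append({
            "response": response, "family": fam, "k": config.gam["k"],
            "lambda": fit.lambda_, "edf": fit.edf_,
            "deviance_explained": fit.deviance_explained_,
            "p_value": fit.p_value_, "n_cells": len(sub),
        })
        fitted_cols[response] = pd.DataFrame({
            "cell_id": sub["cell_id"].to_numpy(),
            "fitted": fit.fitted_values_,
            "residual": gam_residuals(fit),
        })
    pd.DataFrame(gam_rows).to_csv(gdir / "gam_summary.csv", index=False)
    for response, df in fitted_cols.items():
        df.to_csv(gdir / f"gam_cells_{response}.csv", index=False)

    sp_cfg = config.spatial
    coords = occ[["x_m", "y_m"]].to_numpy() / 1000.0

    # correlograms of smooth-model residuals (autocorrelation diagnostics)
    for response, df in fitted_cols.items():
        resid = df.set_index("cell_id")["residual"]
        sub = occ[occ["cell_id"].isin(resid.index)]
        cg = correlogram(
            resid.loc[sub["cell_id"]].to_numpy(),
            sub[["x_m", "y_m"]].to_numpy() / 1000.0,
            n_classes=sp_cfg["n_classes"], n_perm=sp_cfg["n_perm"],
            seed=seeds["residual_correlogram"], rule=sp_cfg["rule"],
            max_cells=sp_cfg["max_cells"],
        )
        cg.to_csv(gdir / f"correlogram_residuals_{response}.csv")

    # correlograms of total / basal / derived richness + comparison
    basal, derived = quartile_split(rd_matched)
    surfaces = {
        "total": richness(pm)[occupied.to_numpy()],
        "basal": richness(pm, basal)[occupied.to_numpy()],
        "derived": richness(pm, derived)[occupied.to_numpy()],
    }
    cgs = {}
    for name, vals in surfaces.items():
        cgs[name] = correlogram(
            vals, coords, n_classes=sp_cfg["n_classes"], n_perm=sp_cfg["n_perm"],
            seed=seeds["richness_correlogram"], rule=sp_cfg["rule"],
            max_cells=sp_cfg["max_cells"],
        )
        cgs[name].to_csv(gdir / f"correlogram_richness_{name}.csv")
    comp_rows = []
    for name in ("basal", "derived"):
        x_cg, y_cg = cgs["total"], cgs[name]
        if config.compare["direction"] == "total_on_subset":
            x_cg, y_cg = y_cg, x_cg
        fit = compare_correlograms(x_cg, y_cg, method=config.compare["method"])
        comp_rows.append({
            "subset": name, "method": fit.method, "slope": fit.slope,
            "intercept": fit.intercept, "r_squared": fit.r_squared,
            "se_slope": fit.se_slope, "se_r2": fit.se_r_squared,
            "n_classes": fit.n, "pearson_r_cells":
                pearson_r(surfaces["total"], surfaces[name]),
        })
    pd.DataFrame(comp_rows).to_csv(gdir / "comparison.csv", index=False)

    manifest["stages"].setdefault("groups", {})[gname] = {
        "n_species": len(pm.species),
        "n_matched": int(len(rd_matched)),
        "n_dropped_no_rd": report.n_matrix_only,
        "n_occupied_cells": int(occupied.sum()),
        "n_basal": len(basal), "n_derived": len(derived),
    }
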