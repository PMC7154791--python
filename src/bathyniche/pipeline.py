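"""End-to-end pipeline: simulate -> layers -> QC -> background -> fit ->
evaluate -> ensemble -> project, as one seeded, configured, logged run.

Every stochastic stage draws from a stage-scoped generator derived by
hashing the master seed with the stage name, so inserting a stage never
perturbs the draws of later stages.  A run manifest records stage
seeds and SHA-256 digests of every artifact; identical config + seed
reproduces identical digests.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    change_maps,
    ensemble as ens,
    io,
    model_eval,
    occurrence_qc,
    predictor_select,
    pseudo_absence,
    sdm_models,
    synthetic_world,
)
from .grid import GridSpec, Layer

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "master_seed": 0,
    "output_dir": "bathyniche_run",
    "world": {
        "n_rows": 120,
        "n_cols": 120,
        "cell_size": 3000.0,
        "land_fraction": 0.15,
    },
    "species_group": "scleractinian",
    "occurrences": {
        "n_presences": 500,
        "corruption": {
            "frac_missing_depth": 0.05,
            "frac_depth_mismatch": 0.05,
            "frac_coarse_position": 0.03,
        },
    },
    "background": {
        "n": None,           # None -> group default (10,000 corals / 100,000 fishes)
        "buffer_km": 6.0,
        "strata_width": 250.0,
    },
    "models": {
        "families": ["MAXENT", "GAM", "RF"],
        "n_trees": 500,
        "rho_threshold": 0.85,
        "vif_threshold": 10.0,
    },
    "evaluation": {"iterations": 10, "subsample": 0.80},
    "ensemble": {
        "importance_reps": 10,
        "bootstrap_B": 100,
        "run_bootstrap": False,
        "weight_mode": "auc+tss",
    },
    "projection": {},
}


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and defaults[key]:
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validate(val, defaults[key], path + key + ".")
        else:
            out[key] = val
    return out


def load_config(source: str | Path | dict | None = None) -> dict:
    """Validate a config mapping (or YAML file) against the schema."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge_validate(user, DEFAULT_CONFIG)
    if cfg["species_group"] not in predictor_select.GROUP_POLICIES:
        raise ValueError(f"unknown species_group {cfg['species_group']!r}")
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage-scoped seed below 2**31, stable in the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: dict | str | Path | None = None) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    cfg = load_config(config)
    master = int(cfg["master_seed"])
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"master_seed": master, "stages": {}, "artifacts": {}}

    def record(stage, **info):
        manifest["stages"][stage] = {"seed": stage_seed(master, stage), **info}

    def save_artifact(name, path: Path):
        manifest["artifacts"][name] = _digest_file(path)

    # ---- simulate + prepare-layers -------------------------------------
    wcfg = cfg["world"]
    grid = GridSpec(
        n_rows=wcfg["n_rows"], n_cols=wcfg["n_cols"], cell_size=wcfg["cell_size"]
    )
    depth, present = synthetic_world.build_world(
        grid, stage_seed(master, "simulate"), land_fraction=wcfg["land_fraction"]
    )
    delta = synthetic_world.ScenarioDelta.rcp85_like()
    future = synthetic_world.apply_scenario(present, delta)
    niche = synthetic_world.default_coral_niche(present)
    ccfg = cfg["occurrences"]["corruption"]
    occurrences = synthetic_world.simulate_occurrences(
        present,
        niche,
        cfg["occurrences"]["n_presences"],
        synthetic_world.CorruptionSpec(**ccfg),
        seed=stage_seed(master, "occurrences"),
    )
    io.write_stack(present, outdir / "layers_present")
    io.write_stack(future, outdir / "layers_future")
    occ_path = outdir / "occurrences.csv"
    io.write_occurrences(occurrences, occ_path)
    record("simulate", n_occurrences=len(occurrences))
    save_artifact("occurrences.csv", occ_path)

    # ---- qc -------------------------------------------------------------
    presences, kept, rejected = occurrence_qc.run_qc(occurrences, depth)
    kept.to_csv(outdir / "qc_kept.csv", index=False)
    rejected.to_csv(outdir / "qc_rejected.csv", index=False)
    record("qc", n_kept=len(kept), n_rejected=len(rejected), n_cells=presences.n_cells)
    save_artifact("qc_kept.csv", outdir / "qc_kept.csv")

    # ---- background -----------------------------------------------------
    group = cfg["species_group"]
    bcfg = cfg["background"]
    n_pa = bcfg["n"] or pseudo_absence.N_PSEUDO_ABSENCE[group]
    mask = pseudo_absence.env_profile_mask(presences, present)
    bg_seed = stage_seed(master, "background")
    candidates = pseudo_absence.sample_background(
        mask, presences, None, bcfg["buffer_km"], seed=bg_seed
    )
    cr, cc_ = grid.rowcol_of_id(candidates)
    cand_depths = depth.values[cr, cc_]
    pres_depths = depth.values[presences.rows, presences.cols]
    edges = pseudo_absence.default_strata_edges(
        np.r_[pres_depths, cand_depths], bcfg["strata_width"]
    )
    pas = pseudo_absence.depth_stratified_subsample(
        candidates, cand_depths, pres_depths, edges, n_pa, seed=bg_seed + 1
    )
    policy = predictor_select.GROUP_POLICIES[group]
    full_table = pseudo_absence.assemble_training(
        presences, pas, present, covariates=list(policy.candidates)
    )
    retained, decision_log = predictor_select.select(policy, full_table)
    table = full_table[["cell_id", "label", *retained, "depth", "latitude"]].copy()
    if "depth" in retained:
        table = table.loc[:, ~table.columns.duplicated()]
    table.to_csv(outdir / "training.csv", index=False)
    (outdir / "predictor_selection.json").write_text(
        json.dumps({"retained": retained, "log": decision_log}, indent=1)
    )
    record("background", n_pseudo_absence=int(len(pas)), retained=retained)
    save_artifact("training.csv", outdir / "training.csv")

    # ---- fit ------------------------------------------------------------
    families = [f.upper() for f in cfg["models"]["families"]]
    smooths = (
        sdm_models.SmoothSpec.coral()
        if group in ("scleractinian", "octocoral")
        else sdm_models.SmoothSpec()
    )
    fit_kwargs = {
        "MAXENT": {},
        "GAM": {"smooths": smooths},
        "RF": {"n_trees": cfg["models"]["n_trees"]},
    }
    models = {}
    for fam in families:
        models[fam] = sdm_models.fit_family(
            fam, table, covariates=retained,
            seed=stage_seed(master, f"fit:{fam}"), **fit_kwargs[fam],
        )
        models[fam].save(outdir / f"model_{fam.lower()}.pkl")
    record("fit", families=families)

    # ---- evaluate -------------------------------------------------------
    rows_tab, cols_tab = grid.rowcol_of_id(table["cell_id"].to_numpy())
    lon = grid.longitude_of_col(cols_tab)
    lat = grid.latitude_of_row(rows_tab)
    blocks = model_eval.make_blocks(lon, lat)
    metric_sets = {}
    for fam in families:
        metric_sets[fam] = model_eval.cv_run(
            fam, table, blocks,
            iterations=cfg["evaluation"]["iterations"],
            subsample=cfg["evaluation"]["subsample"],
            seed=stage_seed(master, f"evaluate:{fam}"),
            covariates=retained, **fit_kwargs[fam],
        )
    metrics_df = model_eval.metrics_frame(metric_sets)
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    record("evaluate", families=families)
    save_artifact("metrics.csv", outdir / "metrics.csv")

    # ---- ensemble -------------------------------------------------------
    ecfg = cfg["ensemble"]
    weights = ens.EnsembleWeights.from_metrics(metric_sets, mode=ecfg["weight_mode"])
    pred_present = {f: sdm_models.predict_hsi(models[f], present) for f in families}
    pred_future = {f: sdm_models.predict_hsi(models[f], future) for f in families}
    hsi_present = ens.ensemble_hsi(pred_present, weights)
    hsi_future = ens.ensemble_hsi(pred_future, weights)
    io.write_layer(hsi_present, outdir / "hsi_present.asc")
    io.write_layer(hsi_future, outdir / "hsi_future.asc")
    importances = {
        fam: {
            v: ens.permutation_importance(
                models[fam], table, v, reps=ecfg["importance_reps"],
                seed=stage_seed(master, f"importance:{fam}:{v}"),
            )
            for v in retained
        }
        for fam in families
    }
    imp_df = ens.ensemble_importance(importances, weights)
    imp_df.to_csv(outdir / "importance.csv", index=False)
    if ecfg["run_bootstrap"]:
        cv_grids = {
            fam: ens.bootstrap_uncertainty(
                fam, table, present, B=ecfg["bootstrap_B"],
                seed=stage_seed(master, f"bootstrap:{fam}"),
                covariates=retained, **fit_kwargs[fam],
            )
            for fam in families
        }
        io.write_layer(
            ens.ensemble_uncertainty(cv_grids, weights), outdir / "cv_present.asc"
        )
    record("ensemble", weights=weights.weight)
    save_artifact("hsi_present.asc", outdir / "hsi_present.asc")
    save_artifact("hsi_future.asc", outdir / "hsi_future.asc")
    save_artifact("importance.csv", outdir / "importance.csv")

    # ---- project --------------------------------------------------------
    train_scores = hsi_present.values[rows_tab, cols_tab]
    labels = table["label"].to_numpy()
    ok = np.isfinite(train_scores)
    thresholds = {
        "P10": model_eval.threshold_p10(train_scores[ok & (labels == 1)]),
        "MSS": model_eval.threshold_mss(labels[ok], train_scores[ok]),
    }
    summaries = {}
    for rule, thr in thresholds.items():
        b_p = change_maps.binarize(hsi_present, thr, "present")
        b_f = change_maps.binarize(hsi_future, thr, "future")
        cmap = change_maps.change(b_p, b_f)
        summary = change_maps.summarize(b_p, b_f, depth, grid)
        summaries[rule] = summary.__dict__
        codes = cmap.codes.astype(float)
        codes[codes < 0] = np.nan
        io.write_layer(
            Layer(grid, "change", codes), outdir / f"change_{rule.lower()}.asc"
        )
    (outdir / "habitat_summary.json").write_text(json.dumps(summaries, indent=1))
    record("project", thresholds={r: t.value for r, t in thresholds.items()})
    save_artifact("habitat_summary.json", outdir / "habitat_summary.json")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
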