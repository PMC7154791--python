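"""Shared fixtures: synthetic worlds and a full recovery run.

The expensive fixtures are session-scoped: one mid-size world for unit
tests and one basin-scale (200 x 200) recovery run — presences, QC,
background, predictor screening, the three fitted families, blocked CV
and the weighted ensemble — reused by every test that needs a fitted
pipeline state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

import bathyniche as bn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from bathyniche import (
    ensemble as ens,
    model_eval,
    pseudo_absence as pa,
    predictor_select as ps,
    sdm_models,
)


@pytest.fixture(scope="session")
def small_world():
    """100 x 100 world for cheap module tests."""
    grid = bn.GridSpec(100, 100)
    depth, stack = bn.build_world(grid, seed=7)
    return grid, depth, stack


@pytest.fixture(scope="session")
def small_niche(small_world):
    _, _, stack = small_world
    return bn.default_coral_niche(stack)


@dataclass
class RecoveryRun:
    grid: bn.GridSpec
    depth: bn.Layer
    present: bn.LayerStack
    future: bn.LayerStack
    niche: bn.NicheSpec
    oracle: bn.Layer
    presences: object
    table: object
    retained: list
    blocks: object
    metric_sets: dict
    models: dict
    weights: object
    hsi_present: bn.Layer
    hsi_future: bn.Layer


FAMILY_KWARGS = {
    "MAXENT": {},
    "GAM": {"smooths": sdm_models.SmoothSpec.coral()},
    "RF": {},
}


@pytest.fixture(scope="session")
def recovery_run() -> RecoveryRun:
    """Strong-niche basin run: 200 x 200 grid, 1000 presence cells."""
    grid = bn.GridSpec(200, 200)
    depth, present = bn.build_world(grid, seed=11)
    future = bn.apply_scenario(present, bn.ScenarioDelta.rcp85_like())
    niche = bn.default_coral_niche(present, strength=1.5)
    oracle = bn.oracle_suitability(present, niche)

    occ = bn.simulate_occurrences(present, niche, 1000, bn.CorruptionSpec(), seed=12)
    presences, _, _ = bn.run_qc(occ, depth)
    mask = pa.env_profile_mask(presences, present)
    candidates = pa.sample_background(mask, presences, None, 6.0, seed=13)
    rng = np.random.default_rng(14)
    pas = np.sort(rng.choice(candidates, size=min(5000, candidates.size), replace=False))
    policy = ps.GROUP_POLICIES["scleractinian"]
    table = pa.assemble_training(presences, pas, present, covariates=list(policy.candidates))
    retained, _ = ps.select(policy, table)

    rows, cols = grid.rowcol_of_id(table["cell_id"].to_numpy())
    blocks = model_eval.make_blocks(grid.longitude_of_col(cols), grid.latitude_of_row(rows))
    metric_sets, models = {}, {}
    for fam, kw in FAMILY_KWARGS.items():
        metric_sets[fam] = model_eval.cv_run(
            fam, table, blocks, iterations=10, seed=20, covariates=retained, **kw
        )
        models[fam] = sdm_models.fit_family(fam, table, covariates=retained, seed=21, **kw)
    weights = ens.EnsembleWeights.from_metrics(metric_sets)
    hsi_present = ens.ensemble_hsi(
        {f: sdm_models.predict_hsi(models[f], present) for f in models}, weights
    )
    hsi_future = ens.ensemble_hsi(
        {f: sdm_models.predict_hsi(models[f], future) for f in models}, weights
    )
    return RecoveryRun(
        grid, depth, present, future, niche, oracle, presences, table, retained,
        blocks, metric_sets, models, weights, hsi_present, hsi_future,
    )
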