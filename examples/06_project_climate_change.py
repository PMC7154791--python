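"""Project the fitted niche onto a high-emissions future and map change.

Applies the default end-of-century scenario delta (bottom warming,
saturation-horizon shoaling, POC-flux decline, deoxygenation), predicts
future habitat suitability, binarizes both periods at the P10 and MSS
thresholds, and summarizes loss, gain, refugia, areas and median
latitude/depth shifts.
"""

import numpy as np

import bathyniche as bn
from bathyniche import change_maps as cm, model_eval, pseudo_absence as pa, sdm_models

grid = bn.GridSpec(120, 120)
depth, present = bn.build_world(grid, seed=19)
future = bn.apply_scenario(present, bn.ScenarioDelta.rcp85_like())
niche = bn.default_coral_niche(present, strength=1.5)
records = bn.simulate_occurrences(present, niche, 400, seed=20)
presences, _, _ = bn.run_qc(records, depth)
mask = pa.env_profile_mask(presences, present)
pas = pa.sample_background(mask, presences, 2000, seed=21)
covs = ["temp", "omega_ar", "poc_seafloor", "slope", "bpi"]
table = pa.assemble_training(presences, pas, present, covariates=covs)

model = sdm_models.fit_maxent(table, covariates=covs, seed=22)
hsi_p = sdm_models.predict_hsi(model, present)
hsi_f = sdm_models.predict_hsi(model, future)  # same niche, future layers

labels = table["label"].to_numpy()
rows, cols = grid.rowcol_of_id(table["cell_id"].to_numpy())
scores = hsi_p.values[rows, cols]
thresholds = {
    "P10": model_eval.threshold_p10(scores[labels == 1]),
    "MSS": model_eval.threshold_mss(labels, scores),
}

for rule, thr in thresholds.items():
    b_p = cm.binarize(hsi_p, thr, "present")
    b_f = cm.binarize(hsi_f, thr, "future")
    summary = cm.summarize(b_p, b_f, depth, grid)
    print(f"{rule} threshold = {thr.value:.3f}")
    print(f"  suitable area: {summary.area_present_km2:.0f} -> "
          f"{summary.area_future_km2:.0f} km2 ({summary.percent_change:+.1f}%)")
    print(f"  refugia: {summary.refugia_percent_of_present:.1f}% of present habitat")
    print(f"  median depth: {summary.median_depth_present:.0f} -> "
          f"{summary.median_depth_future:.0f} m; "
          f"median latitude: {summary.median_latitude_present:.1f} -> "
          f"{summary.median_latitude_future:.1f} deg")
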