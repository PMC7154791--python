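"""Weight the three families into an ensemble and rank the predictors.

Family weights are proportional to the mean of each family's blocked-CV
AUC and TSS.  Variable importance is 1 minus the Pearson correlation
between original predictions and predictions with the variable
permuted (10 permutations), weight-averaged into an ensemble ranking.
"""

import numpy as np

import bathyniche as bn
from bathyniche import ensemble as ens, model_eval, pseudo_absence as pa, sdm_models

grid = bn.GridSpec(120, 120)
depth, stack = bn.build_world(grid, seed=13)
niche = bn.default_coral_niche(stack, strength=1.5)
records = bn.simulate_occurrences(stack, niche, 400, seed=14)
presences, _, _ = bn.run_qc(records, depth)
mask = pa.env_profile_mask(presences, stack)
pas = pa.sample_background(mask, presences, 2000, seed=15)
covs = ["temp", "omega_ar", "poc_seafloor", "slope", "bpi"]
table = pa.assemble_training(presences, pas, stack, covariates=covs)

rows, cols = grid.rowcol_of_id(table["cell_id"].to_numpy())
blocks = model_eval.make_blocks(grid.longitude_of_col(cols), grid.latitude_of_row(rows))

families = ("MAXENT", "GAM", "RF")
kwargs = {"GAM": {"smooths": sdm_models.SmoothSpec.coral()}}
metrics, models = {}, {}
for fam in families:
    kw = kwargs.get(fam, {})
    metrics[fam] = model_eval.cv_run(fam, table, blocks, iterations=5, seed=16,
                                     covariates=covs, **kw)
    models[fam] = sdm_models.fit_family(fam, table, covariates=covs, seed=17, **kw)

weights = ens.EnsembleWeights.from_metrics(metrics)
print("ensemble weights (prop. to mean of AUC and TSS):")
for fam, w in weights.weight.items():
    print(f"  {fam:7s} {w:.3f}")

hsi = ens.ensemble_hsi({f: sdm_models.predict_hsi(m, stack) for f, m in models.items()},
                       weights)
print(f"ensemble HSI: defined on {np.isfinite(hsi.values).sum()} cells, "
      f"range {np.nanmin(hsi.values):.3f}-{np.nanmax(hsi.values):.3f}")

imp = {
    fam: {v: ens.permutation_importance(models[fam], table, v, seed=18) for v in covs}
    for fam in families
}
table_imp = ens.ensemble_importance(imp, weights).sort_values("ensemble", ascending=False)
print("variable importance (1 - Pearson r, ensemble-weighted):")
for _, row in table_imp.iterrows():
    print(f"  {row['variable']:14s} {row['ensemble']:.2f}")
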