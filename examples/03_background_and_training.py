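"""Generate pseudo-absences and assemble a training table.

Background cells come from the environmental profile of the presences
(per-covariate envelope), outside a 6 km buffer around every presence,
then depth-stratified so their depth histogram matches the presences —
the design used when only presence records exist.
"""

import numpy as np

import bathyniche as bn
from bathyniche import pseudo_absence as pa

grid = bn.GridSpec(120, 120)
depth, stack = bn.build_world(grid, seed=2)
niche = bn.default_coral_niche(stack)
records = bn.simulate_occurrences(stack, niche, 400, seed=4)
presences, _, _ = bn.run_qc(records, depth)

mask = pa.env_profile_mask(presences, stack)
print(f"environmental profile keeps {mask.eligible.sum()} of "
      f"{stack.ocean_mask.sum()} ocean cells eligible")

candidates = pa.sample_background(mask, presences, None, buffer_km=6.0, seed=5)
print(f"{candidates.size} candidate cells survive the 6 km presence buffer")

cr, cc = grid.rowcol_of_id(candidates)
cand_depth = depth.values[cr, cc]
pres_depth = depth.values[presences.rows, presences.cols]
edges = pa.default_strata_edges(np.r_[pres_depth, cand_depth], width=250.0)
pas = pa.depth_stratified_subsample(
    candidates, cand_depth, pres_depth, edges, n_target=1500, seed=6
)

table = pa.assemble_training(presences, pas, stack,
                             covariates=["temp", "omega_ar", "poc_seafloor", "slope", "bpi"])
print(f"training table: {len(table)} rows "
      f"({int((table.label == 1).sum())} presences, {int((table.label == 0).sum())} pseudo-absences)")
pr, _ = np.histogram(pres_depth, edges)
br, _ = np.histogram(cand_depth[np.isin(candidates, pas)], edges)
l1 = np.abs(pr / pr.sum() - br / br.sum()).sum()
print(f"L1 distance between presence and background depth histograms: {l1:.4f}")
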