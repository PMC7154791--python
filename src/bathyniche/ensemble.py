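"""Metric-weighted ensembling, permutation importance, bootstrap uncertainty.

The three family HSI maps are averaged per cell with weights
proportional to the mean of each family's blocked-CV AUC and TSS.
Variable importance is 1 minus the Pearson correlation between original
predictions and predictions with the variable permuted (10 permutations
by default).  Per-cell uncertainty is the coefficient of variation of
100 bootstrap refit maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import sdm_models
from .grid import Layer, LayerStack
from .model_eval import MetricSet
from .sdm_models import FittedModel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleWeights:
    """Per-family normalized weights, weight_f proportional to (AUC_f + TSS_f) / 2."""

    auc: dict
    tss: dict
    weight: dict

    @classmethod
    def from_metrics(
        cls, metrics: dict[str, MetricSet], rule: str = "MSS", mode: str = "auc+tss"
    ) -> "EnsembleWeights":
        auc_d, tss_d, raw = {}, {}, {}
        for fam, ms in metrics.items():
            a, t = ms.weight_inputs(rule)
            auc_d[fam], tss_d[fam] = a, t
            if mode == "auc+tss":
                raw[fam] = (a + t) / 2.0
            elif mode == "auc":
                raw[fam] = a
            elif mode == "tss":
                raw[fam] = t
            else:
                raise ValueError(f"unknown weighting mode {mode!r}")
        total = sum(max(v, 0.0) for v in raw.values())
        if total <= 0:
            raise ValueError("all ensemble weights are zero")
        weight = {f: max(v, 0.0) / total for f, v in raw.items()}
        return cls(auc_d, tss_d, weight)


def ensemble_hsi(
    predictions: dict[str, Layer], weights: EnsembleWeights
) -> Layer:
    """Per-cell weighted mean of the family HSI maps.

    A cell missing in any family is missing in the ensemble, so the
    result is a convex combination bounded by the per-cell min and max.
    """
    fams = list(predictions)
    grid = predictions[fams[0]].grid
    num = np.zeros(grid.shape)
    defined = np.ones(grid.shape, dtype=bool)
    for fam in fams:
        layer = predictions[fam]
        if layer.grid.shape != grid.shape:
            raise ValueError("prediction layers must be grid-aligned")
        defined &= layer.mask
        num += weights.weight[fam] * np.nan_to_num(layer.values)
    num[~defined] = np.nan
    return Layer(grid, "hsi", np.clip(num, 0.0, 1.0))


def permutation_importance(
    model: FittedModel,
    table: pd.DataFrame,
    variable: str,
    reps: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Importance = mean of 1 - Pearson(original, permuted-variable predictions).

    A variable the model does not use correlates perfectly and scores
    exactly 0.  Constant predictions (zero variance) report 0 with a
    warning flag rather than failing.
    """
    if variable not in table.columns:
        raise KeyError(f"variable {variable!r} not in table")
    rng = np.random.default_rng(seed)
    original = model.predict_table(table)
    if np.std(original) < 1e-12:
        log.warning("constant predictions; importance of %s reported as 0", variable)
        return 0.0, 0.0
    vals = []
    for _ in range(reps):
        shuffled = table.copy()
        shuffled[variable] = rng.permutation(shuffled[variable].to_numpy())
        permuted = model.predict_table(shuffled)
        if np.std(permuted) < 1e-12 or np.allclose(permuted, original):
            r = 1.0
        else:
            r = stats.pearsonr(original, permuted).statistic
        vals.append(1.0 - r)
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def ensemble_importance(
    per_family: dict[str, dict[str, tuple[float, float]]],
    weights: EnsembleWeights,
) -> pd.DataFrame:
    """Weight-averaged per-variable importance table.

    ``per_family[family][variable] = (mean, sd)``; a variable absent
    from a family contributes 0 for that family.
    """
    variables = sorted({v for d in per_family.values() for v in d})
    rows = []
    for v in variables:
        row = {"variable": v}
        ens = 0.0
        for fam, imp in per_family.items():
            m, s = imp.get(v, (0.0, 0.0))
            row[f"{fam}_mean"], row[f"{fam}_sd"] = m, s
            ens += weights.weight[fam] * m
        row["ensemble"] = ens
        rows.append(row)
    return pd.DataFrame(rows)


def bootstrap_uncertainty(
    family: str,
    table: pd.DataFrame,
    stack: LayerStack,
    B: int = 100,
    seed: int = 0,
    mean_floor: float = 1e-6,
    max_failure_frac: float = 0.10,
    **fit_kwargs,
) -> Layer:
    """Per-cell coefficient of variation over B bootstrap refits.

    Rows are resampled with replacement stratified by label (every
    replicate keeps the training prevalence), the model is refitted and
    an HSI map predicted; CV = sd / mean per cell, missing where the
    mean is below the floor.
    """
    rng = np.random.default_rng(seed)
    y = table["label"].to_numpy()
    idx1 = np.nonzero(y == 1)[0]
    idx0 = np.nonzero(y == 0)[0]
    sums = np.zeros(stack.grid.shape)
    sq_sums = np.zeros(stack.grid.shape)
    n_ok = 0
    failures = 0
    for _ in range(B):
        rows = np.r_[
            rng.choice(idx1, size=idx1.size, replace=True),
            rng.choice(idx0, size=idx0.size, replace=True),
        ]
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model = sdm_models.fit_family(
                family, table.iloc[rows].reset_index(drop=True), seed=fit_seed, **fit_kwargs
            )
            hsi = sdm_models.predict_hsi(model, stack).values
        except Exception as err:  # refit failures are tolerated up to the cap
            failures += 1
            log.warning("bootstrap refit failed: %s", err)
            if failures > max_failure_frac * B:
                raise RuntimeError(
                    f"{failures} of {B} bootstrap refits failed (> {max_failure_frac:.0%})"
                ) from err
            continue
        sums += np.nan_to_num(hsi)
        sq_sums += np.nan_to_num(hsi) ** 2
        n_ok += 1
    mean = sums / n_ok
    var = np.maximum(sq_sums / n_ok - mean**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.sqrt(var) / mean
    cv[mean < mean_floor] = np.nan
    cv[~stack.ocean_mask] = np.nan
    return Layer(stack.grid, "cv", cv)


def ensemble_uncertainty(
    cv_grids: dict[str, Layer], weights: EnsembleWeights
) -> Layer:
    """Weighted per-cell mean of the family CV grids."""
    fams = list(cv_grids)
    grid = cv_grids[fams[0]].grid
    out = np.zeros(grid.shape)
    defined = np.ones(grid.shape, dtype=bool)
    for fam in fams:
        layer = cv_grids[fam]
        if layer.grid.shape != grid.shape:
            raise ValueError("CV grids must be aligned")
        defined &= layer.mask
        out += weights.weight[fam] * np.nan_to_num(layer.values)
    out[~defined] = np.nan
    return Layer(grid, "cv", out)
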