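"""Collinearity screening and group-specific predictor sets.

Candidate predictors are screened pairwise with Spearman correlation
and jointly with variance inflation factors; within each offending pair
the ecologically lower-priority variable is dropped.  Group presets
encode the taxon-specific candidate lists: aragonite saturation for
scleractinians, calcite saturation for octocorals, and depth/oxygen for
fishes (corals never see depth, dissolved oxygen or pH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PredictorPolicy:
    group: str
    candidates: tuple[str, ...]
    priority: tuple[str, ...]  # total order, most ecologically relevant first
    rho_threshold: float = 0.85
    vif_threshold: float = 10.0

    def __post_init__(self) -> None:
        if set(self.priority) != set(self.candidates):
            raise ValueError("priority must be a total order on the candidates")

    def rank(self, var: str) -> int:
        return self.priority.index(var)


#: group presets; priority encodes ecological relevance (saturation state
#: over depth for corals, so depth is what the collinearity rule removes)
GROUP_POLICIES: dict[str, PredictorPolicy] = {
    "scleractinian": PredictorPolicy(
        "scleractinian",
        candidates=("omega_ar", "temp", "poc_seafloor", "slope", "bpi", "depth"),
        priority=("omega_ar", "temp", "poc_seafloor", "slope", "bpi", "depth"),
    ),
    "octocoral": PredictorPolicy(
        "octocoral",
        candidates=("omega_cal", "temp", "poc_seafloor", "slope", "bpi", "depth"),
        priority=("omega_cal", "temp", "poc_seafloor", "slope", "bpi", "depth"),
    ),
    "fish": PredictorPolicy(
        "fish",
        candidates=("depth", "temp", "poc_seafloor", "DO", "slope", "bpi"),
        priority=("depth", "temp", "poc_seafloor", "DO", "slope", "bpi"),
    ),
}


def spearman_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Symmetric Spearman rank-correlation matrix with unit diagonal."""
    if len(table) < 3:
        raise ValueError("need >= 3 rows")
    for v in variables:
        if table[v].nunique() <= 1:
            raise ValueError(f"variable {v!r} is constant")
    if len(variables) == 1:
        return pd.DataFrame([[1.0]], index=variables, columns=variables)
    rho = stats.spearmanr(table[variables].to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-variable case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=variables, columns=variables)


def vif(table: pd.DataFrame, variables: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j).

    R2_j is from regressing variable j on the other variables (with an
    intercept).  Perfect collinearity yields ``inf`` rather than an
    error.
    """
    if len(table) <= len(variables) + 1:
        raise ValueError("need n_rows > n_vars + 1")
    X = table[variables].to_numpy(dtype=float)
    out = {}
    for j, v in enumerate(variables):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[v] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def select(
    policy: PredictorPolicy,
    table: pd.DataFrame,
) -> tuple[list[str], list[dict]]:
    """Apply the collinearity rule; returns retained variables + decision log.

    First, while any retained pair has |Spearman rho| above the
    threshold, the lower-priority member of the strongest such pair is
    dropped.  Then variables are dropped (highest VIF first, lower
    priority breaking ties) until all VIFs are at or below the
    threshold.  Deterministic; the log records each drop and its
    trigger.
    """
    missing = [v for v in policy.candidates if v not in table.columns]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    retained = list(policy.candidates)
    decision_log: list[dict] = []

    rho = spearman_matrix(table, retained)
    while len(retained) > 1:
        sub = rho.loc[retained, retained].abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= policy.rho_threshold:
            break
        a, b = retained[i], retained[j]
        drop = a if policy.rank(a) > policy.rank(b) else b
        keep = b if drop == a else a
        decision_log.append(
            {"dropped": drop, "trigger": "spearman", "partner": keep,
             "value": float(sub[i, j]), "threshold": policy.rho_threshold}
        )
        retained.remove(drop)

    while len(retained) > 1:
        vals = vif(table, retained)
        if vals.max() <= policy.vif_threshold:
            break
        worst = vals.max()
        ties = [v for v in retained if vals[v] == worst]
        drop = max(ties, key=policy.rank)
        decision_log.append(
            {"dropped": drop, "trigger": "vif", "value": float(worst),
             "threshold": policy.vif_threshold}
        )
        retained.remove(drop)

    if not retained:
        raise ValueError("collinearity screening dropped every candidate variable")
    return retained, decision_log
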