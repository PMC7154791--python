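"""The three habitat-suitability model families.

All families share one contract: fit on a labelled presence /
pseudo-absence table, predict a habitat suitability index (HSI) in
[0, 1] for new covariate tables or whole layer stacks, persist and
reload to identical predictions.  The ensemble layer cannot tell them
apart except by metadata.

* Maxent — an L1-regularized presence-background density-ratio model
  over linear + quadratic + hinge features of the covariates, with the
  logistic output anchored at a stated prevalence.
* GAM — a binomial logit additive model with small fixed-dimension
  B-spline smooths and exhaustive AIC subset selection.
* RF — a classification random forest whose HSI is the presence-class
  vote fraction.
"""

from __future__ import annotations

import abc
import hashlib
import itertools
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.special import expit, logit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .grid import Layer, LayerStack

FAMILIES = ("MAXENT", "GAM", "RF")


@dataclass(frozen=True)
class SmoothSpec:
    """Per-covariate spline basis dimensions for the GAM."""

    default_dim: int = 4
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in [self.default_dim, *self.overrides.values()]:
            if dim < 3:
                raise ValueError("basis dimension must be >= 3")

    def dim(self, covariate: str) -> int:
        return self.overrides.get(covariate, self.default_dim)

    @classmethod
    def coral(cls) -> "SmoothSpec":
        """Coral preset: 4 basis functions, 3 for temperature and saturation."""
        return cls(4, {"temp": 3, "omega_ar": 3, "omega_cal": 3})


def _check_labels(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both labels (1 and 0)")


def _table_digest(table: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(table, index=False).to_numpy().tobytes()
    ).hexdigest()[:16]


class FittedModel(abc.ABC):
    """Uniform fit/predict surface over the three families."""

    family: str

    def __init__(self, covariates: list[str], seed: int, table: pd.DataFrame):
        self.covariates = list(covariates)
        self.seed = int(seed)
        y = table["label"].to_numpy()
        self.training_summary = {
            "n_presence": int((y == 1).sum()),
            "n_absence": int((y == 0).sum()),
            "prevalence": float((y == 1).mean()),
            "training_digest": _table_digest(table[["label", *self.covariates]]),
        }

    @abc.abstractmethod
    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        """HSI in [0, 1] for each row of a covariate table."""

    def predict_stack(self, stack: LayerStack) -> Layer:
        return predict_hsi(self, stack)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        sidecar = {
            "family": self.family,
            "covariates": self.covariates,
            "seed": self.seed,
            **self.training_summary,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


# ---------------------------------------------------------------- Maxent

class _MaxentFeatures:
    """Linear + quadratic + hinge feature expansion on [0, 1]-scaled covariates."""

    def __init__(self, table: pd.DataFrame, covariates: list[str], n_hinge: int = 5):
        self.covariates = covariates
        self.lo = {c: float(table[c].min()) for c in covariates}
        self.hi = {c: float(table[c].max()) for c in covariates}
        self.knots = np.linspace(0, 1, n_hinge + 2)[1:-1]

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for c in self.covariates:
            span = self.hi[c] - self.lo[c]
            u = (table[c].to_numpy(dtype=float) - self.lo[c]) / (span if span > 0 else 1.0)
            u = np.clip(u, 0.0, 1.0)
            cols.append(u)
            cols.append(u**2)
            for t in self.knots:
                cols.append(np.maximum(0.0, (u - t) / (1.0 - t)))
                cols.append(np.maximum(0.0, (t - u) / t))
        return np.column_stack(cols)


class MaxentModel(FittedModel):
    family = "MAXENT"

    def __init__(self, table, covariates, prevalence, seed, C):
        super().__init__(covariates, seed, table)
        y = table["label"].to_numpy()
        _check_labels(y)
        self.features = _MaxentFeatures(table, self.covariates)
        X = self.features.transform(table)
        self.clf = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=seed
        ).fit(X, y)
        n1, n0 = (y == 1).sum(), (y == 0).sum()
        if prevalence is None:
            prevalence = n1 / n0  # proportion of presences over pseudo-absences
        self.prevalence = float(np.clip(prevalence, 1e-6, 1 - 1e-6))
        # shift the intercept from the training class balance to the
        # stated prevalence; output stays a logistic-scale ranking index
        self._shift = logit(self.prevalence) - logit(n1 / (n1 + n0))

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        eta = self.clf.decision_function(self.features.transform(table))
        return expit(eta + self._shift)


def fit_maxent(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    prevalence: float | None = None,
    seed: int = 0,
    regularization_c: float = 1.0,
) -> MaxentModel:
    covariates = covariates or _infer_covariates(table)
    return MaxentModel(table, covariates, prevalence, seed, regularization_c)


# ------------------------------------------------------------------- GAM

class _SplineBasis:
    """Fixed-dimension B-spline basis with knots at training quantiles."""

    def __init__(self, x: np.ndarray, dim: int):
        self.degree = 3 if dim >= 4 else 2
        n_interior = dim - self.degree - 1
        self.lo, self.hi = float(x.min()), float(x.max())
        if self.hi <= self.lo:
            self.hi = self.lo + 1e-9
        interior = (
            np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
            if n_interior > 0 else np.array([])
        )
        self.t = np.r_[[self.lo] * (self.degree + 1), interior, [self.hi] * (self.degree + 1)]
        self.dim = dim

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), self.lo, self.hi)
        M = BSpline.design_matrix(x, self.t, self.degree).toarray()
        return M[:, 1:]  # drop one column: the model carries a global intercept


class GamModel(FittedModel):
    family = "GAM"

    def __init__(self, table, covariates, smooths, seed):
        super().__init__(covariates, seed, table)
        y = table["label"].to_numpy()
        _check_labels(y)
        self.smooths = smooths
        self.selected, self.result, self.bases, self.aic_trace = self._select(table, y)
        self.params = np.asarray(self.result.params)

    def _design(self, table, subset, bases):
        mats = [np.ones((len(table), 1))]
        mats += [bases[c].design(table[c].to_numpy()) for c in subset]
        return np.column_stack(mats)

    def _fit_subset(self, table, y, subset, bases):
        X = self._design(table, subset, bases)
        # near-separated niches overflow the logit link mid-IRLS; harmless
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not res.converged:
            raise RuntimeError(f"GAM IRLS failed to converge for subset {subset}")
        return res

    def _select(self, table, y):
        bases = {
            c: _SplineBasis(table[c].to_numpy(dtype=float), self.smooths.dim(c))
            for c in self.covariates
        }
        if len(self.covariates) <= 8:
            subsets = [
                combo
                for r in range(1, len(self.covariates) + 1)
                for combo in itertools.combinations(self.covariates, r)
            ]
        else:
            subsets = self._forward_subsets(table, y, bases)
        trace, best = [], None
        errors = []
        for subset in subsets:
            try:
                res = self._fit_subset(table, y, subset, bases)
            except Exception as err:  # separation / convergence failures skip the subset
                errors.append(f"{subset}: {err}")
                continue
            trace.append({"subset": list(subset), "aic": float(res.aic)})
            if best is None or res.aic < best[1].aic:
                best = (subset, res)
        if best is None:
            raise RuntimeError("no GAM candidate subset converged: " + "; ".join(errors))
        subset, res = best
        return list(subset), res, bases, trace

    def _forward_subsets(self, table, y, bases):
        """Forward AIC path for > 8 candidates (exhaustive would be 2^p)."""
        current: list[str] = []
        path = []
        remaining = list(self.covariates)
        best_aic = np.inf
        while remaining:
            scores = []
            for c in remaining:
                try:
                    res = self._fit_subset(table, y, tuple(current + [c]), bases)
                    scores.append((res.aic, c))
                except Exception:
                    continue
            if not scores:
                break
            aic, c = min(scores)
            if aic >= best_aic:
                break
            best_aic = aic
            current.append(c)
            remaining.remove(c)
            path.append(tuple(current))
        return path or [tuple(self.covariates[:1])]

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        X = self._design(table, self.selected, self.bases)
        return expit(X @ self.params)


def fit_gam(
    table: pd.DataFrame,
    smooths: SmoothSpec | None = None,
    covariates: list[str] | None = None,
    seed: int = 0,
) -> GamModel:
    covariates = covariates or _infer_covariates(table)
    return GamModel(table, covariates, smooths or SmoothSpec(), seed)


# -------------------------------------------------------------------- RF

class RFModel(FittedModel):
    family = "RF"

    def __init__(self, table, covariates, seed, n_trees, oob_score):
        super().__init__(covariates, seed, table)
        y = table["label"].to_numpy()
        _check_labels(y)
        self.forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
            oob_score=oob_score,
        ).fit(table[self.covariates].to_numpy(), y)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict_proba(table[self.covariates].to_numpy())[:, 1]

    @property
    def oob_scores(self) -> np.ndarray:
        """Out-of-bag presence vote fraction per training row."""
        return self.forest.oob_decision_function_[:, 1]


def fit_rf(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    seed: int = 0,
    n_trees: int = 500,
    oob_score: bool = False,
) -> RFModel:
    covariates = covariates or _infer_covariates(table)
    return RFModel(table, covariates, seed, n_trees, oob_score)


# ---------------------------------------------------------------- shared

def _infer_covariates(table: pd.DataFrame) -> list[str]:
    drop = {"cell_id", "label", "latitude"}
    return [c for c in table.columns if c not in drop]


def fit_family(
    family: str,
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    seed: int = 0,
    smooths: SmoothSpec | None = None,
    prevalence: float | None = None,
    n_trees: int = 500,
) -> FittedModel:
    family = family.upper()
    if family == "MAXENT":
        return fit_maxent(table, covariates, prevalence, seed)
    if family == "GAM":
        return fit_gam(table, smooths, covariates, seed)
    if family == "RF":
        return fit_rf(table, covariates, seed, n_trees)
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")


def predict_hsi(model: FittedModel, stack: LayerStack) -> Layer:
    """Predict HSI over a layer stack; missing covariate cells stay missing.

    Projection onto a future scenario is this same operation on the
    future stack.
    """
    missing = [c for c in model.covariates if c not in stack]
    if missing:
        raise KeyError(f"stack lacks covariate layers: {missing}")
    defined = np.ones(stack.grid.shape, dtype=bool)
    for c in model.covariates:
        defined &= stack[c].mask
    rr, cc = np.nonzero(defined)
    table = pd.DataFrame(stack.table_at_cells(rr, cc, model.covariates))
    out = np.full(stack.grid.shape, np.nan)
    out[rr, cc] = np.clip(model.predict_table(table), 0.0, 1.0)
    return Layer(stack.grid, "hsi", out)
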