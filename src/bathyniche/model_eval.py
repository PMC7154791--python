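"""Spatial block cross-validation and threshold-based skill metrics.

The study area is split into four contiguous rectangles holding similar
numbers of occurrence points (median latitude split, then per-half
median longitude).  Each CV iteration holds one block out for testing,
trains on an 80% subsample of the rest, and scores AUC, kappa,
sensitivity, specificity and TSS at two binarization thresholds: the
10th-percentile training-presence threshold (P10) and the maximum of
sensitivity + specificity (MSS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sdm_models

log = logging.getLogger(__name__)

METRICS = ("auc", "kappa", "sensitivity", "specificity", "tss")
THRESHOLD_RULES = ("P10", "MSS")


@dataclass(frozen=True)
class ThresholdSpec:
    rule: str   # P10 | MSS
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("threshold value must be in [0, 1]")
        if self.rule not in THRESHOLD_RULES:
            raise ValueError(f"unknown threshold rule {self.rule!r}")


@dataclass(frozen=True)
class BlockAssignment:
    block_of_point: np.ndarray  # 1..4 per point
    split_lat: float
    split_lon_low: float   # longitude split within the southern half
    split_lon_high: float  # longitude split within the northern half

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.block_of_point, minlength=5)[1:]


@dataclass
class MetricSet:
    """Mean and sd of each metric over CV iterations, per threshold rule."""

    mean: dict  # rule -> metric -> float
    sd: dict
    thresholds: dict  # rule -> mean threshold value
    n_iterations: int
    n_skipped: int = 0

    def weight_inputs(self, rule: str = "MSS") -> tuple[float, float]:
        return self.mean[rule]["auc"], self.mean[rule]["tss"]


def make_blocks(lon: np.ndarray, lat: np.ndarray, n_blocks: int = 4) -> BlockAssignment:
    """Checkerboard of 4 rectangles balanced on point counts.

    Points are split at the median latitude; each half is split at its
    own median longitude.  Every block must hold 15%-35% of the points.
    """
    if n_blocks != 4:
        raise ValueError("the blocked-CV design uses exactly 4 blocks")
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    n = lat.size
    if n < 4 * n_blocks:
        raise ValueError("need at least 16 points for 4 blocks")
    split_lat = float(np.median(lat))
    south = lat < split_lat
    north = ~south
    if south.sum() == 0 or north.sum() == 0:
        raise ValueError("degenerate coordinates: latitude split is empty on one side")
    split_lon_low = float(np.median(lon[south]))
    split_lon_high = float(np.median(lon[north]))
    block = np.empty(n, dtype=int)
    block[south & (lon < split_lon_low)] = 1
    block[south & (lon >= split_lon_low)] = 2
    block[north & (lon < split_lon_high)] = 3
    block[north & (lon >= split_lon_high)] = 4
    frac = np.bincount(block, minlength=5)[1:] / n
    if frac.min() < 0.15 or frac.max() > 0.35:
        raise ValueError(
            f"block balance violated (fractions {np.round(frac, 3)}); "
            "coordinates too heavily duplicated to balance"
        )
    return BlockAssignment(block, split_lat, split_lon_low, split_lon_high)


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank (Mann-Whitney) AUC; ties receive half credit."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both labels")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def confusion_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float
) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, kappa, TSS) at ``score >= threshold``."""
    labels = np.asarray(labels)
    pred = np.asarray(scores, float) >= threshold
    pos, neg = labels == 1, labels == 0
    if pos.sum() == 0 or neg.sum() == 0:
        raise ValueError("confusion metrics need both labels")
    tp = float((pred & pos).sum())
    fn = float((~pred & pos).sum())
    tn = float((~pred & neg).sum())
    fp = float((pred & neg).sum())
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1 - pe) if pe < 1 else 0.0
    return sens, spec, kappa, sens + spec - 1.0


def threshold_p10(presence_scores: np.ndarray) -> ThresholdSpec:
    """10th percentile of predicted HSI at training presences (type-7 quantile)."""
    s = np.asarray(presence_scores, float)
    if s.size < 10:
        raise ValueError("P10 threshold needs >= 10 presence scores")
    return ThresholdSpec("P10", float(np.percentile(s, 10, method="linear")))


def threshold_mss(labels: np.ndarray, scores: np.ndarray) -> ThresholdSpec:
    """Threshold maximizing sensitivity + specificity; ties -> lowest.

    Candidates are midpoints between adjacent distinct scores plus the
    extremes.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    uniq = np.unique(scores)
    cand = np.clip(
        np.r_[uniq[0] - 1e-9, (uniq[:-1] + uniq[1:]) / 2.0], 0.0, 1.0
    )
    best_val, best_thr = -np.inf, cand[0]
    for thr in cand:
        sens, spec, _, _ = confusion_metrics(labels, scores, thr)
        if sens + spec > best_val + 1e-12:
            best_val, best_thr = sens + spec, thr
    return ThresholdSpec("MSS", float(best_thr))


def accuracy_class(auc_value: float, tss_value: float) -> str:
    """Good / moderate / poor accuracy class; disagreement resolves to worse."""
    def cls_auc(a):
        return "good" if a > 0.8 else ("moderate" if a >= 0.7 else "poor")

    def cls_tss(t):
        return "good" if t > 0.6 else ("moderate" if t >= 0.2 else "poor")

    order = {"poor": 0, "moderate": 1, "good": 2}
    return min(cls_auc(auc_value), cls_tss(tss_value), key=order.__getitem__)


def cv_run(
    family: str,
    table: pd.DataFrame,
    blocks: BlockAssignment,
    iterations: int = 10,
    subsample: float = 0.80,
    seed: int = 0,
    max_skips: int = 5,
    **fit_kwargs,
) -> MetricSet:
    """Blocked cross-validation of one model family.

    Each iteration draws a test block uniformly at random, trains on an
    80% subsample of the remaining blocks, computes both thresholds on
    the training data, and scores the held-out block.  A test block
    with a single label skips the iteration (logged); more than
    ``max_skips`` skips is an error.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    y_all = table["label"].to_numpy()
    block = blocks.block_of_point
    records = {rule: {m: [] for m in METRICS} for rule in THRESHOLD_RULES}
    thr_values = {rule: [] for rule in THRESHOLD_RULES}
    skipped = 0
    done = 0
    while done < iterations:
        test_block = int(rng.integers(1, 5))
        fit_seed = int(rng.integers(0, 2**31 - 1))
        test_idx = np.nonzero(block == test_block)[0]
        train_idx = np.nonzero(block != test_block)[0]
        if len(np.unique(y_all[test_idx])) < 2:
            skipped += 1
            log.warning("iteration skipped: test block %d has one label", test_block)
            if skipped > max_skips:
                raise RuntimeError(f"more than {max_skips} CV iterations skipped")
            continue
        n_sub = max(int(round(subsample * train_idx.size)), 2)
        sub = rng.choice(train_idx, size=n_sub, replace=False)
        train = table.iloc[sub]
        if len(np.unique(train["label"])) < 2:
            skipped += 1
            if skipped > max_skips:
                raise RuntimeError(f"more than {max_skips} CV iterations skipped")
            continue
        model = sdm_models.fit_family(family, train, seed=fit_seed, **fit_kwargs)
        train_scores = model.predict_table(train)
        thresholds = {
            "P10": threshold_p10(train_scores[train["label"].to_numpy() == 1]),
            "MSS": threshold_mss(train["label"].to_numpy(), train_scores),
        }
        test = table.iloc[test_idx]
        test_scores = model.predict_table(test)
        a = auc(test["label"].to_numpy(), test_scores)
        for rule, thr in thresholds.items():
            sens, spec, kap, tss = confusion_metrics(
                test["label"].to_numpy(), test_scores, thr.value
            )
            for m, v in zip(METRICS, (a, kap, sens, spec, tss)):
                records[rule][m].append(v)
            thr_values[rule].append(thr.value)
        done += 1

    mean = {r: {m: float(np.mean(v)) for m, v in records[r].items()} for r in records}
    sd = {
        r: {m: (float(np.std(v, ddof=1)) if len(v) > 1 else 0.0) for m, v in records[r].items()}
        for r in records
    }
    thresholds_mean = {r: float(np.mean(v)) for r, v in thr_values.items()}
    return MetricSet(mean, sd, thresholds_mean, iterations, skipped)


def metrics_frame(metric_sets: dict[str, MetricSet]) -> pd.DataFrame:
    """One row per (family, threshold rule): mean +/- sd of every metric."""
    rows = []
    for fam, ms in metric_sets.items():
        for rule in THRESHOLD_RULES:
            row = {"family": fam, "threshold_rule": rule,
                   "threshold": ms.thresholds[rule]}
            for m in METRICS:
                row[f"{m}_mean"] = ms.mean[rule][m]
                row[f"{m}_sd"] = ms.sd[rule][m]
            rows.append(row)
    return pd.DataFrame(rows)
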