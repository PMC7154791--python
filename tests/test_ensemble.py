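"""Weighted ensembling, permutation importance, bootstrap uncertainty."""

import numpy as np
import pandas as pd
import pytest

from bathyniche import ensemble as ens
from bathyniche.grid import GridSpec, Layer, LayerStack
from bathyniche.model_eval import MetricSet
from bathyniche.sdm_models import FittedModel, fit_maxent


def metric_set(auc, tss):
    mean = {r: {"auc": auc, "tss": tss, "kappa": 0, "sensitivity": 0, "specificity": 0}
            for r in ("P10", "MSS")}
    sd = {r: {k: 0.0 for k in mean[r]} for r in mean}
    return MetricSet(mean, sd, {"P10": 0.5, "MSS": 0.5}, 10)


class TestEnsembleWeights:
    def test_normalized_example(self):
        w = ens.EnsembleWeights.from_metrics({
            "MAXENT": metric_set(1.0, 1.0),
            "GAM": metric_set(0.5, 0.5),
            "RF": metric_set(0.5, 0.5),
        })
        assert w.weight == pytest.approx({"MAXENT": 0.5, "GAM": 0.25, "RF": 0.25})
        assert sum(w.weight.values()) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ens.EnsembleWeights.from_metrics({"A": metric_set(0.0, 0.0)})

    def test_alternative_modes(self):
        ms = {"A": metric_set(1.0, 0.0), "B": metric_set(0.0, 1.0)}
        assert ens.EnsembleWeights.from_metrics(ms, mode="auc").weight["A"] == 1.0
        assert ens.EnsembleWeights.from_metrics(ms, mode="tss").weight["B"] == 1.0


def hsi_layer(grid, value):
    return Layer(grid, "hsi", np.full(grid.shape, float(value)))


class TestEnsembleHsi:
    GRID = GridSpec(10, 10)

    def test_equal_weights_simple_mean(self):
        w = ens.EnsembleWeights({}, {}, {"A": 1/3, "B": 1/3, "C": 1/3})
        out = ens.ensemble_hsi(
            {"A": hsi_layer(self.GRID, 0.3), "B": hsi_layer(self.GRID, 0.6),
             "C": hsi_layer(self.GRID, 0.9)}, w)
        np.testing.assert_allclose(out.values, 0.6)

    def test_zero_weight_family_ignored(self):
        w = ens.EnsembleWeights({}, {}, {"A": 0.5, "B": 0.5, "C": 0.0})
        out = ens.ensemble_hsi(
            {"A": hsi_layer(self.GRID, 0.2), "B": hsi_layer(self.GRID, 0.4),
             "C": hsi_layer(self.GRID, 1.0)}, w)
        np.testing.assert_allclose(out.values, 0.3)

    def test_convex_combination_bounds(self, recovery_run):
        rr = recovery_run
        from bathyniche.sdm_models import predict_hsi
        preds = {f: predict_hsi(m, rr.present) for f, m in rr.models.items()}
        out = ens.ensemble_hsi(preds, rr.weights)
        stackmin = np.nanmin([p.values for p in preds.values()], axis=0)
        stackmax = np.nanmax([p.values for p in preds.values()], axis=0)
        m = np.isfinite(out.values)
        assert np.all(out.values[m] >= stackmin[m] - 1e-9)
        assert np.all(out.values[m] <= stackmax[m] + 1e-9)

    def test_missing_in_any_family_missing_in_ensemble(self):
        w = ens.EnsembleWeights({}, {}, {"A": 0.5, "B": 0.5})
        a = hsi_layer(self.GRID, 0.5)
        b = hsi_layer(self.GRID, 0.5)
        b.values[0, 0] = np.nan
        out = ens.ensemble_hsi({"A": a, "B": b}, w)
        assert np.isnan(out.values[0, 0])


class _IdentityModel(FittedModel):
    """Predicts its single covariate directly (for importance oracles)."""

    family = "MAXENT"

    def __init__(self, covariate, table):
        super().__init__([covariate], 0, table)
        self.cov = covariate

    def predict_table(self, table):
        return np.clip(table[self.cov].to_numpy(dtype=float), 0, 1)


class _ConstantModel(FittedModel):
    family = "RF"

    def __init__(self, table, covariates):
        super().__init__(covariates, 0, table)

    def predict_table(self, table):
        return np.full(len(table), 0.5)


def toy_table(n=1000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "cell_id": np.arange(n), "label": rng.integers(0, 2, n),
        "u": rng.random(n), "v": rng.random(n),
    })


class TestPermutationImportance:
    def test_unused_variable_exactly_zero(self):
        table = toy_table()
        model = _IdentityModel("u", table)
        mean, sd = ens.permutation_importance(model, table, "v", seed=1)
        assert mean == 0.0 and sd == 0.0

    def test_identity_model_importance_near_one(self):
        """A random permutation of the only input decorrelates predictions:
        expected Pearson r ~ 0, so 1 - r ~ 1."""
        table = toy_table(n=1000)
        model = _IdentityModel("u", table)
        mean, _ = ens.permutation_importance(model, table, "u", reps=10, seed=2)
        assert mean == pytest.approx(1.0, abs=0.15)

    def test_sd_from_ten_replicates(self):
        table = toy_table()
        model = _IdentityModel("u", table)
        _, sd = ens.permutation_importance(model, table, "u", reps=10, seed=3)
        assert sd > 0.0

    def test_constant_predictions_flagged_zero(self):
        table = toy_table()
        model = _ConstantModel(table, ["u"])
        mean, sd = ens.permutation_importance(model, table, "u", seed=4)
        assert mean == 0.0 and sd == 0.0

    def test_true_covariate_outranks_noise(self, recovery_run):
        """Rank-recovery: the temperature response niche scores higher than
        an appended pure-noise covariate in >= 8/10 seeded replicates."""
        rr = recovery_run
        rng = np.random.default_rng(9)
        table = rr.table.copy()
        table["white_noise"] = rng.random(len(table))
        covs = rr.retained + ["white_noise"]
        wins = 0
        for seed in range(10):
            model = fit_maxent(table, covariates=covs, seed=seed)
            true_imp, _ = ens.permutation_importance(model, table, "temp", seed=seed)
            noise_imp, _ = ens.permutation_importance(model, table, "white_noise", seed=seed)
            wins += true_imp > noise_imp
        assert wins >= 8


class TestEnsembleImportance:
    W = ens.EnsembleWeights({}, {}, {"MAXENT": 0.5, "GAM": 0.25, "RF": 0.25})

    def test_identical_importances_pass_through(self):
        per = {f: {"temp": (0.4, 0.1)} for f in self.W.weight}
        out = ens.ensemble_importance(per, self.W)
        assert out.loc[out.variable == "temp", "ensemble"].iloc[0] == pytest.approx(0.4)

    def test_single_family_scaled_by_weight(self):
        per = {"MAXENT": {"temp": (0.8, 0.0)}, "GAM": {}, "RF": {}}
        out = ens.ensemble_importance(per, self.W)
        assert out["ensemble"].iloc[0] == pytest.approx(0.4)

    def test_dot_product(self):
        per = {"MAXENT": {"x": (0.4, 0)}, "GAM": {"x": (0.2, 0)}, "RF": {"x": (0.2, 0)}}
        out = ens.ensemble_importance(per, self.W)
        assert out["ensemble"].iloc[0] == pytest.approx(0.30)


class TestBootstrapUncertainty:
    @pytest.fixture(scope="class")
    def setup(self, small_world):
        import bathyniche as bn
        from bathyniche import pseudo_absence as pa
        _, depth, stack = small_world
        niche = bn.default_coral_niche(stack)
        occ = bn.simulate_occurrences(stack, niche, 250, seed=41)
        presences, _, _ = bn.run_qc(occ, depth)
        mask = pa.env_profile_mask(presences, stack)
        pas = pa.sample_background(mask, presences, 1000, seed=42)
        covs = ["temp", "omega_ar", "poc_seafloor"]
        table = pa.assemble_training(presences, pas, stack, covariates=covs)
        return stack, table, covs

    def test_same_seed_identical_grid(self, setup):
        stack, table, covs = setup
        a = ens.bootstrap_uncertainty("MAXENT", table, stack, B=10, seed=5, covariates=covs)
        b = ens.bootstrap_uncertainty("MAXENT", table, stack, B=10, seed=5, covariates=covs)
        np.testing.assert_array_equal(a.values, b.values)

    def test_cv_nonnegative_where_defined(self, setup):
        stack, table, covs = setup
        out = ens.bootstrap_uncertainty("MAXENT", table, stack, B=10, seed=6, covariates=covs)
        v = out.values[np.isfinite(out.values)]
        assert (v >= 0).all()

    def test_cv_shrinks_with_sample_size(self, setup, small_world):
        import bathyniche as bn
        from bathyniche import pseudo_absence as pa
        _, depth, stack = small_world
        niche = bn.default_coral_niche(stack)
        medians = {}
        for n in (100, 800):
            occ = bn.simulate_occurrences(stack, niche, n, seed=43)
            presences, _, _ = bn.run_qc(occ, depth)
            mask = pa.env_profile_mask(presences, stack)
            pas = pa.sample_background(mask, presences, 4 * n, seed=44)
            covs = ["temp", "omega_ar", "poc_seafloor"]
            table = pa.assemble_training(presences, pas, stack, covariates=covs)
            grid = ens.bootstrap_uncertainty("MAXENT", table, stack, B=20, seed=7,
                                             covariates=covs)
            medians[n] = np.nanmedian(grid.values)
        assert medians[800] < medians[100]


class TestEnsembleUncertainty:
    GRID = GridSpec(10, 10)

    def cv_layer(self, value):
        return Layer(self.GRID, "cv", np.full(self.GRID.shape, float(value)))

    def test_identical_grids_pass_through(self):
        w = ens.EnsembleWeights({}, {}, {"A": 0.6, "B": 0.4})
        out = ens.ensemble_uncertainty({"A": self.cv_layer(0.2), "B": self.cv_layer(0.2)}, w)
        np.testing.assert_allclose(out.values, 0.2)

    def test_single_nonzero_weight(self):
        w = ens.EnsembleWeights({}, {}, {"A": 1.0, "B": 0.0})
        out = ens.ensemble_uncertainty({"A": self.cv_layer(0.3), "B": self.cv_layer(0.9)}, w)
        np.testing.assert_allclose(out.values, 0.3)

    def test_three_cell_dot_product(self):
        w = ens.EnsembleWeights({}, {}, {"A": 0.5, "B": 0.25, "C": 0.25})
        out = ens.ensemble_uncertainty(
            {"A": self.cv_layer(0.4), "B": self.cv_layer(0.2), "C": self.cv_layer(0.2)}, w)
        np.testing.assert_allclose(out.values, 0.30)


class TestBootstrapStratification:
    def test_replicates_preserve_prevalence(self, monkeypatch):
        """Label-stratified resampling keeps the training prevalence in
        every bootstrap replicate."""
        seen = []
        from bathyniche import sdm_models as sm

        real_fit = sm.fit_family

        def spy(family, table, **kw):
            seen.append(float((table["label"] == 1).mean()))
            return real_fit(family, table, **kw)

        monkeypatch.setattr(sm, "fit_family", spy)
        table = toy_table(n=400, seed=8)
        table["label"] = (np.arange(400) < 100).astype(int)  # prevalence 0.25
        ens.bootstrap_uncertainty("MAXENT", table, _ustack(GridSpec(10, 10)),
                                  B=5, seed=9, covariates=["u", "v"])
        assert seen and all(p == 0.25 for p in seen)


def _ustack(grid):
    rng = np.random.default_rng(2)
    u = Layer(grid, "u", rng.random(grid.shape))
    v = Layer(grid, "v", rng.random(grid.shape))
    return LayerStack({"u": u, "v": v})
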