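"""GPM feature assembly, selection, fitting, cross-validation, transfer,
and the elastic-net variant."""

import numpy as np
import pandas as pd
import pytest

import graphpm as g
from conftest import make_cohort_frame
from graphpm.cohort import CohortTable, ModelSpec, assemble_features
from graphpm.metrics import MetricVector
from graphpm.model import LOOCV, RepeatedKFold, fit_gpm, select_feature


def _mv(sid, state, values):
    return MetricVector(sid, state, values)


def _feature_frame(n, p, rng, prefix="task:m"):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="subject_id"),
        columns=[f"{prefix}{j:02d}" for j in range(p)],
    )


class TestModelSpec:
    def test_baseline_target_covaries_other_two_scales(self):
        spec = ModelSpec("anhedonia", "baseline")
        assert spec.covariate_columns == [
            "impulsivity_baseline", "mania_baseline", "medication_load",
        ]

    def test_followup_target_covaries_all_baselines(self):
        spec = ModelSpec("mania", "6m")
        assert spec.covariate_columns == [
            "anhedonia_baseline", "impulsivity_baseline", "mania_baseline",
            "medication_load",
        ]
        assert spec.target_column not in spec.covariate_columns

    def test_mania_defaults_to_log1p(self):
        assert ModelSpec("mania", "6m").transform == "log1p"
        assert ModelSpec("anhedonia").transform == "none"


class TestAssembleFeatures:
    def test_two_states_times_41_metrics_gives_82_columns(self):
        values = {m: 0.1 for m in (
            "characteristic_path_length", "global_efficiency", "mean_clustering",
            "mean_local_efficiency", "mean_betweenness",
        )}
        for roi in [f"roi{r}" for r in range(12)]:
            for met in ("clustering", "local_efficiency", "betweenness"):
                values[f"{roi}:{met}"] = 0.2
        assert len(values) == 41
        mvs = [_mv("s0", st, values) for st in ("task", "rest")]
        table = assemble_features(mvs, ModelSpec("anhedonia"))
        assert table.shape == (1, 82)

    def test_global_only_single_state(self):
        values = {m: 1.0 for m in (
            "characteristic_path_length", "global_efficiency", "mean_clustering",
            "mean_local_efficiency", "mean_betweenness",
        )}
        spec = ModelSpec("anhedonia", candidate_states=("task",),
                         candidate_metrics=tuple(values))
        table = assemble_features([_mv("s0", "task", values)], spec)
        assert table.shape == (1, 5)

    def test_missing_state_scan_leaves_nan(self):
        values = {"global_efficiency": 1.0}
        mvs = [_mv("s0", "task", values), _mv("s0", "rest", values),
               _mv("s1", "task", values)]
        table = assemble_features(mvs, ModelSpec("anhedonia"))
        assert np.isnan(table.loc["s1", "rest:global_efficiency"])

    def test_canonical_ordering(self):
        values = {"b_metric": 1.0, "a_metric": 2.0}
        mvs = [_mv("s0", st, values) for st in ("task", "rest")]
        cols = list(assemble_features(mvs, ModelSpec("anhedonia")).columns)
        assert cols == ["rest:a_metric", "rest:b_metric", "task:a_metric", "task:b_metric"]

    def test_no_candidates_raises(self):
        with pytest.raises(ValueError, match="no candidate features"):
            assemble_features([], ModelSpec("anhedonia"))


class TestSelectFeature:
    def test_exact_match_selected(self, rng):
        X = _feature_frame(20, 5, rng)
        y = X["task:m02"].to_numpy()
        name, r = select_feature(X, y, np.arange(20))
        assert name == "task:m02"
        assert abs(r) == pytest.approx(1.0)

    def test_tie_broken_by_canonical_order(self, rng):
        X = _feature_frame(20, 3, rng)
        X["task:m01"] = X["task:m00"]
        y = X["task:m00"].to_numpy()
        name, _ = select_feature(X, y, np.arange(20))
        assert name == "task:m00"

    def test_zero_variance_feature_skipped(self, rng):
        X = _feature_frame(15, 3, rng)
        X["task:m00"] = 1.0
        name, _ = select_feature(X, X["task:m01"].to_numpy(), np.arange(15))
        assert name == "task:m01"

    def test_all_zero_variance_raises(self):
        X = pd.DataFrame({"task:a": np.ones(10), "task:b": np.zeros(10)})
        with pytest.raises(ValueError, match="zero training variance"):
            select_feature(X, np.arange(10.0), np.arange(10))

    def test_planted_feature_selected_in_most_replicates(self):
        """beta = 1 SD effect with noise SD 0.5 on n = 80: selection finds
        the planted column in at least 80% of replicates."""
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            X = _feature_frame(80, 20, rng)
            y = X["task:m07"].to_numpy() + rng.normal(0, 0.5, 80)
            name, _ = select_feature(X, y, np.arange(80))
            hits += name == "task:m07"
        assert hits >= 80


class TestFitGpm:
    def test_exact_recovery_without_noise(self, rng):
        x = rng.normal(size=30)
        coefs = fit_gpm(x, 2.0 * x + 3.0)
        assert coefs["intercept"] == pytest.approx(3.0, abs=1e-9)
        assert coefs["brain"] == pytest.approx(2.0, abs=1e-9)

    def test_null_brain_coefficient_near_zero(self, rng):
        n = 200
        x = rng.normal(size=n)
        C = pd.DataFrame({"cov": rng.normal(size=n)})
        y = 0.5 * C["cov"].to_numpy() + rng.normal(size=n)
        coefs = fit_gpm(x, y, C)
        # 2 SE of the brain coefficient under independence ~ 2/sqrt(n)
        assert abs(coefs["brain"]) < 2.5 / np.sqrt(n)

    def test_duplicated_covariate_raises_naming_columns(self, rng):
        x = rng.normal(size=20)
        C = pd.DataFrame({"med": rng.normal(size=20)})
        C["med_copy"] = C["med"]
        with pytest.raises(ValueError, match="med"):
            fit_gpm(x, rng.normal(size=20), C)


def _planted_model(n, rng, beta=5.0, noise=0.0, p=6):
    """Features + cohort with target exactly linear in one feature."""
    X = _feature_frame(n, p, rng)
    frame = make_cohort_frame(n, rng)
    frame["anhedonia_baseline"] = (
        3.0 + beta * X["task:m03"].to_numpy() + noise * rng.normal(size=n)
    )
    cohort = CohortTable(frame)
    spec = ModelSpec("anhedonia", candidate_states=("task",), transform="none")
    return g.GraphPredictiveModel(X, cohort, spec), X


class TestCrossValidation:
    def test_noiseless_effect_predicted_exactly(self, rng):
        model, _ = _planted_model(30, rng, noise=0.0)
        res = model.fit(LOOCV())
        np.testing.assert_allclose(res.predicted, res.observed, atol=1e-8)
        assert res.mse < 1e-16

    def test_determinism_bit_identical(self, rng):
        model, _ = _planted_model(40, rng, noise=1.0)
        r1 = model.fit(RepeatedKFold(k=5, repeats=2, seed=3))
        r2 = model.fit(RepeatedKFold(k=5, repeats=2, seed=3))
        assert np.array_equal(r1.predicted, r2.predicted)
        assert r1.selected == r2.selected

    def test_fold_below_minimum_training_size_raises(self, rng):
        model, _ = _planted_model(12, rng)
        with pytest.raises(ValueError, match="training cases"):
            model.fit(RepeatedKFold(k=2, repeats=1, seed=0))

    def test_permuted_target_r_centred_on_zero(self, planted_cohort):
        """Shuffling the target kills prediction: across 50 seeded
        permutations the CV r distribution centres near 0."""
        model = planted_cohort.model()
        res = model.fit(LOOCV())
        rng = np.random.default_rng(99)
        rs = [res._pipeline(rng.permutation(res.observed)) for _ in range(50)]
        assert abs(np.mean(rs)) < 0.15
        assert np.mean(rs) < res.pearson_r  # true signal clearly higher

    def test_loocv_and_10fold_mses_similar(self, planted_cohort):
        model = planted_cohort.model()
        m_loo = model.fit(LOOCV()).mse
        m_kf = model.fit(RepeatedKFold(k=10, repeats=1, seed=0)).mse
        assert abs(m_loo - m_kf) / m_loo < 0.15

    def test_null_model_ignores_brain(self, rng):
        model, _ = _planted_model(40, rng, noise=0.5)
        null = model.fit_null(LOOCV())
        assert all(s == {} for s in null.selected)
        res = model.fit(LOOCV())
        assert res.mse < null.mse

    def test_null_mse_near_zero_when_target_is_covariate(self, rng):
        n = 40
        X = _feature_frame(n, 4, rng)
        frame = make_cohort_frame(n, rng)
        frame["anhedonia_baseline"] = 1.5 * frame["impulsivity_baseline"] - 2.0
        model = g.GraphPredictiveModel(
            X, CohortTable(frame),
            ModelSpec("anhedonia", candidate_states=("task",), transform="none"),
        )
        assert model.fit_null(LOOCV()).mse < 1e-16

    def test_log1p_applied_for_mania(self, rng):
        n = 40
        X = _feature_frame(n, 4, rng)
        frame = make_cohort_frame(n, rng)
        frame["mania_6m"] = np.expm1(
            1.0 + 0.5 * X["task:m01"].to_numpy()
        )  # log1p-linear in the feature
        model = g.GraphPredictiveModel(
            X, CohortTable(frame), ModelSpec("mania", "6m", candidate_states=("task",))
        )
        res = model.fit(LOOCV())
        np.testing.assert_allclose(res.observed, np.log1p(frame["mania_6m"]), atol=1e-12)
        assert res.mse < 0.1  # near-exact on the log scale

    def test_leakage_canary(self, planted_cohort):
        """A feature equal to the target for held-out subjects only (noise
        for training subjects) must not improve CV MSE: selection and
        fitting never see test subjects."""
        model = planted_cohort.model()
        base = model.fit(LOOCV())
        n = model.y_.size
        rng = np.random.default_rng(7)
        noise = rng.normal(size=n)
        pred = np.full(n, np.nan)
        for train, test in LOOCV().folds(n):
            canary = noise.copy()
            canary[test] = model.y_[test]  # informative only when held out
            feats = model.features_.copy()
            feats["task:zz_canary"] = canary
            m2 = g.GraphPredictiveModel(feats, model.cohort, model.spec)
            pred[test], _, _ = m2._cv_single(train, test, use_brain=True)
        canary_mse = float(np.mean((model.y_ - pred) ** 2))
        assert canary_mse >= base.mse - 1e-10


class TestMissingness:
    def test_pairwise_deletion_per_model(self, rng):
        n = 30
        X = _feature_frame(n, 4, rng)
        frame = make_cohort_frame(n, rng)
        frame.loc[frame.index[:5], "anhedonia_6m"] = np.nan
        model = g.GraphPredictiveModel(
            X, CohortTable(frame),
            ModelSpec("anhedonia", "6m", candidate_states=("task",), transform="none"),
        )
        assert model.subjects_.size == n - 5

    def test_too_few_complete_cases_raises(self, rng):
        X = _feature_frame(8, 3, rng)
        frame = make_cohort_frame(8, rng)
        model = g.GraphPredictiveModel(
            X, CohortTable(frame),
            ModelSpec("anhedonia", candidate_states=("task",), transform="none"),
        )
        with pytest.raises(ValueError, match="complete cases"):
            model.fit(LOOCV())


class TestTransfer:
    def _grouped_model(self, rng, effect_in_test=True):
        n = 80
        X = _feature_frame(n, 5, rng)
        frame = make_cohort_frame(n, rng)
        frame["group"] = ["unipolar"] * 55 + ["bipolar"] * 25
        signal = X["task:m02"].to_numpy().copy()
        if not effect_in_test:
            signal[55:] = rng.normal(size=25)  # effect absent in test group
        frame["anhedonia_baseline"] = 70 + 8.0 * signal + rng.normal(0, 2.0, n)
        cohort = CohortTable(frame)
        spec = ModelSpec("anhedonia", candidate_states=("task",), transform="none")
        return g.GraphPredictiveModel(X, cohort, spec)

    def test_shared_effect_transfers(self, rng):
        model = self._grouped_model(rng, effect_in_test=True)
        res = model.fit_transfer("unipolar", "bipolar")
        cv = model.fit(LOOCV())
        assert res.n_used == 25
        assert abs(res.mse - cv.mse) / cv.mse < 0.25
        null = model.fit_transfer_null("unipolar", "bipolar")
        assert res.mse < null.mse

    def test_effect_only_in_train_group_does_not_transfer(self, rng):
        model = self._grouped_model(rng, effect_in_test=False)
        res = model.fit_transfer("unipolar", "bipolar")
        assert abs(res.pearson_r) < 0.4  # no systematic transfer

    def test_missing_group_raises(self, rng):
        model = self._grouped_model(rng)
        with pytest.raises(ValueError, match="no complete cases"):
            model.fit_transfer("unipolar", "schizoaffective")


class TestElasticNet:
    def test_alpha_grid_has_21_values(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 2)
        assert grid.size == 21
        assert grid[0] == 0.0 and grid[-1] == 1.0

    def test_informative_feature_gets_nonzero_coefficient(self):
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(8800 + rep)
            n = 60
            X = _feature_frame(n, 41, rng)
            frame = make_cohort_frame(n, rng)
            frame["anhedonia_baseline"] = (
                70 + 6.0 * X["task:m20"].to_numpy() + rng.normal(0, 2.0, n)
            )
            model = g.GraphPredictiveModel(
                X, CohortTable(frame),
                ModelSpec("anhedonia", candidate_states=("task",), transform="none"),
            )
            res = model.fit_elastic_net(
                RepeatedKFold(k=5, repeats=1, seed=rep), n_lambda=10, inner_folds=3
            )
            nz = [s["nonzero"] for s in res.selected]
            hits += all("task:m20" in fold_nz for fold_nz in nz)
        assert hits >= 8

    def test_infinite_penalty_reduces_to_covariate_model(self, rng):
        model, _ = _planted_model(40, rng, noise=1.0)
        scheme = RepeatedKFold(k=5, repeats=1, seed=1)
        res = model.fit_elastic_net(scheme, lambda_grid=np.array([1e9]), inner_folds=3)
        null = model.fit_null(scheme)
        np.testing.assert_allclose(res.predicted, null.predicted, atol=1e-6)
        assert all(s["nonzero"] == [] for s in res.selected)


def test_prediction_plot_smoke(rng):
    import matplotlib
    matplotlib.use("Agg")
    model, _ = _planted_model(30, rng, noise=1.0)
    ax = model.fit(LOOCV()).plot()
    assert ax.get_xlabel() == "observed score"
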