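"""Permeability regressor: fitting, predictive distribution, LOOCV metrics,
and similarity queries."""

import numpy as np
import pandas as pd
import pytest

from linkergen.chem import BIT_FP_2048, FingerprintSpec, morgan_fingerprint
from linkergen.errors import ConfigError
from linkergen.fixtures import generate_permeability_dataset
from linkergen.permeability import (
    PermeabilityDataset,
    PermeabilityRegressor,
    PredictiveDistribution,
    compute_metrics,
    loocv_evaluate,
    max_tanimoto_to_reference,
    register_regressor,
    REGRESSOR_FACTORIES,
)


class TestFit:
    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            PermeabilityRegressor().fit(["CCO", "CCC"], [0.1, 0.2])

    def test_unknown_regressor_rejected(self):
        est = PermeabilityRegressor(regressor="nonexistent")
        with pytest.raises(ConfigError):
            est.fit(["CCO", "CCC", "CCN"], [0.1, 0.2, 0.3])

    def test_linear_feature_rule_capacity(self, permeability_data):
        # target is an exact linear function of one fingerprint count; the
        # default ensemble must memorize training and generalize on average
        ds100, _ = generate_permeability_dataset(100, seed=3)
        spec = FingerprintSpec(2, 500, True)
        F = np.vstack([morgan_fingerprint(s, spec) for s in ds100.smiles])
        idx = int(np.argmax(F.var(axis=0)))
        y = 0.05 * F[:, idx]
        est = PermeabilityRegressor(quantiles=()).fit(ds100.smiles[:50], y[:50])
        train_err = np.abs(est.predict(ds100.smiles[:50]) - y[:50])
        test_err = np.abs(est.predict(ds100.smiles[50:]) - y[50:])
        assert train_err.max() < 0.05
        assert test_err.mean() < 0.05

    def test_duplicate_record_memorized(self, permeability_data, fitted_model):
        dataset, _ = permeability_data
        pred = fitted_model.predict([dataset.smiles[0]])[0]
        assert abs(pred - dataset.y[0]) < 0.1

    def test_prediction_invariant_to_record_order(self, permeability_data):
        dataset, _ = permeability_data
        probe = dataset.smiles[0]
        a = PermeabilityRegressor(quantiles=(), random_state=0).fit(
            dataset.smiles, dataset.y
        )
        order = np.random.default_rng(5).permutation(len(dataset))
        b = PermeabilityRegressor(quantiles=(), random_state=0).fit(
            [dataset.smiles[i] for i in order], dataset.y[order]
        )
        assert a.predict([probe])[0] == pytest.approx(b.predict([probe])[0], abs=1e-9)

    def test_canonical_invariance_of_predictions(self, fitted_model):
        d1 = fitted_model.predict(["OCCOCCO"])[0]
        d2 = fitted_model.predict(["C(O)COCCO"])[0]
        assert d1 == pytest.approx(d2, abs=1e-12)


class TestPredictiveDistribution:
    def test_percentiles_monotone(self, permeability_data):
        dataset, _ = permeability_data
        est = PermeabilityRegressor().fit_dataset(dataset)
        dist = est.predict_distribution(dataset.smiles[3])
        qs = [dist.percentile(q) for q in (10, 30, 50, 70, 90)]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        assert np.isfinite(dist.mean)

    def test_median_between_30_and_70(self):
        dist = PredictiveDistribution(0.0, (10, 30, 50, 70, 90), (0.5, -1, 0, 1, 2))
        assert dist.percentile(30) <= dist.percentile(50) <= dist.percentile(70)

    def test_crossing_quantiles_rearranged(self):
        dist = PredictiveDistribution(0.0, (10, 90), (1.0, -1.0))
        assert dist.percentile(10) <= dist.percentile(90)


class TestDataset:
    def test_duplicate_smiles_rejected(self):
        df = pd.DataFrame({"smiles": ["CCO", "OCC"], "raw_papp": ["1", "2"]})
        with pytest.raises(ValueError):
            PermeabilityDataset.from_table(df)

    def test_censored_roundtrip_via_csv(self, tmp_path):
        df = pd.DataFrame({"smiles": ["CCO", "CCN", "CCC"], "raw_papp": ["<2", "3", "0.5"]})
        ds = PermeabilityDataset.from_table(df)
        path = tmp_path / "perm.csv"
        ds.to_csv(path)
        back = PermeabilityDataset.from_csv(path)
        assert [r.papp for r in back.records] == [1.0, 3.0, 0.5]
        assert [r.censored for r in back.records] == [True, False, False]


def _oracle_factory(truth: dict):
    """Regressor factory that looks up the true target by feature row."""

    class Oracle:
        def fit(self, X, y):
            return self

        def predict(self, X):
            return np.array([truth[tuple(row)] for row in np.asarray(X)])

    return lambda params, random_state, quantile: Oracle()


class TestLoocv:
    def test_perfect_predictor_yields_r2_one(self, permeability_data):
        dataset, _ = permeability_data
        est = PermeabilityRegressor(regressor="oracle", quantiles=())
        F = est._featurize(dataset.smiles)
        truth = {tuple(row): y for row, y in zip(F.to_numpy(), dataset.y)}
        register_regressor("oracle", _oracle_factory(truth))
        try:
            metrics, _ = loocv_evaluate(dataset, est)
        finally:
            REGRESSOR_FACTORIES.pop("oracle")
        assert metrics.r2 == pytest.approx(1.0)
        assert metrics.rmse == pytest.approx(0.0, abs=1e-12)

    def test_constant_regressor_nonpositive_r2(self, permeability_data):
        # the leave-one-out mean of the other n-1 targets always scores r2 <= 0
        dataset, _ = permeability_data

        class ConstantMean:
            def fit(self, X, y):
                self.mean_ = float(np.mean(y))
                return self

            def predict(self, X):
                return np.full(len(X), self.mean_)

        register_regressor("constant", lambda p, r, q: ConstantMean())
        est = PermeabilityRegressor(regressor="constant", quantiles=())
        try:
            metrics, _ = loocv_evaluate(dataset, est)
        finally:
            REGRESSOR_FACTORIES.pop("constant")
        assert metrics.r2 <= 0

    def test_metrics_identity(self, permeability_data):
        dataset, _ = permeability_data
        metrics, table = loocv_evaluate(
            dataset, PermeabilityRegressor(quantiles=())
        )
        y = table.y_true.to_numpy()
        sst = float(((y - y.mean()) ** 2).sum())
        assert metrics.r2 == pytest.approx(
            1 - len(y) * metrics.rmse**2 / sst, abs=1e-9
        )

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            loocv_evaluate((["CCO", "CCC"], [0.1, 0.2]))


class TestMaxTanimoto:
    def test_member_query_is_one(self):
        fps = [morgan_fingerprint(s, BIT_FP_2048) for s in ("CCO", "CCC")]
        assert max_tanimoto_to_reference("CCO", fps) == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            max_tanimoto_to_reference("CCO", [])


def test_persistence_roundtrip(tmp_path, permeability_data, fitted_model):
    dataset, _ = permeability_data
    path = tmp_path / "model.joblib"
    fitted_model.save(path)
    loaded = PermeabilityRegressor.load(path)
    probe = dataset.smiles[0]
    assert loaded.predict([probe])[0] == fitted_model.predict([probe])[0]
    assert len(loaded.train_ad_fps_) == len(dataset)
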