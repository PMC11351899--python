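import numpy as np
import pytest

from eegimpute.engine import impute_feature, plan_order, run_pipeline
from eegimpute.synthetic import (MissingnessSpec, SyntheticConfig,
                                 generate_complete, inject_missingness)
from eegimpute.tabular import TabularDataset, partition_columns
from eegimpute.transformer import TransformerConfig

QUICK = TransformerConfig(seed=0, max_epochs=10, batch_size=64, lr=3e-3,
                          dropout=0.0, n_layers=1, d_model=16, n_heads=2,
                          d_ff=32)


def masked_copy(values, holes):
    v = values.copy()
    for i, j in holes:
        v[i, j] = np.nan
    return v


class TestPlanOrder:
    def test_ascending_missing_count_with_stable_ties(self, rng):
        values = rng.normal(size=(20, 4))
        holes = [(i, 1) for i in range(10)] + \
                [(i, 2) for i in range(3)] + [(i, 3) for i in range(3)]
        ds = TabularDataset(masked_copy(values, holes),
                            ["f0", "f1", "f2", "f3"], np.arange(20))
        part = partition_columns(ds, ds.col_names)
        assert plan_order(ds, part) == ["f2", "f3", "f1"]

    def test_single_and_empty_plans(self, rng):
        values = rng.normal(size=(10, 3))
        complete = TabularDataset(values, ["a", "b", "c"], np.arange(10))
        part = partition_columns(complete, complete.col_names)
        assert plan_order(complete, part) == []
        ds = TabularDataset(masked_copy(values, [(0, 1)]),
                            ["a", "b", "c"], np.arange(10))
        part = partition_columns(ds, ds.col_names)
        assert plan_order(ds, part) == ["b"]


class TestImputeFeature:
    def test_column_complete_after_call_and_observed_untouched(self, rng):
        values = rng.normal(size=(60, 4))
        holes = [(i, 3) for i in range(0, 60, 7)]
        ds = TabularDataset(masked_copy(values, holes),
                            ["a", "b", "c", "d"], np.arange(60))
        out, trace, model = impute_feature(ds, "d", ["a", "b", "c"], QUICK)
        assert not out.mask[:, 3].any()
        obs = ~ds.mask[:, 3]
        np.testing.assert_array_equal(out.values[obs, 3], ds.values[obs, 3])
        assert trace.n_imputed == len(holes)
        assert trace.n_train == 60 - len(holes)
        assert trace.method == "transformer" and model is not None

    def test_constant_column_imputed_exactly(self, rng):
        values = rng.normal(size=(40, 3))
        values[:, 2] = 5.5
        holes = [(i, 2) for i in range(0, 40, 5)]
        ds = TabularDataset(masked_copy(values, holes), ["a", "b", "c"],
                            np.arange(40))
        out, trace, _ = impute_feature(ds, "c", ["a", "b"], QUICK)
        np.testing.assert_allclose(out.values[:, 2], 5.5, atol=1e-3)
        assert trace.method == "constant"

    def test_sparse_column_falls_back_to_mean(self, rng, caplog):
        values = rng.normal(size=(30, 3))
        holes = [(i, 2) for i in range(18)]  # only 12 observed < threshold
        ds = TabularDataset(masked_copy(values, holes), ["a", "b", "c"],
                            np.arange(30))
        with caplog.at_level("WARNING"):
            out, trace, model = impute_feature(ds, "c", ["a", "b"], QUICK)
        assert trace.method == "mean"
        assert model is None
        expected = ds.values[~ds.mask[:, 2], 2].mean()
        np.testing.assert_allclose(out.values[:18, 2], expected)
        assert any("mean imputation" in r.message for r in caplog.records)

    def test_incomplete_predictors_rejected(self, rng):
        values = rng.normal(size=(30, 3))
        ds = TabularDataset(masked_copy(values, [(0, 0), (1, 2)]),
                            ["a", "b", "c"], np.arange(30))
        with pytest.raises(ValueError, match="predictor"):
            impute_feature(ds, "c", ["a", "b"], QUICK)

    def test_linear_column_recovered_on_noiseless_data(self, rng):
        # target column is an exact linear map of the predictors
        n = 800
        X = rng.normal(size=(n, 3))
        w = np.array([1.0, -2.0, 0.5])
        values = np.column_stack([X, X @ w])
        holes = [(i, 3) for i in range(0, n, 10)]
        ds = TabularDataset(masked_copy(values, holes),
                            ["a", "b", "c", "d"], np.arange(n))
        cfg = TransformerConfig(seed=1, max_epochs=60, batch_size=128,
                                lr=3e-3, dropout=0.0, n_layers=1)
        out, _, _ = impute_feature(ds, "d", ["a", "b", "c"], cfg)
        idx = [i for i, _ in holes]
        truth = values[idx, 3]
        resid = out.values[idx, 3] - truth
        r2 = 1 - np.sum(resid ** 2) / np.sum((truth - truth.mean()) ** 2)
        assert r2 > 0.95


class TestRunPipeline:
    @pytest.fixture
    def scenario(self):
        complete = generate_complete(SyntheticConfig(
            n_rows=300, n_channels=6, seed=20))
        truth = inject_missingness(complete, MissingnessSpec(
            rate=0.1, min_complete_rows=20, seed=21,
            exempt_cols=("Timestamp", "Cognitive_State_Index",
                         "Channel_1", "Channel_3", "Channel_5")))
        return truth

    def test_output_complete_and_in_original_order(self, scenario):
        out, trace = run_pipeline(
            scenario.masked, QUICK,
            id_cols=["Timestamp", "Cognitive_State_Index"])
        assert not out.mask.any()
        assert out.row_ids.tolist() == scenario.masked.row_ids.tolist()

    def test_observed_cells_bit_identical(self, scenario):
        masked = scenario.masked
        out, _ = run_pipeline(masked, QUICK,
                              id_cols=["Timestamp", "Cognitive_State_Index"])
        for c in masked.col_names:
            src = masked.column(c)
            obs = ~np.isnan(src)
            got = out.column(c)
            np.testing.assert_array_equal(got[obs], src[obs])

    def test_trace_conserves_missing_counts_and_order(self, scenario):
        masked = scenario.masked
        counts = masked.missing_counts()
        out, trace = run_pipeline(masked, QUICK,
                                  id_cols=["Timestamp",
                                           "Cognitive_State_Index"])
        assert sorted(trace.order) == sorted(
            c for c, k in counts.items() if k > 0)
        for entry in trace.per_column:
            assert entry.n_imputed == counts[entry.column]
        # ascending missingness order
        imputed_counts = [counts[c] for c in trace.order]
        assert imputed_counts == sorted(imputed_counts)

    def test_complete_input_is_identity(self, rng):
        values = rng.normal(size=(30, 4))
        ds = TabularDataset(values, ["a", "b", "c", "d"], np.arange(30))
        out, trace = run_pipeline(ds, QUICK)
        np.testing.assert_array_equal(out.values, ds.values)
        assert trace.order == [] and trace.per_column == []

    def test_no_complete_feature_column_rejected(self, rng):
        values = rng.normal(size=(30, 2))
        values[0, 0] = np.nan
        values[1, 1] = np.nan
        ds = TabularDataset(values, ["a", "b"], np.arange(30))
        with pytest.raises(ValueError, match="baseline"):
            run_pipeline(ds, QUICK)

    def test_no_complete_row_rejected(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(30, 3))
        values[:15, 1] = np.nan
        values[15:, 2] = np.nan
        ds = TabularDataset(values, ["a", "b", "c"], np.arange(30))
        with pytest.raises(ValueError, match="complete row"):
            run_pipeline(ds, QUICK)

    def test_masked_id_columns_rejected(self, rng):
        values = rng.normal(size=(30, 3))
        values[0, 0] = np.nan
        ds = TabularDataset(values, ["t", "a", "b"], np.arange(30))
        with pytest.raises(ValueError, match="id-like"):
            run_pipeline(ds, QUICK, id_cols=["t"])

    def test_predictor_set_grows_monotonically(self, scenario):
        # train counts can only benefit from previously imputed columns:
        # every later column sees >= the initially complete predictors
        out, trace = run_pipeline(scenario.masked, QUICK,
                                  id_cols=["Timestamp",
                                           "Cognitive_State_Index"])
        assert [e.column for e in trace.per_column] == trace.order
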