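import numpy as np
import pandas as pd
import pytest

from omibone.metabolome import (
    IntensityTable,
    filter_detection,
    knn_impute,
    log_autoscale,
    pqn_normalize,
    preprocess,
    rsd_filter,
)


def _table(values, qc):
    frame = pd.DataFrame(np.asarray(values, dtype=float))
    return IntensityTable(values=frame, qc=np.asarray(qc, dtype=bool))


class TestDetectionFilter:
    def test_feature_failing_qc_rule_removed(self):
        # feature 0: 40% of QC, 100% of biological -> removed
        vals = np.ones((7, 2))
        vals[2:5, 0] = np.nan  # QC rows are 2..6 (5 of them); 3 missing
        t = _table(vals, [0, 0, 1, 1, 1, 1, 1])
        out = filter_detection(t)
        assert out.values.shape[1] == 1

    def test_fully_detected_feature_kept(self):
        t = _table(np.ones((5, 3)), [0, 0, 0, 1, 1])
        assert filter_detection(t).values.shape[1] == 3

    def test_enumerated_presence_patterns(self):
        # 4 QC + 5 bio samples, 10 features with known detection rates;
        # survivors require >=50% QC AND >=80% bio presence
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(size=(9, 10)))
        qc = np.r_[np.ones(4, dtype=bool), np.zeros(5, dtype=bool)]
        qc_missing = [0, 1, 2, 3, 0, 2, 3, 0, 1, 0]   # of 4 QC rows
        bio_missing = [0, 0, 0, 0, 1, 1, 1, 2, 2, 3]  # of 5 bio rows
        for j, (mq, mb) in enumerate(zip(qc_missing, bio_missing)):
            vals[:mq, j] = np.nan
            vals[4:4 + mb, j] = np.nan
        t = IntensityTable(pd.DataFrame(vals), qc=qc)
        expected = [
            j for j in range(10)
            if (4 - qc_missing[j]) / 4 >= 0.5 and (5 - bio_missing[j]) / 5 >= 0.8
        ]
        out = filter_detection(t)
        assert list(out.values.columns) == expected

    def test_threshold_bounds_checked(self):
        t = _table(np.ones((3, 2)), [1, 0, 0])
        with pytest.raises(ValueError):
            filter_detection(t, qc_min=1.5)


class TestKnnImpute:
    def test_k1_copies_unique_nearest_neighbour(self):
        vals = np.array([
            [1.0, 10.0, 5.0],
            [1.0, 10.0, np.nan],
            [50.0, 90.0, 100.0],
        ])
        t = _table(vals, [0, 0, 0])
        out = knn_impute(t, k=1)
        assert out.values.iloc[1, 2] == pytest.approx(5.0)

    def test_complete_table_is_identity(self, toy_intensity):
        complete = toy_intensity.with_values(toy_intensity.values.fillna(1.0))
        out = knn_impute(complete, k=2)
        pd.testing.assert_frame_equal(out.values, complete.values)

    def test_hand_distance_mean_of_two_neighbours(self):
        # 6x4 toy; distances computed by hand on log intensities over
        # shared features place rows 1 and 2 nearest to row 0
        base = np.exp(np.array([
            [1.0, 2.0, np.nan, 3.0],
            [1.1, 2.0, 4.0, 3.0],
            [0.9, 2.1, 6.0, 3.0],
            [9.0, 9.0, 9.0, 9.0],
            [8.0, 8.5, 9.0, 9.5],
            [7.5, 8.0, 9.5, 9.0],
        ]))
        t = _table(base, [0] * 6)
        out = knn_impute(t, k=2)
        logs = np.log(base)
        d = []
        for i in range(1, 6):
            shared = ~np.isnan(logs[0])
            diff = logs[0, shared] - logs[i, shared]
            d.append(np.sqrt((diff**2).mean() * 4))
        nearest = np.argsort(d)[:2] + 1
        expected = np.exp(np.mean([logs[i, 2] for i in nearest]))
        assert out.values.iloc[0, 2] == pytest.approx(expected, rel=1e-10)

    def test_observed_entries_unchanged(self, toy_intensity):
        out = knn_impute(toy_intensity, k=3)
        mask = toy_intensity.values.notna().to_numpy()
        np.testing.assert_array_equal(
            out.values.to_numpy()[mask],
            toy_intensity.values.to_numpy()[mask],
        )

    def test_k_at_least_sample_count_rejected(self, toy_intensity):
        with pytest.raises(ValueError, match="sample count"):
            knn_impute(toy_intensity, k=9)


class TestPqn:
    def test_identical_samples_unchanged(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        t = _table(vals, [0, 0, 0, 1, 1])
        out = pqn_normalize(t)
        np.testing.assert_allclose(out.values.to_numpy(), vals)

    def test_doubled_sample_recovers_reference(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        vals = np.vstack([ref, ref, 2.0 * ref])
        t = _table(vals, [1, 1, 0])
        out = pqn_normalize(t)
        np.testing.assert_allclose(out.values.iloc[2].to_numpy(), ref)

    def test_sparse_perturbation_preserved(self):
        # 10% of features perturbed: dilution factor stays 1, the
        # perturbations survive normalisation
        ref = np.linspace(1, 20, 20)
        sample = ref.copy()
        sample[3] *= 5.0
        sample[11] *= 0.2
        vals = np.vstack([ref, ref, sample])
        t = _table(vals, [1, 1, 0])
        out = pqn_normalize(t)
        np.testing.assert_allclose(out.values.iloc[2].to_numpy(), sample)

    def test_rank_order_preserved_within_sample(self):
        rng = np.random.default_rng(5)
        vals = np.exp(rng.normal(size=(6, 15)))
        t = _table(vals, [1, 1, 0, 0, 0, 0])
        out = pqn_normalize(t)
        for i in range(6):
            orig = np.argsort(vals[i])
            new = np.argsort(out.values.iloc[i].to_numpy())
            assert (orig == new).all()

    def test_nonpositive_values_rejected(self):
        t = _table(np.ones((3, 2)), [1, 0, 0])
        t.values.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            pqn_normalize(t)


class TestRsdFilter:
    def test_constant_qc_feature_kept(self):
        vals = np.column_stack([np.ones(4), [1.0, 2.0, 3.0, 2.0]])
        t = _table(vals, [1, 1, 1, 0])
        out = rsd_filter(t, max_rsd=0.30)
        assert 0 in out.values.columns

    def test_hand_rsd_fifty_percent_removed(self):
        # QC values [1,2,3]: sd=1, mean=2, RSD=50% -> removed at 30%
        vals = np.column_stack([[1.0, 2.0, 3.0, 2.0], np.ones(4)])
        t = _table(vals, [1, 1, 1, 0])
        out = rsd_filter(t, max_rsd=0.30)
        assert list(out.values.columns) == [1]

    def test_infinite_threshold_is_identity(self, toy_intensity):
        complete = toy_intensity.with_values(toy_intensity.values.fillna(2.0))
        out = rsd_filter(complete, max_rsd=np.inf)
        assert out.values.shape == complete.values.shape

    def test_needs_two_qc_samples(self):
        t = _table(np.ones((3, 2)), [1, 0, 0])
        with pytest.raises(ValueError, match="two QC"):
            rsd_filter(t)


class TestLogAutoscale:
    def test_hand_computation_geometric_series(self):
        # [1, e, e^2] -> log [0,1,2] -> scaled [-1,0,1] (n-1 denominator)
        vals = np.column_stack([[1.0, np.e, np.e**2]] * 2)
        t = _table(vals, [0, 0, 0])
        out = log_autoscale(t)
        np.testing.assert_allclose(out.iloc[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_output_columns_standardized(self, toy_intensity):
        complete = knn_impute(toy_intensity, k=3)
        out = log_autoscale(complete)
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert np.abs(out.var(axis=0, ddof=1) - 1).max() < 1e-10

    def test_constant_feature_named_in_error(self):
        vals = np.column_stack([np.full(4, 3.0), [1.0, 2.0, 3.0, 4.0]])
        frame = pd.DataFrame(vals, columns=["flat", "ok"])
        t = IntensityTable(frame, qc=np.zeros(4, dtype=bool))
        with pytest.raises(ValueError, match="flat"):
            log_autoscale(t)


def test_pipeline_order_regression(toy_intensity):
    """The fixed chain equals applying each stage in the stated order."""
    step = filter_detection(toy_intensity, 0.5, 0.8)
    step = knn_impute(step, k=3)
    step = pqn_normalize(step, reference="qc")
    step = rsd_filter(step, 0.30)
    manual = log_autoscale(step)
    auto = preprocess(toy_intensity, k=3)
    pd.testing.assert_frame_equal(auto, manual)


def test_zero_encoded_missing_rejected():
    frame = pd.DataFrame([[0.0, 1.0], [1.0, 2.0]])
    with pytest.raises(ValueError, match="NaN"):
        IntensityTable(frame, qc=np.array([True, False]))
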