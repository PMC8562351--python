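"""Leave-one-out cross-validation protocol, hyperparameter selection, and
sensitivity experiments."""

import numpy as np
import pytest

from lssnd import loocv as lv
from lssnd import spectra as sp
from lssnd.cnn import NetworkSpec, TrainingConfig

from conftest import NULL_COHORT_AGES, make_small_cohort

# protocol patience (100 epochs) is needed to outlast the initial ReLU
# plateau; these tiny folds train in a couple of seconds regardless
QUICK = TrainingConfig(learning_rate=0.01, min_delta=0.001)


class TestFolds:
    def test_22_samples_give_22_folds_of_20_training_samples(self):
        ids = [f"S{i:02d}" for i in range(22)]
        folds = lv.make_loocv_folds(ids, seed=0)
        assert len(folds) == 22
        assert all(len(f.training_sample_ids) == 20 for f in folds)

    def test_each_sample_tests_exactly_once(self):
        ids = [f"S{i}" for i in range(9)]
        folds = lv.make_loocv_folds(ids, seed=1)
        assert sorted(f.test_sample_id for f in folds) == sorted(ids)

    def test_validation_choice_deterministic(self):
        ids = [f"S{i}" for i in range(8)]
        a = lv.make_loocv_folds(ids, seed=5)
        b = lv.make_loocv_folds(ids, seed=5)
        assert [f.validation_sample_id for f in a] == \
            [f.validation_sample_id for f in b]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            lv.make_loocv_folds(["a", "b"], seed=0)

    def test_leaky_split_rejected(self):
        with pytest.raises(ValueError):
            lv.FoldSplit(0, "a", "b", ("a", "c"))


class TestAccuracy:
    def test_arithmetic(self):
        m = lv.ConfusionMatrix(np.diag([10, 5, 4]))
        assert lv.accuracy(m) == 1.0
        m2 = lv.ConfusionMatrix(np.ones((3, 3), int))
        assert np.isclose(lv.accuracy(m2), 3 / 9)
        m3 = lv.ConfusionMatrix(np.array([[19, 1, 0], [0, 0, 0], [0, 0, 0]]))
        assert np.isclose(lv.accuracy(m3), 0.95)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            lv.accuracy(lv.ConfusionMatrix(np.zeros((3, 3), int)))


class TestSelection:
    def test_highest_accuracy_wins(self):
        r = [{"validation_accuracy": 0.8, "validation_loss": 0.1, "id": 0},
             {"validation_accuracy": 1.0, "validation_loss": 0.9, "id": 1}]
        assert lv._select_best(r)["id"] == 1

    def test_tie_broken_by_lower_loss(self):
        r = [{"validation_accuracy": 1.0, "validation_loss": 0.5, "id": 0},
             {"validation_accuracy": 1.0, "validation_loss": 0.2, "id": 1},
             {"validation_accuracy": 1.0, "validation_loss": 0.3, "id": 2}]
        assert lv._select_best(r)["id"] == 1

    def test_single_point_grid_returned(self, small_dataset):
        _, ds = small_dataset
        folds = lv.make_loocv_folds(ds.unique_samples, seed=0)
        grid = lv.HyperGrid(learning_rates=(0.01,), min_deltas=(0.001,))
        cfg, model, _ = lv.grid_search_fold(folds[0], ds, grid,
                                            base_config=QUICK, seed=0)
        assert cfg.learning_rate == 0.01
        assert cfg.min_delta == 0.001


class TestHyperGrid:
    def test_default_grid_is_10_by_4(self):
        g = lv.HyperGrid()
        assert len(g.points()) == 40
        assert np.isclose(g.learning_rates[0], 1e-4)
        assert np.isclose(g.learning_rates[-1], 1e-2)
        ratios = np.diff(np.log(g.learning_rates))
        assert np.allclose(ratios, ratios[0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            lv.HyperGrid(learning_rates=())


class TestRunLOOCV:
    def test_separable_cohort_high_accuracy_and_bookkeeping(
            self, small_dataset):
        _, ds = small_dataset
        grid = lv.HyperGrid(learning_rates=(0.002, 0.005, 0.01),
                            min_deltas=(0.001,))
        report = lv.run_loocv(ds, grid, base_config=QUICK, seed=3)
        assert len(report.folds) == len(ds.unique_samples)
        assert report.aggregate_accuracy >= 0.95
        # Eq.-1 accuracy identical to confusion-matrix trace/total
        assert report.aggregate_accuracy == \
            report.confusion.n_correct / report.confusion.n_total
        assert report.confusion.n_total == ds.X.shape[0]

    def test_leakage_detected(self, small_dataset):
        _, ds = small_dataset
        ids = ds.unique_samples
        bad = lv.FoldSplit(0, ids[0], ids[1], tuple(ids[2:]))
        # corrupt the split after construction: validation sample in training
        object.__setattr__(bad, "training_sample_ids", tuple(ids[1:]))
        with pytest.raises(lv.LeakageError):
            lv.grid_search_fold(
                bad, ds, lv.HyperGrid(learning_rates=(0.01,),
                                      min_deltas=(0.001,)),
                base_config=QUICK, seed=0)

    def test_label_permutation_near_chance(self):
        ages = NULL_COHORT_AGES
        _, ds = make_small_cohort(n_acquisitions=4, seed=2, ages=ages)
        rng = np.random.default_rng(0)
        ids = ds.unique_samples
        shuffled = rng.permutation([ds.sample_classes[s] for s in ids])
        ds_null = lv.SpectraDataset(ds.X, ds.sample_ids,
                                    dict(zip(ids, shuffled)))
        grid = lv.HyperGrid(learning_rates=(0.005,), min_deltas=(0.001,))
        report = lv.run_loocv(ds_null, grid, base_config=QUICK, seed=1)
        n = len(ids)
        band = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
        # leave-one-out under permuted labels is biased at or below chance
        # (the held-out sample's class is always the training minority), so
        # the sound check is one-sided: no better than chance
        assert report.aggregate_accuracy <= 1 / 3 + band


class TestFisherLSD:
    def test_clearly_different_group_detected(self):
        g = [np.array([0.5, 0.55, 0.6]), np.array([0.52, 0.57, 0.62]),
             np.array([0.95, 0.96, 0.97])]
        F, p, sig = lv.fisher_lsd(g)
        assert p < 0.01
        assert (0, 2) in sig and (1, 2) in sig

    def test_identical_groups_no_significance(self):
        g = [np.array([0.8, 0.8]), np.array([0.8, 0.8])]
        F, p, sig = lv.fisher_lsd(g)
        assert sig == ()
        assert p == 1.0


class TestWavelengthSensitivity:
    def _window_localized_records(self, n_samples=12, n_acq=4, n=240):
        """Toy study whose class signal lives only in the 900-1100 nm third."""
        rng = np.random.default_rng(0)
        wl = np.linspace(500.0, 1100.0, n)
        # zero-integral oscillatory signature confined to [900, 1100) so the
        # mean normalization carries no class information into other windows
        bump = np.exp(-0.5 * ((wl - 1000.0) / 40.0) ** 2) \
            * np.sin(2 * np.pi * (wl - 900.0) / 50.0) * (wl >= 900)
        records, classes = [], {}
        for i in range(n_samples):
            cls = ("low", "medium", "high")[i % 3]
            classes[f"S{i}"] = cls
            amp = {"low": -0.2, "medium": 0.0, "high": 0.2}[cls]
            for a in range(n_acq):
                for fiber in ("R1", "R2"):
                    trace = 2.0 + amp * bump + rng.normal(0, 0.003, n)
                    records.append(sp.SpectrumRecord(
                        wl.copy(), trace, f"S{i}", fiber, a))
        return records, classes

    def test_signal_window_wins_and_is_significant(self):
        records, classes = self._window_localized_records()
        result = lv.wavelength_sensitivity_experiment(
            records, classes, train_config=QUICK,
            filter_spec=sp.FilterSpec(sd_measures=3, kernel_measures=12),
            seed=0)
        means = result["mean_accuracies"]
        assert means[2] == max(means)
        assert means[2] > means[1]
        assert (0, 2) in result["significant_pairs"] \
            or (1, 2) in result["significant_pairs"]


class TestResolutionSensitivity:
    def test_scale_schedule(self):
        ks = lv.resolution_scale_schedule()
        assert len(ks) == 15
        assert np.isclose(ks[0], 10.0) and np.isclose(ks[-1], 1000.0)
        ratios = ks[1:] / ks[:-1]
        assert np.allclose(ratios, ratios[0], atol=1e-9)

    def test_small_sweep_returns_table(self, small_dataset):
        _, ds = small_dataset
        table = lv.resolution_sensitivity_experiment(
            ds, train_config=QUICK, scales=np.array([2.0, 4.0]), seed=0)
        assert list(table["K"]) == [2.0, 4.0]
        assert np.all(table["mean_accuracy"] >= 0)

    def test_overlarge_k_names_scale(self, small_dataset):
        _, ds = small_dataset
        with pytest.raises(RuntimeError, match="K="):
            lv.resolution_sensitivity_experiment(
                ds, train_config=QUICK, scales=np.array([5000.0]), seed=0)
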