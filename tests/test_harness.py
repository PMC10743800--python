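import numpy as np
import pytest

from projage.harness import (
    ChannelDataset,
    ProjectionCache,
    constant_predictor_mae,
    evaluate,
    make_splits,
    parse_channel_spec,
    project_subject,
    project_volume,
    train_model,
    uniform_channel_spec,
)
from projage.model import ModelConfig, build_model
from projage.moments import moment_map
from projage.phantom import PhantomConfig, generate_cohort
from projage.volume_io import SubjectRecord

from .conftest import random_volume


class TestMakeSplits:
    def test_biobank_scale_split_sizes(self):
        plan = make_splits([f"s{i}" for i in range(29_035)], seed=0)
        assert len(plan.train_ids) == 20_325
        assert len(plan.val_ids) == 4_355
        assert len(plan.test_ids) == 4_355

    def test_small_cohort_floor_rule(self):
        plan = make_splits([f"s{i}" for i in range(20)], seed=1)
        assert (len(plan.train_ids), len(plan.val_ids), len(plan.test_ids)) == (14, 3, 3)

    def test_partition_and_fold_invariants(self):
        ids = [f"s{i}" for i in range(40)]
        plan = make_splits(ids, seed=2)
        train, val, test = set(plan.train_ids), set(plan.val_ids), set(plan.test_ids)
        assert train | val | test == set(ids)
        assert not (train & val) and not (train & test) and not (val & test)
        fold_vals = [set(v) for _, v in plan.folds]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (fold_vals[i] & fold_vals[j])
            t, v = set(plan.folds[i][0]), fold_vals[i]
            assert t | v == train | val
            assert not (t & v)

    def test_deterministic_under_seed(self):
        ids = [f"s{i}" for i in range(50)]
        assert make_splits(ids, seed=9) == make_splits(ids, seed=9)
        assert make_splits(ids, seed=9) != make_splits(ids, seed=10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            make_splits(["a", "b", "c"], seed=0)


class TestChannelSpecs:
    def test_parse_ranges_and_lists(self):
        spec = parse_channel_spec("moments:1-2 eigen:1,3")
        assert spec[0] == (("moment", 1), ("moment", 2), ("eigen", 1), ("eigen", 3))
        assert spec[0] == spec[1] == spec[2]

    def test_parse_eigen_1_to_16_accepted(self):
        spec = parse_channel_spec("eigen:1-16")
        assert len(spec[0]) == 16

    def test_bad_clause_rejected(self):
        with pytest.raises(ValueError):
            parse_channel_spec("medians:1-2")

    def test_project_volume_stack_layout(self, rng):
        vol = random_volume(rng, (10, 9, 12))
        stacks = project_volume(vol, uniform_channel_spec("moment", [1, 2]))
        assert len(stacks) == 3
        assert stacks[0].shape == (2, 9, 12)
        assert stacks[2].shape == (2, 10, 9)
        np.testing.assert_array_equal(stacks[1][0], moment_map(vol, 1, 1).image)

    def test_unknown_moment_order_rejected(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        with pytest.raises(ValueError):
            project_volume(vol, uniform_channel_spec("moment", [5]))


class TestProjectionCache:
    def _subject_and_volume(self, rng, tmp_path):
        from projage.volume_io import save_volume

        vol = random_volume(rng, (10, 10, 10))
        path = tmp_path / "s1.nii.gz"
        save_volume(vol, path)
        return SubjectRecord("s1", 60, path), vol

    def test_warm_cache_skips_recomputation(self, tmp_path, rng):
        rec, _ = self._subject_and_volume(rng, tmp_path)
        cache = ProjectionCache(tmp_path / "cache", {"v": 1})
        spec = uniform_channel_spec("moment", [1, 2])
        first = project_subject(rec, spec, cache)
        assert cache.compute_count == 1
        second = project_subject(rec, spec, cache)
        assert cache.compute_count == 1  # warm hit
        for a, b in zip(first, second):
            np.testing.assert_array_equal(a, b)

    def test_parameter_hash_change_invalidates(self, tmp_path, rng):
        rec, _ = self._subject_and_volume(rng, tmp_path)
        spec = uniform_channel_spec("moment", [1])
        cache1 = ProjectionCache(tmp_path / "cache", {"sign_convention": "a"})
        project_subject(rec, spec, cache1)
        cache2 = ProjectionCache(tmp_path / "cache", {"sign_convention": "b"})
        project_subject(rec, spec, cache2)
        assert cache2.compute_count == 1  # stale entry regenerated

    def test_additional_channels_extend_entry(self, tmp_path, rng):
        rec, _ = self._subject_and_volume(rng, tmp_path)
        cache = ProjectionCache(tmp_path / "cache", {"v": 1})
        project_subject(rec, uniform_channel_spec("moment", [1]), cache)
        stacks = project_subject(rec, uniform_channel_spec("moment", [1, 2]), cache)
        assert cache.compute_count == 2
        assert stacks[0].shape[0] == 2

    def test_missing_volume_raises_input_error(self, tmp_path):
        rec = SubjectRecord("ghost", 50, tmp_path / "nope.nii.gz")
        with pytest.raises(Exception, match="no such file"):
            project_subject(rec, uniform_channel_spec("moment", [1]))


class TestEvaluate:
    def test_basic_mae_rmse(self):
        report = evaluate([(3.0, 4.0), (5.0, 4.0)])
        assert report.mae == pytest.approx(1.0)
        assert report.rmse == pytest.approx(1.0)
        assert report.n == 2

    def test_perfect_predictions(self):
        report = evaluate([(60.0, 60.0), (45.0, 45.0)])
        assert report.mae == 0.0 and report.rmse == 0.0

    def test_rmse_at_least_mae(self, rng):
        pairs = list(zip(rng.normal(60, 5, 30), rng.integers(45, 80, 30).astype(float)))
        report = evaluate(pairs)
        assert report.rmse >= report.mae >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate([])

    def test_constant_predictor_baseline(self):
        assert constant_predictor_mae(np.array([50.0, 70.0]), np.array([60.0, 65.0])) == pytest.approx(2.5)


def _tiny_training_setup(seed=0):
    cfg = PhantomConfig(grid=(24, 24, 20), seed=seed)
    subjects = generate_cohort(30, cfg)
    records = [SubjectRecord(s.subject_id, s.recorded_age, "mem") for s in subjects]
    ds = ChannelDataset(records, volumes={s.subject_id: s.volume for s in subjects})
    plan = make_splits([s.subject_id for s in subjects], seed=seed)
    spec = uniform_channel_spec("moment", [1, 2])
    model_cfg = ModelConfig.reduced(
        (("m1", "m2"),) * 3, ds.input_shapes(spec), n_units=2, cap_features=4,
        head_widths=(8,), seed=seed,
    )
    return ds, plan, spec, model_cfg


class TestTrainModel:
    def test_history_and_early_stopping_contract(self):
        ds, plan, spec, model_cfg = _tiny_training_setup()
        trained = train_model(
            build_model(model_cfg),
            ds.stacks(plan.train_ids, spec),
            ds.stacks(plan.val_ids, spec),
            epochs=5,
            seed=0,
        )
        assert len(trained.history) == 5
        maes = [h["val_mae"] for h in trained.history]
        assert trained.best_epoch == int(np.argmin(maes))

    def test_training_is_deterministic(self):
        ds, plan, spec, model_cfg = _tiny_training_setup()
        histories = []
        for _ in range(2):
            trained = train_model(
                build_model(model_cfg),
                ds.stacks(plan.train_ids, spec),
                ds.stacks(plan.val_ids, spec),
                epochs=3,
                seed=4,
            )
            histories.append(trained.history)
        assert histories[0] == histories[1]

    def test_loss_decreases_on_smoke_run(self):
        ds, plan, spec, model_cfg = _tiny_training_setup(seed=1)
        trained = train_model(
            build_model(model_cfg),
            ds.stacks(plan.train_ids, spec),
            ds.stacks(plan.val_ids, spec),
            epochs=15,
            seed=1,
        )
        assert trained.history[-1]["train_loss"] < trained.history[0]["train_loss"]

    def test_empty_fold_rejected(self):
        ds, plan, spec, model_cfg = _tiny_training_setup()
        xs, y = ds.stacks(plan.train_ids, spec)
        with pytest.raises(ValueError):
            train_model(build_model(model_cfg), (xs, y), ([x[:0] for x in xs], y[:0]), epochs=1)
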