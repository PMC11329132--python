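"""Training mechanics, estimator contract, cross-validation bookkeeping."""

import numpy as np
import pytest

import ctthinslice as ct
from ctthinslice.pairing import POSITIONS, PositionLabel


class TestTrainPositionModel:
    def test_zero_residual_smoke_training(self, constant_case, tiny_train_config):
        """Method 2 on a constant case drives the residual toward zero."""
        import dataclasses

        examples = ct.make_training_examples(constant_case, "C", method=2)
        cfg = dataclasses.replace(tiny_train_config, epochs=50)
        gen, history = ct.train_position_model(examples, cfg)
        out = gen(np.asarray(examples[0].input, np.float32)[None, None])
        assert float(np.abs(out).mean()) < 0.05
        assert len(history) == 50

    def test_history_length_equals_epochs(self, small_case, tiny_train_config):
        examples = ct.make_training_examples(small_case, "C", method=1)
        _, history = ct.train_position_model(examples, tiny_train_config)
        assert len(history) == tiny_train_config.epochs
        assert all({"g_loss", "d_loss"} <= set(h) for h in history)

    def test_empty_examples_rejected(self, tiny_train_config):
        with pytest.raises(ValueError):
            ct.train_position_model([], tiny_train_config)

    def test_mixed_positions_rejected(self, small_case, tiny_train_config):
        mixed = (ct.make_training_examples(small_case, "C", 1)
                 + ct.make_training_examples(small_case, "1N", 1))
        with pytest.raises(ValueError, match="share"):
            ct.train_position_model(mixed, tiny_train_config)


class TestEstimator:
    def test_sklearn_param_contract(self):
        est = ct.CGANSliceEnhancer(method=1, epochs=3)
        params = est.get_params()
        assert params["method"] == 1 and params["epochs"] == 3
        est.set_params(method=2)
        assert est.method == 2

    def test_fit_sets_fitted_attributes(self, tiny_cases, tiny_train_config):
        est = ct.CGANSliceEnhancer(
            method=2, epochs=1, gen_depth=tiny_train_config.gen_depth,
            gen_width=tiny_train_config.gen_width,
            disc_blocks=tiny_train_config.disc_blocks,
            disc_width=tiny_train_config.disc_width, random_state=1)
        est.fit(tiny_cases[:2])
        assert set(est.bundle_.generators) == set(POSITIONS)
        assert est.bundle_.method == 2
        assert sorted(est.history_) == sorted(p.value for p in POSITIONS)
        assert est.case_ids_ == [c.case_id for c in tiny_cases[:2]]

    def test_transform_before_fit_rejected(self, tiny_cases):
        with pytest.raises(RuntimeError):
            ct.CGANSliceEnhancer().transform(tiny_cases[0].thick)

    def test_transform_returns_enhanced_volume(self, tiny_cases, tiny_train_config):
        est = ct.CGANSliceEnhancer(
            method=1, epochs=1, gen_depth=4, gen_width=4,
            disc_blocks=2, disc_width=4, random_state=2)
        est.fit(tiny_cases[:2])
        env = est.transform(tiny_cases[0].thick)
        assert isinstance(env, ct.EnhancedVolume)
        assert env.method == 1

    def test_example_counts_in_provenance(self, medium_case):
        """30 thin slices -> 10 rows; 2P and 2N lose one boundary row."""
        est = ct.CGANSliceEnhancer(method=1, epochs=1, gen_depth=4, gen_width=4,
                                   disc_blocks=2, disc_width=4, random_state=0)
        est.fit([medium_case])
        n = est.bundle_.provenance["n_examples"]
        assert n == {"2P": 9, "1P": 10, "C": 10, "1N": 10, "2N": 9}

    def test_same_seed_identical_bundles(self, tiny_cases):
        kwargs = dict(method=2, epochs=1, gen_depth=4, gen_width=4,
                      disc_blocks=2, disc_width=4, random_state=5)
        a = ct.CGANSliceEnhancer(**kwargs).fit(tiny_cases[:2]).bundle_
        b = ct.CGANSliceEnhancer(**kwargs).fit(tiny_cases[:2]).bundle_
        assert a.checksum() == b.checksum()


class TestBundleSerialization:
    def test_save_load_round_trip(self, tiny_cases, tmp_path):
        est = ct.CGANSliceEnhancer(method=2, epochs=1, gen_depth=4, gen_width=4,
                                   disc_blocks=2, disc_width=4, random_state=6)
        bundle = est.fit(tiny_cases[:2]).bundle_
        bundle.save(tmp_path / "bundle")
        back = ct.ModelBundle.load(tmp_path / "bundle")
        assert back.checksum() == bundle.checksum()
        assert back.method == 2
        assert back.training_case_ids == bundle.training_case_ids

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ct.ModelBundle(method=1,
                           generators={PositionLabel.C: ct.IdentityGenerator()})


class TestEvaluationRegimes:
    def test_reproduce_training_eval_report_shape(self, tiny_cases):
        bundle = ct.stub_bundle(ct.ConstantGenerator(0.0), method=2)
        report = ct.reproduce_training_eval(bundle, tiny_cases,
                                            require_training_cases=False)
        means = report.grand_means(2)
        assert {"pooled", "mean_of_case_means"} <= set(means)
        assert len(report.per_case[2]) == len(tiny_cases)

    def test_scores_agree_with_direct_metric_calls(self, tiny_cases):
        bundle = ct.stub_bundle(ct.ConstantGenerator(0.0), method=2)
        case = tiny_cases[0]
        result = ct.evaluate_case(bundle, case)
        env = ct.enhance_volume(bundle, case.thick)
        lo = env.index_offset
        for i, triple in enumerate(result.triples):
            assert triple.mse == ct.mse(env.volume.voxels[i], case.thin.voxels[lo + i])
            assert triple.ssim == ct.ssim(env.volume.voxels[i], case.thin.voxels[lo + i])

    def test_unknown_case_rejected_for_reproduction(self, tiny_cases):
        est = ct.CGANSliceEnhancer(method=1, epochs=1, gen_depth=4, gen_width=4,
                                   disc_blocks=2, disc_width=4, random_state=7)
        bundle = est.fit(tiny_cases[:2]).bundle_
        with pytest.raises(ValueError, match="not in the bundle"):
            ct.reproduce_training_eval(bundle, [tiny_cases[2]])


@pytest.fixture(scope="module")
def folds(tiny_cases, tiny_train_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_train_config, epochs=1)
    return ct.cross_validate(tiny_cases, cfg, method=2)


class TestCrossValidate:

    def test_all_folds_partition(self, folds, tiny_cases):
        assert len(folds) == len(tiny_cases)
        assert [f.test_case_id for f in folds] == [c.case_id for c in tiny_cases]

    def test_no_leakage(self, folds):
        for f in folds:
            assert f.test_case_id not in f.train_case_ids

    def test_fold_subset(self, tiny_cases, tiny_train_config):
        import dataclasses

        cfg = dataclasses.replace(tiny_train_config, epochs=1)
        subset = ct.cross_validate(tiny_cases, cfg, method=1, folds=[0, 2])
        assert [f.fold_index for f in subset] == [0, 2]

    def test_too_few_cases_rejected(self, tiny_cases, tiny_train_config):
        with pytest.raises(ValueError):
            ct.cross_validate(tiny_cases[:1], tiny_train_config, method=1)


def test_derive_seed_stable_and_bounded():
    a = ct.derive_seed(3, "train", 1)
    assert a == ct.derive_seed(3, "train", 1)
    assert a != ct.derive_seed(3, "train", 2)
    assert 0 <= a < 2 ** 31
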