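"""Dataset assembly, normalization, splits, metrics, and net training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neckforce.anthropometry import AnthroProfile, sample_population, DEFAULT_POPULATION
from neckforce.model import MotionTrajectory, build_default_model
from neckforce.motion import MotionSpec, generate_motion
from neckforce.surrogate import (
    FEATURE_NAMES,
    MuscleForceSurrogate,
    MuscleNet,
    ZScoreNormalizer,
    build_dataset,
    evaluate,
    nrmse,
    r2,
    split_dataset,
)


class TestZScore:
    def test_hand_computed_standardization(self):
        # population-SD convention: [1,2,3] -> +/- sqrt(3/2)
        z = ZScoreNormalizer().fit(np.array([[1.0], [2.0], [3.0]]))
        out = z.transform(np.array([[1.0], [2.0], [3.0]])).ravel()
        assert np.allclose(out, [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_guard(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.warns(UserWarning):
            z = ZScoreNormalizer().fit(X)
        out = z.transform(X)
        assert np.allclose(out[:, 0], 0.0)
        assert np.isfinite(out).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30))
    def test_roundtrip_inverts(self, values):
        X = np.asarray(values)[:, None]
        z = ZScoreNormalizer()
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = z.inverse_transform(z.fit_transform(X))
        assert np.allclose(back, X, atol=1e-9 * max(1, np.abs(X).max()))

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3.0, 2.5, size=(500, 4))
        out = ZScoreNormalizer().fit_transform(X)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.std(axis=0), 1.0, atol=1e-9)


class TestSplit:
    def test_two_stage_split_sizes(self):
        s = split_dataset(100, seed=0)
        assert (len(s.train), len(s.val), len(s.test)) == (64, 16, 20)

    def test_partition_is_disjoint_and_exhaustive(self):
        s = split_dataset(173, seed=5)
        all_idx = np.concatenate([s.train, s.val, s.test])
        assert len(np.unique(all_idx)) == 173

    def test_deterministic(self):
        a, b = split_dataset(200, seed=9), split_dataset(200, seed=9)
        assert np.array_equal(a.train, b.train) and np.array_equal(a.test, b.test)

    def test_grouped_split_keeps_groups_intact(self):
        groups = np.repeat(np.arange(10), 20)
        s = split_dataset(200, seed=1, groups=groups)
        for part in (s.train, s.val, s.test):
            part_groups = set(groups[part])
            for other in (s.train, s.val, s.test):
                if other is not part:
                    assert part_groups.isdisjoint(set(groups[other]))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(3, seed=0)


class TestMetrics:
    def test_r2_contracts(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert r2(ref, ref) == pytest.approx(1.0)
        assert r2(np.full(3, ref.mean()), ref) == pytest.approx(0.0)
        assert r2(np.array([1.0, 2.0, 4.0]), ref) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            r2(ref, np.ones(3))

    def test_nrmse_contracts(self):
        assert nrmse(np.array([0.0, 2.0]), np.array([0.0, 2.0])) == 0.0
        assert nrmse(np.array([1.0, 1.0]), np.array([0.0, 2.0])) == pytest.approx(0.5)
        ref = np.array([0.5, 1.5, 2.5, 0.1])
        pred = np.array([0.4, 1.7, 2.2, 0.3])
        assert nrmse(3 * pred, 3 * ref) == pytest.approx(nrmse(pred, ref))
        with pytest.raises(ValueError):
            nrmse(np.ones(3), np.ones(3))

    def test_r2_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            ref = rng.normal(size=30)
            pred = rng.normal(size=30)
            assert r2(pred, ref) <= 1.0
            assert nrmse(pred, ref) >= 0.0


@pytest.fixture(scope="module")
def tiny_dataset(reduced_model_module):
    profiles = sample_population(DEFAULT_POPULATION, 2, seed=0)
    motion = generate_motion(MotionSpec(duration=2.0, cycles=1))
    return build_dataset(profiles, motion, reduced_model_module)


@pytest.fixture(scope="module")
def reduced_model_module():
    from neckforce.muscles import REDUCED_MUSCLE_SET
    return build_default_model(muscle_names=REDUCED_MUSCLE_SET)


class TestBuildDataset:
    def test_row_accounting_and_constant_anthro(self, reduced_model_module):
        profiles = [AnthroProfile(6.377, 39.92, 10.73)]
        motion = generate_motion(MotionSpec(duration=5.0))
        feats, labels = build_dataset(profiles, motion, reduced_model_module)
        assert len(feats) == len(labels) == 500
        for col in ("neck_length", "shoulder_width", "head_mass"):
            assert feats[col].nunique() == 1
        assert list(feats.columns[1:13]) == FEATURE_NAMES

    def test_duplicated_profile_duplicates_rows(self, reduced_model_module):
        p = AnthroProfile(6.377, 39.92, 10.73)
        motion = generate_motion(MotionSpec(duration=1.0))
        feats, labels = build_dataset([p, p], motion, reduced_model_module)
        half = len(feats) // 2
        assert np.allclose(labels.iloc[:half].to_numpy(),
                           labels.iloc[half:].to_numpy())

    def test_empty_profiles_rejected(self, reduced_model_module):
        with pytest.raises(ValueError):
            build_dataset([], generate_motion(MotionSpec(duration=1.0)),
                          reduced_model_module)


class TestTraining:
    def test_linear_generative_model_recovered(self):
        # labels are a fixed linear map of features plus small noise:
        # a 12-64-32-1 net must explain essentially all test variance
        rng = np.random.default_rng(3)
        X = rng.normal(size=(1500, 12))
        w = 0.5 * rng.normal(size=12)
        y = X @ w + 30.0 + 0.01 * rng.normal(size=1500)   # positive, force-like
        assert y.min() > 0
        s = split_dataset(1500, seed=3)
        sur = MuscleForceSurrogate(seed=3, max_epochs=100, patience=15)
        sur.fit(X[s.train], y[s.train], muscle_names=["lin"],
                validation=(X[s.val], y[s.val]))
        metrics = evaluate(sur, X[s.test], y[s.test])
        assert metrics["R2"].iloc[0] > 0.99

    def test_tiny_dataset_memorization_capacity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 12))
        y = np.abs(rng.normal(size=10)) * 50
        sur = MuscleForceSurrogate(seed=1, max_epochs=2000)
        sur.fit(X, y, muscle_names=["memo"])      # no validation: no early stop
        pred = sur.predict(X)[:, 0]
        assert r2(pred, y) > 0.95

    def test_same_seed_reproduces_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 12))
        y = X[:, 0] * 3 + 1
        nets = []
        for _ in range(2):
            sur = MuscleForceSurrogate(seed=7, max_epochs=10)
            sur.fit(X, y, muscle_names=["m"])
            nets.append(sur.nets_[0])
        for W1, W2 in zip(nets[0].coefs, nets[1].coefs):
            assert np.array_equal(W1, W2)

    def test_predict_clips_negative_outputs(self):
        net = MuscleNet("neg", [np.zeros((12, 1))], [np.array([-5.0])],
                        label_mean=0.0, label_scale=1.0, seed=0)
        sur = MuscleForceSurrogate()
        sur.normalizer_ = ZScoreNormalizer()
        sur.normalizer_.mean_ = np.zeros(12)
        sur.normalizer_.scale_ = np.ones(12)
        sur.nets_ = [net]
        sur.muscle_names_ = ["neg"]
        assert np.all(sur.predict(np.ones((4, 12))) == 0.0)

    def test_muscle_order_independence_and_missing_net(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 12))
        Y = np.column_stack([X[:, 0] * 2 + 5, X[:, 1] * 3 + 7])
        sur = MuscleForceSurrogate(seed=5, max_epochs=15)
        sur.fit(X, Y, muscle_names=["a", "b"])
        p_ab = sur.predict(X, muscles=["a", "b"])
        p_ba = sur.predict(X, muscles=["b", "a"])
        assert np.allclose(p_ab[:, 0], p_ba[:, 1])
        with pytest.raises(KeyError):
            sur.predict(X, muscles=["c"])

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(150, 12))
        y = np.abs(X[:, 2]) * 40
        sur = MuscleForceSurrogate(seed=6, max_epochs=10)
        sur.fit(X, y, muscle_names=["m"])
        path = tmp_path / "ensemble.npz"
        sur.save(path)
        back = MuscleForceSurrogate.load(path)
        assert np.allclose(back.predict(X), sur.predict(X))

    def test_nonfinite_labels_rejected(self):
        X = np.zeros((10, 12))
        y = np.full(10, np.nan)
        with pytest.raises(ValueError):
            MuscleForceSurrogate().fit(X, y)
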