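import numpy as np
import pytest

import mirnacle as m
from mirnacle import cascade as casc
from mirnacle.cascade import NEGATIVE, POSITIVE, LabeledExample, StageTrainingSet
from mirnacle.errors import (
    CVConfigurationError,
    InconsistentInputError,
    InsufficientMinorityError,
    InvalidInputError,
    TrainingDataError,
)
from mirnacle.features import STAGE1_NAMES, FeatureVector


def stage1_vector(rng=None, values=None):
    if values is None:
        values = rng.normal(size=len(STAGE1_NAMES))
    return FeatureVector(stage=1, values=tuple(float(v) for v in values))


def gaussian_training_set(
    n_pos, n_neg, seed=0, separation=6.0
) -> StageTrainingSet:
    """Two Gaussian blobs in stage-1 feature space."""
    rng = np.random.default_rng(seed)
    ts = StageTrainingSet(stage=1)
    for k in range(n_pos):
        vals = rng.normal(loc=separation, size=len(STAGE1_NAMES))
        ts.add(LabeledExample(stage1_vector(values=vals), POSITIVE, f"p{k}"))
    for k in range(n_neg):
        vals = rng.normal(loc=0.0, size=len(STAGE1_NAMES))
        ts.add(LabeledExample(stage1_vector(values=vals), NEGATIVE, f"n{k}"))
    return ts


class TestSmoteOversample:
    def test_target_equals_minority_yields_nothing(self):
        rng = np.random.default_rng(0)
        minority = [stage1_vector(rng) for _ in range(5)]
        assert m.smote_oversample(minority, k=3, target=5, seed=1) == []

    def test_two_identical_points(self):
        fv = stage1_vector(values=[1.0] * len(STAGE1_NAMES))
        synth = m.smote_oversample([fv, fv], k=5, target=10, seed=2)
        assert len(synth) == 8
        for s in synth:
            assert s.values == fv.values

    def test_convexity_over_1000_draws(self):
        rng = np.random.default_rng(3)
        minority = [stage1_vector(rng) for _ in range(10)]
        X = np.array([fv.as_array() for fv in minority])
        synth = m.smote_oversample(minority, k=5, target=10 + 1000, seed=4)
        assert len(synth) == 1000
        lo, hi = X.min(axis=0), X.max(axis=0)
        for s in synth:
            v = s.as_array()
            assert np.all(v >= lo - 1e-9) and np.all(v <= hi + 1e-9)
            # each synthetic lies on a segment between two minority points
            collinear = False
            for i in range(len(X)):
                d = v - X[i]
                for j in range(len(X)):
                    if i == j:
                        continue
                    e = X[j] - X[i]
                    u = np.dot(d, e) / np.dot(e, e)
                    if 0 <= u <= 1 and np.allclose(v, X[i] + u * e, atol=1e-8):
                        collinear = True
                        break
                if collinear:
                    break
            assert collinear

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        minority = [stage1_vector(rng) for _ in range(6)]
        a = m.smote_oversample(minority, k=3, target=20, seed=9)
        b = m.smote_oversample(minority, k=3, target=20, seed=9)
        assert a == b

    def test_too_few_minority(self):
        with pytest.raises(InsufficientMinorityError):
            m.smote_oversample([stage1_vector(np.random.default_rng(0))], 5, 10, 0)

    def test_bad_target(self):
        rng = np.random.default_rng(0)
        minority = [stage1_vector(rng) for _ in range(4)]
        with pytest.raises(InvalidInputError):
            m.smote_oversample(minority, k=3, target=3, seed=0)


class TestTrainStageModel:
    def test_separable_set_resubstitution(self):
        ts = gaussian_training_set(30, 30, seed=1)
        model = m.train_stage_model(ts, seed=1, n_trees=50)
        X, y = ts.arrays()
        p = model.predict_proba(X)
        assert np.all((p >= 0.5) == (y == 1))

    def test_smote_balances_to_parity(self, monkeypatch):
        recorded = {}
        original_fit = casc.RandomForestClassifier.fit

        def spy_fit(self, X, y, **kw):
            recorded["counts"] = np.bincount(y)
            return original_fit(self, X, y, **kw)

        monkeypatch.setattr(casc.RandomForestClassifier, "fit", spy_fit)
        ts = gaussian_training_set(20, 200, seed=2)
        m.train_stage_model(ts, seed=2, n_trees=10)
        assert list(recorded["counts"]) == [200, 200]

    def test_same_seed_same_predictions(self):
        ts = gaussian_training_set(15, 40, seed=3)
        probe = np.random.default_rng(4).normal(size=(20, len(STAGE1_NAMES)))
        a = m.train_stage_model(ts, seed=7, n_trees=30).predict_proba(probe)
        b = m.train_stage_model(ts, seed=7, n_trees=30).predict_proba(probe)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        ts = gaussian_training_set(10, 0, seed=1) if False else StageTrainingSet(stage=1)
        rng = np.random.default_rng(0)
        for k in range(5):
            ts.add(LabeledExample(stage1_vector(rng), POSITIVE, f"p{k}"))
        with pytest.raises(TrainingDataError):
            m.train_stage_model(ts)


@pytest.fixture(scope="module")
def model():
    return m.train_stage_model(gaussian_training_set(25, 25, seed=5), seed=5, n_trees=30)


class TestClassifyStage:

    def test_threshold_zero_always_passes(self, model):
        fv = stage1_vector(np.random.default_rng(6))
        p, ok = m.classify_stage(model, fv, 0.0)
        assert ok and 0.0 <= p <= 1.0

    def test_threshold_one_requires_certainty(self, model):
        fv = stage1_vector(np.random.default_rng(7))
        p, ok = m.classify_stage(model, fv, 1.0)
        assert ok == (p == 1.0)

    def test_inclusive_rule(self, model, monkeypatch):
        monkeypatch.setattr(
            type(model), "predict_proba", lambda self, X: np.array([0.7])
        )
        _, ok = m.classify_stage(model, stage1_vector(np.random.default_rng(8)), 0.7)
        assert ok

    def test_stage_mismatch(self, model):
        fv2 = FeatureVector(stage=2, values=tuple(np.zeros(35)))
        with pytest.raises(InconsistentInputError):
            m.classify_stage(model, fv2, 0.5)


class TestBuildStageTrainingSets:
    def test_degenerate_negative_raises(self):
        pos = [m.generate_hairpin(m.HairpinSpec(stem=20, loop=6, seed=1))]
        neg = [m.RNASequence.from_string("A" * 80, "homopolymer")]
        with pytest.raises(TrainingDataError):
            m.build_stage_training_sets(pos, neg)

    def test_counting_contract_and_labels(self):
        pos, neg = m.training_sequences(10, 10, seed=42)
        sets = m.build_stage_training_sets(pos, neg)
        pos_ids = {s.id for s in pos}
        for ts in sets:
            counts = ts.class_counts
            assert counts[POSITIVE] <= 10 and counts[NEGATIVE] <= 10
            for ex in ts.examples:
                expected = POSITIVE if ex.source_id in pos_ids else NEGATIVE
                assert ex.label == expected

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            m.build_stage_training_sets([], [])


class TestCrossValidate:
    def test_separable_set_perfect_metrics(self):
        ts = gaussian_training_set(30, 30, seed=9)
        sn, sl, gm = m.cross_validate(ts, folds=5, seed=9, n_trees=30)
        assert (sn, sl, gm) == (100.0, 100.0, 100.0)

    def test_default_folds_is_10(self):
        import inspect

        assert inspect.signature(m.cross_validate).parameters["folds"].default == 10

    def test_permuted_labels_near_chance(self):
        gms = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ts = StageTrainingSet(stage=1)
            for k in range(40):
                label = POSITIVE if rng.uniform() < 0.5 else NEGATIVE
                if k < 2:  # guarantee both classes present
                    label = POSITIVE if k == 0 else NEGATIVE
                ts.add(LabeledExample(stage1_vector(rng), label, f"x{k}"))
            counts = ts.class_counts
            if min(counts.values()) < 4:
                continue
            gms.append(m.cross_validate(ts, folds=4, seed=seed, n_trees=30)[2])
        assert abs(float(np.mean(gms)) - 50.0) <= 10.0

    def test_class_too_small(self):
        ts = gaussian_training_set(3, 30, seed=1)
        with pytest.raises(CVConfigurationError):
            m.cross_validate(ts, folds=10)

    def test_no_synthetic_points_leak_into_test_folds(self, monkeypatch):
        ts = gaussian_training_set(8, 40, seed=13)
        X, _ = ts.arrays()
        original_rows = {tuple(np.round(row, 9)) for row in X}
        tested_rows = []
        smote_calls = []

        original_predict = casc.StageModel.predict_proba
        original_smote = casc._smote_arrays

        def spy_predict(self, Xq):
            arr = np.atleast_2d(np.asarray(Xq, dtype=float))
            tested_rows.extend(map(tuple, np.round(arr, 9)))
            return original_predict(self, Xq)

        def spy_smote(X_min, k, n_synth, rng, lo, span):
            out = original_smote(X_min, k, n_synth, rng, lo, span)
            smote_calls.append(len(out))
            return out

        monkeypatch.setattr(casc.StageModel, "predict_proba", spy_predict)
        monkeypatch.setattr(casc, "_smote_arrays", spy_smote)
        m.cross_validate(ts, folds=4, seed=13, n_trees=10)

        # SMOTE ran for every training fold ...
        assert len(smote_calls) == 4 and all(n > 0 for n in smote_calls)
        # ... and every evaluated row is an original example, no synthetics
        assert len(tested_rows) == len(ts.examples)
        assert set(tested_rows) <= original_rows


class TestCascadeModelPersistence:
    def test_save_load_round_trip(self, small_cascade, tmp_path):
        small_cascade.save(tmp_path / "model")
        loaded = m.CascadeModel.load(tmp_path / "model")
        assert loaded.thresholds == small_cascade.thresholds
        probe = np.random.default_rng(1).uniform(size=(5, len(STAGE1_NAMES)))
        assert np.array_equal(
            loaded.models[1].predict_proba(probe),
            small_cascade.models[1].predict_proba(probe),
        )

    def test_metadata_is_plain_text(self, small_cascade, tmp_path):
        import json

        small_cascade.save(tmp_path / "model")
        meta = json.loads((tmp_path / "model" / "metadata.json").read_text())
        assert meta["thresholds"] == list(small_cascade.thresholds)
        assert set(meta["stages"]) == {"1", "2", "3"}


class TestArffRoundTrip:
    def test_training_set_round_trip(self, tmp_path):
        ts = gaussian_training_set(5, 7, seed=21)
        path = tmp_path / "stage1.arff"
        ts.to_arff(path)
        back = StageTrainingSet.from_arff(path)
        assert back.stage == 1
        assert back.class_counts == ts.class_counts
        a = np.array([ex.vector.values for ex in ts.examples])
        b = np.array([ex.vector.values for ex in back.examples])
        assert np.allclose(a, b, atol=1e-4)
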