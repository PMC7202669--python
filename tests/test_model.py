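"""CNN architecture, training protocol, CV splits, and ensembling."""

import numpy as np
import pytest

from sscnn.model import (
    EnsembleModel,
    ModelSpec,
    SampleSet,
    TrainConfig,
    TrainedModel,
    build_cnn,
    ensemble_predict,
    load_model,
    make_cv_splits,
    parameter_count,
    save_model,
    train,
)


def independent_param_count(n_labels, filters=(128, 256, 384, 512),
                            k=7, n_features=92, window=29):
    """Arithmetic oracle: per-layer counts summed with plain Python."""
    total, in_ch, length = 0, n_features, window
    for f in filters:
        total += (in_ch * k + 1) * f
        length = length - k + 1
        in_ch = f
    total += (length * in_ch + 1) * n_labels
    return total


class TestArchitecture:
    @pytest.mark.parametrize("n_labels", [3, 4, 5, 8])
    def test_parameter_count_matches_oracle(self, n_labels):
        spec = ModelSpec(n_labels=n_labels)
        assert parameter_count(spec) == independent_param_count(n_labels)
        assert build_cnn(spec, seed=0).n_params == parameter_count(spec)

    def test_conv_stack_output_length(self):
        assert ModelSpec(n_labels=8).conv_output_length == 29 - 4 * 6 == 5

    def test_invalid_n_labels(self):
        with pytest.raises(ValueError):
            ModelSpec(n_labels=1)

    def test_window_too_small_for_stack(self):
        with pytest.raises(ValueError, match="too small"):
            ModelSpec(n_labels=3, window_width=9)

    def test_softmax_rows_sum_to_one(self):
        spec = ModelSpec(n_labels=5, filters=(8, 8, 8, 8))
        net = build_cnn(spec, seed=3)
        x = np.random.default_rng(0).normal(size=(7, 29, 92)).astype(np.float32)
        probs = net.predict_proba(x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert (probs >= 0).all()


def _toy_samples(n, seed, n_labels=3, separable=True):
    """Windows whose center one-hot determines the label (when separable)."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_labels, size=n)
    X = np.zeros((n, 29, 92), dtype=np.float32)
    X += rng.normal(0, 0.05, size=X.shape).astype(np.float32)
    for i in range(n):
        residue = y[i] if separable else rng.integers(0, n_labels)
        X[i, 14, residue] = 1.0
    return SampleSet(X=X, y=y, letters=tuple("HEC"[:n_labels]))


SMALL = dict(filters=(8, 12, 16, 20))


class TestTraining:
    def test_learns_separable_toy(self):
        train_set = _toy_samples(600, seed=1)
        valid_set = _toy_samples(200, seed=2)
        spec = ModelSpec(n_labels=3, **SMALL)
        net = build_cnn(spec, seed=0)
        config = TrainConfig(n_epochs=15, seed=0)
        model, history = train(net, train_set, valid_set, config, spec=spec)
        assert model.best_valid_accuracy > 0.95

    def test_same_seed_identical_history(self):
        train_set = _toy_samples(300, seed=1)
        valid_set = _toy_samples(100, seed=2)
        spec = ModelSpec(n_labels=3, **SMALL)
        histories = []
        for _ in range(2):
            net = build_cnn(spec, seed=4)
            _, h = train(net, train_set, valid_set,
                         TrainConfig(n_epochs=3, seed=4), spec=spec)
            histories.append(h)
        assert histories[0] == histories[1]

    def test_checkpoint_is_best_validation_epoch(self):
        train_set = _toy_samples(300, seed=1)
        valid_set = _toy_samples(100, seed=2)
        spec = ModelSpec(n_labels=3, **SMALL)
        net = build_cnn(spec, seed=0)
        model, history = train(net, train_set, valid_set,
                               TrainConfig(n_epochs=6, seed=0), spec=spec)
        best = max(h["valid_acc"] for h in history)
        assert model.best_valid_accuracy == best
        # restored weights actually reproduce the checkpointed accuracy
        pred = model.predict_proba(valid_set.X).argmax(axis=1)
        assert float((pred == valid_set.y).mean()) == pytest.approx(best)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(n_epochs=0)

    def test_empty_training_set_rejected(self):
        spec = ModelSpec(n_labels=3, **SMALL)
        empty = SampleSet(X=np.zeros((0, 29, 92), dtype=np.float32),
                          y=np.zeros(0, dtype=np.int64), letters=tuple("HEC"))
        with pytest.raises(ValueError, match="empty"):
            train(build_cnn(spec, seed=0), empty, empty,
                  TrainConfig(n_epochs=1), spec=spec)

    def test_decay_follows_epochs(self):
        assert TrainConfig(n_epochs=650).effective_decay == pytest.approx(
            0.01 / 650)
        assert TrainConfig(n_epochs=10).effective_decay == pytest.approx(1e-3)

    def test_save_load_round_trip(self, tmp_path):
        train_set = _toy_samples(200, seed=1)
        valid_set = _toy_samples(80, seed=2)
        spec = ModelSpec(n_labels=3, **SMALL)
        net = build_cnn(spec, seed=0)
        model, _ = train(net, train_set, valid_set,
                         TrainConfig(n_epochs=2, seed=0), spec=spec)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.letters == model.letters
        assert np.allclose(loaded.predict_proba(valid_set.X),
                           model.predict_proba(valid_set.X))


class TestCVSplits:
    def test_ratio_and_cover(self):
        chains = [f"c{i}" for i in range(100)]
        splits = make_cv_splits(chains, n_splits=10, seed=0)
        assert len(splits) == 10
        covered = set()
        for tr, va in splits:
            assert len(tr) == 90 and len(va) == 10
            assert set(tr) | set(va) == set(chains)
            assert not set(tr) & set(va)
            covered |= set(va)
        assert covered == set(chains)

    def test_same_seed_same_splits(self):
        chains = list(range(57))
        assert (make_cv_splits(chains, seed=9)
                == make_cv_splits(chains, seed=9))

    def test_too_few_chains(self):
        with pytest.raises(ValueError):
            make_cv_splits(list(range(5)), n_splits=10)


class _FixedMember:
    """Stub ensemble member returning predetermined probabilities."""

    def __init__(self, probs, letters):
        self._probs = np.asarray(probs, dtype=float)
        self.letters = tuple(letters)

    def predict_proba(self, X):
        return self._probs


class TestEnsemble:
    def test_unanimous_vote(self):
        member = _FixedMember([[0.9, 0.05, 0.05]], "HEC")
        ens = EnsembleModel(members=[member] * 10, scheme_name="rule1_3")
        labels, probs = ensemble_predict(ens, np.zeros((1, 29, 92)))
        assert labels == "H"
        assert np.allclose(probs[0], [0.9, 0.05, 0.05])

    def test_tie_broken_by_summed_probability(self):
        # five members vote H (index 0), five vote C (index 2); the C votes
        # are more confident so the summed probability favours C
        h_member = _FixedMember([[0.55, 0.05, 0.40]], "HEC")
        c_member = _FixedMember([[0.05, 0.05, 0.90]], "HEC")
        ens = EnsembleModel(members=[h_member] * 5 + [c_member] * 5,
                            scheme_name="rule1_3")
        labels, _ = ensemble_predict(ens, np.zeros((1, 29, 92)))
        assert labels == "C"

    def test_single_member_equals_argmax(self):
        member = _FixedMember([[0.2, 0.5, 0.3], [0.6, 0.2, 0.2]], "HEC")
        ens = EnsembleModel(members=[member], scheme_name="rule1_3")
        labels, _ = ensemble_predict(ens, np.zeros((2, 29, 92)))
        assert labels == "EH"

    def test_mixed_alphabets_rejected(self):
        a = _FixedMember([[1.0, 0.0, 0.0]], "HEC")
        b = _FixedMember([[1.0, 0.0, 0.0]], "HET")
        with pytest.raises(ValueError, match="alphabet"):
            EnsembleModel(members=[a, b], scheme_name="rule1_3")

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel(members=[], scheme_name="rule1_3")
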