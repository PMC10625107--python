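import numpy as np
import pytest

from apscreen.scoring import ScoreSet
from apscreen.seqspace import PeptideSystem, augment_mixed, lhs_sample
from apscreen.surrogate import (
    DEFAULT_PARAMS,
    LabelledDataset,
    label_dataset,
)
from apscreen.trn import (
    FULL_PRESET,
    SCALED_PRESET,
    TINY_PRESET,
    TrainConfig,
    TrnConfig,
    build_model,
    evaluate,
    load_model,
    predict,
    save_model,
    train,
)


class TestBuildModel:
    def test_same_seed_bitwise_identical_parameters(self):
        m1 = build_model(TINY_PRESET, seed=5)
        m2 = build_model(TINY_PRESET, seed=5)
        for a, b in zip(m1.state(), m2.state()):
            np.testing.assert_array_equal(a, b)
        m3 = build_model(TINY_PRESET, seed=6)
        assert any(
            not np.array_equal(a, b) for a, b in zip(m1.state(), m3.state())
        )

    def test_full_preset_parameter_count_matches_bookkeeping(self):
        cfg = FULL_PRESET.with_(model_length=5)
        model = build_model(cfg, seed=0)
        d, ffn, L = 512, 2048, 5
        per_block = (
            4 * (d * d + d)          # Q, K, V, output projections
            + 2 * 2 * d              # two layer norms (gain + bias)
            + (d * ffn + ffn) + (ffn * d + d)  # feed-forward sublayer
        )
        mlp_dims = [512, 256, 64, 32, 1]
        d_in = L * d
        mlp = 0
        for i, d_out in enumerate(mlp_dims):
            mlp += d_in * d_out + d_out
            if i < len(mlp_dims) - 1:
                mlp += 2 * d_out     # batch norm gain + bias
            d_in = d_out
        expected = 22 * d + 6 * per_block + mlp
        assert model.n_parameters() == expected

    def test_scaled_preset_forward_smoke(self):
        model = build_model(SCALED_PRESET, seed=0)
        tokens = np.zeros((3, 5), dtype=np.int64)
        out = model.forward(tokens, train=False)
        assert out.shape == (3,) and np.isfinite(out).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TrnConfig(mlp_dims=(64, 32))
        with pytest.raises(ValueError):
            TrnConfig(pooling="max")
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=1.5)


@pytest.fixture(scope="module")
def model():
    return build_model(TINY_PRESET, seed=1)


class TestPredictDeterminism:

    def test_identical_inputs_identical_outputs(self, model):
        systems = ["NRMMR", "DMGID", "LRLRL"]
        a = predict(model, systems)
        b = predict(model, systems)
        assert a.values == b.values

    def test_batched_and_single_inference_agree(self, model):
        systems = [str(p) for p in lhs_sample(5, 64, seed=2)]
        batched = predict(model, systems, batch_size=64)
        single = {s: predict(model, [s]).values[s] for s in set(systems)}
        for s in set(systems):
            assert batched.values[s] == pytest.approx(single[s], rel=1e-5)


class TestTraining:
    def test_constant_labels_learned_to_near_constant_predictions(self):
        # dropout stays on: with constant targets it keeps hidden-activation
        # variance alive, which batch normalization needs to generalize its
        # train-time statistics to evaluation mode
        peps = lhs_sample(5, 200, seed=0)
        data = LabelledDataset(
            [PeptideSystem.single(p) for p in peps], np.full(200, 1.5)
        )
        res = train(
            TINY_PRESET, data, TrainConfig(epochs=300, n_seeds=1), seed=0
        )
        assert res.averaged["val_mae"] < 0.05
        preds = predict(res.model, [str(p) for p in peps[:20]]).array()
        assert np.ptp(preds) < 0.15

    def test_best_model_selection_is_monotone(self):
        peps = lhs_sample(5, 400, seed=1)
        data = label_dataset(peps, DEFAULT_PARAMS, seed=1)
        res = train(TINY_PRESET, data, TrainConfig(epochs=10, n_seeds=1), seed=0)
        history = res.history[0]
        assert res.per_seed[0]["val_mae"] <= history[-1] + 1e-12
        assert res.per_seed[0]["val_mae"] == pytest.approx(min(history), abs=1e-9)

    def test_equal_seeds_reproduce_training_exactly(self):
        peps = lhs_sample(5, 300, seed=2)
        data = label_dataset(peps, DEFAULT_PARAMS, seed=2)
        tcfg = TrainConfig(epochs=5, n_seeds=1)
        r1 = train(TINY_PRESET, data, tcfg, seed=3)
        r2 = train(TINY_PRESET, data, tcfg, seed=3)
        assert r1.per_seed == r2.per_seed
        for a, b in zip(r1.model.state(), r2.model.state()):
            np.testing.assert_array_equal(a, b)

    def test_multi_seed_averaging(self):
        peps = lhs_sample(5, 300, seed=4)
        data = label_dataset(peps, DEFAULT_PARAMS, seed=4)
        res = train(TINY_PRESET, data, TrainConfig(epochs=3, n_seeds=2), seed=0)
        assert len(res.per_seed) == 2
        assert res.averaged["val_mae"] == pytest.approx(
            np.mean([m["val_mae"] for m in res.per_seed])
        )

    def test_noiseless_additive_labels_learned_well(self):
        """The scaled preset regresses noise-free additive surrogate labels
        to high fidelity from 2000 samples."""
        params = DEFAULT_PARAMS.with_(
            noise_sd=0.0, pair_bonus=0.0, charge_penalty=0.0
        )
        pool = lhs_sample(5, 2500, seed=5)
        data = label_dataset(pool[:2000], params, seed=0)
        test = label_dataset(pool[2000:], params, seed=0)
        res = train(
            SCALED_PRESET, data, TrainConfig(epochs=150, n_seeds=1),
            seed=0, test_data=test,
        )
        assert res.averaged["test_r2"] >= 0.9

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(
                TINY_PRESET,
                LabelledDataset([], np.array([])),
                TrainConfig(epochs=1, n_seeds=1),
            )


class TestMixedSystems:
    def test_swap_augmentation_reduces_positional_asymmetry(self):
        """Swap augmentation trains A+B and B+A toward the same score: the
        mean |pred(A+B) - pred(B+A)| gap of the augmented model is clearly
        below that of the same model trained without augmentation."""
        rng = np.random.default_rng(0)
        from apscreen.seqspace import ALPHABET

        pairs = [
            PeptideSystem.mixed(
                "".join(rng.choice(list(ALPHABET), 5)),
                "".join(rng.choice(list(ALPHABET), 5)),
            )
            for _ in range(600)
        ]
        labels = label_dataset(pairs, DEFAULT_PARAMS, seed=0).labels
        cfg = TINY_PRESET.with_(model_length=11)
        tcfg = TrainConfig(epochs=100, n_seeds=1)
        probes = pairs[:100]

        def swap_gap(model):
            fwd = predict(model, [str(s) for s in probes]).array()
            rev = predict(model, [str(s.swapped()) for s in probes]).array()
            return float(np.abs(fwd - rev).mean())

        aug_systems, aug_labels = augment_mixed(pairs, list(labels))
        res_aug = train(
            cfg, LabelledDataset(aug_systems, np.array(aug_labels)), tcfg, seed=0
        )
        res_raw = train(cfg, LabelledDataset(pairs, labels), tcfg, seed=0)
        assert swap_gap(res_aug.model) < 0.8 * swap_gap(res_raw.model)


class TestEvaluate:
    def test_perfect_prediction(self):
        t = ScoreSet({"a": 1.0, "b": 2.0, "c": 1.5})
        m = evaluate(t, t)
        assert m.mae == 0.0 and m.r2 == 1.0

    def test_constant_predictor_r2_zero(self):
        truth = ScoreSet({"a": 1.0, "b": 2.0, "c": 3.0})
        pred = ScoreSet({k: 2.0 for k in truth.values})
        m = evaluate(pred, truth)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_error_ratio_hand_value(self):
        m = evaluate(
            ScoreSet({"x": 1.05}), ScoreSet({"x": 1.00}), bins=[0.95, 1.05]
        )
        assert m.error_ratio_profile[0]["mean_error_ratio_pct"] == pytest.approx(5.0)
        assert m.mae == pytest.approx(0.05)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import mean_absolute_error, r2_score

        t = rng.normal(1.5, 0.2, 200)
        p = t + rng.normal(0, 0.05, 200)
        keys = [f"s{i}" for i in range(200)]
        m = evaluate(ScoreSet(dict(zip(keys, p))), ScoreSet(dict(zip(keys, t))))
        assert m.mae == pytest.approx(mean_absolute_error(t, p), rel=1e-12)
        assert m.r2 == pytest.approx(r2_score(t, p), rel=1e-12)

    def test_disjoint_keys_rejected(self):
        with pytest.raises(Exception):
            evaluate(ScoreSet({"a": 1.0}), ScoreSet({"b": 1.0}))


def test_checkpoint_roundtrip(tmp_path):
    model = build_model(TINY_PRESET, seed=9)
    systems = ["NRMMR", "LRLRL"]
    before = predict(model, systems)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    after = predict(loaded, systems)
    for k in before.values:
        assert after.values[k] == pytest.approx(before.values[k], rel=1e-6)
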