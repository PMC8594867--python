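import numpy as np
import pytest

from pcmbench.core_data import FINGERPRINT_LENGTH, MAX_SEQUENCE_LENGTH
from pcmbench.modeling import (
    LogisticSurrogate,
    ModelConfig,
    build_model,
    encode_batch,
    predict,
    random_baseline,
    train_select,
)


class TestRandomBaseline:
    @pytest.mark.parametrize(
        "f,n,expected_actives",
        [(0.5, 10, 5), (0.0, 7, 0), (0.26, 10, 3), (1.0, 4, 4), (0.33, 9, 3)],
    )
    def test_exact_active_count_every_draw(self, f, n, expected_actives, rng):
        for _ in range(20):
            scores = random_baseline(f, n, rng)
            assert len(scores) == n
            assert int((scores >= 0.5).sum()) == expected_actives

    def test_score_ranges(self, rng):
        scores = random_baseline(0.4, 1000, rng)
        actives = scores[scores >= 0.5]
        inactives = scores[scores < 0.5]
        assert np.all(actives <= 1.0) and np.all(inactives >= 0.0)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            random_baseline(1.2, 5, rng)
        with pytest.raises(ValueError):
            random_baseline(0.5, -1, rng)

    def test_zero_n_allowed(self, rng):
        assert len(random_baseline(0.7, 0, rng)) == 0


def _toy_config(**kw):
    defaults = dict(
        conv_filters=4, conv_kernel=4, dense_size=8, dropout_rate=0.0,
        learning_rate=5e-3, epochs=3, batch_size=16, seed=0,
    )
    defaults.update(kw)
    return ModelConfig(**defaults)


def _toy_batch(n, rng, separable=False):
    """Random (protein, fingerprint, label) arrays; optionally a linearly
    separable rule where label = bit 0 of the fingerprint."""
    Xp = np.zeros((n, MAX_SEQUENCE_LENGTH, 26), dtype=np.float32)
    for i in range(n):
        L = 30
        idx = rng.integers(0, 26, L)
        Xp[i, -L:, :][np.arange(L), idx] = 1.0
    Xf = (rng.random((n, FINGERPRINT_LENGTH)) < 0.1).astype(np.float32)
    if separable:
        # one shared protein; a redundant block of fingerprint bits carries
        # a clean, linearly separable signal
        Xp[:] = Xp[0]
        y = (rng.random(n) < 0.5).astype(np.float64)
        Xf[:, :10] = y[:, None]
    else:
        y = (rng.random(n) < 0.5).astype(np.float64)
    return Xp, Xf, y


class TestPCMNetwork:
    def test_forward_contracts(self, rng):
        model = build_model(_toy_config())
        Xp, Xf, _ = _toy_batch(5, rng)
        scores = model.predict_scores(Xp, Xf)
        assert scores.shape == (5,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_inference_deterministic_despite_dropout_config(self, rng):
        model = build_model(_toy_config(dropout_rate=0.5))
        Xp, Xf, _ = _toy_batch(4, rng)
        assert np.array_equal(model.predict_scores(Xp, Xf),
                              model.predict_scores(Xp, Xf))

    def test_infeasible_kernel_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_kernel=MAX_SEQUENCE_LENGTH + 1)

    def test_numeric_gradients_match_backprop(self, rng):
        """Finite-difference oracle for the hand-written backward pass."""
        model = build_model(_toy_config(seed=3))
        Xp, Xf, y = _toy_batch(3, rng)

        def loss():
            prob, _ = model.forward(Xp, Xf)
            eps = 1e-12
            return -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))

        prob, cache = model.forward(Xp, Xf)
        grads = model._backward(prob, y, cache)
        h = 1e-6
        for name in ("W2", "b2", "W1", "bc", "Wc"):
            flat = model.params[name].reshape(-1)
            for k in rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + h
                up = loss()
                flat[k] = orig - h
                down = loss()
                flat[k] = orig
                numeric = (up - down) / (2 * h)
                assert grads[name].reshape(-1)[k] == pytest.approx(numeric, abs=1e-5)


class TestTrainSelect:
    def test_separable_data_reaches_perfect_validation(self, rng):
        cfg = _toy_config(epochs=50, learning_rate=2e-2, seed=1)
        model = build_model(cfg)
        Xp, Xf, y = _toy_batch(60, rng, separable=True)
        train = (Xp[:40], Xf[:40], y[:40])
        val = (Xp[40:], Xf[40:], y[40:])
        model, epoch, history = train_select(model, train, val, cfg)
        assert max(h["val_acc"] for h in history) == 1.0
        assert history[epoch]["val_acc"] == 1.0

    def test_single_epoch_selects_epoch_zero(self, rng):
        cfg = _toy_config(epochs=1)
        model = build_model(cfg)
        Xp, Xf, y = _toy_batch(20, rng)
        _, epoch, history = train_select(
            model, (Xp[:15], Xf[:15], y[:15]), (Xp[15:], Xf[15:], y[15:]), cfg
        )
        assert epoch == 0 and len(history) == 1

    def test_selected_epoch_is_argmax_and_earliest(self, rng):
        cfg = _toy_config(epochs=6, seed=2)
        model = build_model(cfg)
        Xp, Xf, y = _toy_batch(30, rng)
        _, epoch, history = train_select(
            model, (Xp[:20], Xf[:20], y[:20]), (Xp[20:], Xf[20:], y[20:]), cfg
        )
        accs = [h["val_acc"] for h in history]
        assert accs[epoch] == max(accs)
        assert epoch == accs.index(max(accs))

    def test_empty_sets_rejected(self, rng):
        cfg = _toy_config()
        model = build_model(cfg)
        Xp, Xf, y = _toy_batch(5, rng)
        with pytest.raises(ValueError):
            train_select(model, (Xp[:0], Xf[:0], y[:0]), (Xp, Xf, y), cfg)


class TestPredict:
    def _tiny_world(self, rng):
        fps = {f"c{i}": (rng.random(FINGERPRINT_LENGTH) < 0.1).astype(np.int8)
               for i in range(4)}
        seqs = {"p0": "ACDEFGHIKL", "p1": "MNPQRSTVWY"}
        return fps, seqs

    def test_empty_input_empty_output(self, rng):
        model = build_model(_toy_config())
        fps, seqs = self._tiny_world(rng)
        assert len(predict(model, [], fps, seqs)) == 0

    def test_same_pair_same_score_and_bounds(self, rng):
        model = build_model(_toy_config())
        fps, seqs = self._tiny_world(rng)
        pairs = [("c0", "p0"), ("c1", "p1"), ("c0", "p0")]
        scores = predict(model, pairs, fps, seqs)
        assert scores[0] == scores[2]
        assert np.all((scores >= 0) & (scores <= 1))

    def test_unknown_ids_rejected(self, rng):
        model = build_model(_toy_config())
        fps, seqs = self._tiny_world(rng)
        with pytest.raises(KeyError):
            predict(model, [("nope", "p0")], fps, seqs)
        with pytest.raises(KeyError):
            predict(model, [("c0", "nope")], fps, seqs)


def test_baseline_auroc_and_mcc_centered(rng):
    """Against labels independent of the scores, the baseline's AUROC
    averages 0.5 and its MCC averages 0 (imbalance-insensitivity)."""
    from pcmbench.evaluation import auroc, binarize_scores, mcc

    aurocs, mccs = [], []
    for _ in range(800):
        f = rng.random()
        labels = (rng.random(40) < 0.5).astype(int)
        scores = random_baseline(f, 40, rng)
        a = auroc(labels, scores)
        m = mcc(labels, binarize_scores(scores))
        if not np.isnan(a):
            aurocs.append(a)
        if not np.isnan(m):
            mccs.append(m)
    for values, center in ((aurocs, 0.5), (mccs, 0.0)):
        se = np.std(values) / np.sqrt(len(values))
        assert abs(np.mean(values) - center) < 3 * se + 1e-3


def test_surrogate_learns_fingerprint_rule(rng):
    from pcmbench.core_data import BioactivityRecord

    fps = {f"c{i}": (rng.random(FINGERPRINT_LENGTH) < 0.1).astype(np.int8)
           for i in range(200)}
    seqs = {"p0": "ACDEFGHIKLMNPQRSTVWY" * 10}
    records = []
    for i, (cid, fp) in enumerate(fps.items()):
        if i < 5:
            fp[0] = i % 2  # ensure both classes
        records.append(
            BioactivityRecord(compound_id=cid, protein_id="p0", label=int(fp[0]))
        )
    surrogate = LogisticSurrogate(seed=0).fit(records[:150], fps, seqs)
    pairs = [(r.compound_id, "p0") for r in records[150:]]
    scores = predict(surrogate, pairs, fps, seqs)
    labels = np.array([r.label for r in records[150:]])
    acc = np.mean((scores >= 0.5) == labels)
    assert acc > 0.9
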