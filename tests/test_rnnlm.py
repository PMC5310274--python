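import itertools
import math

import numpy as np
import pytest

from rnnbias.rnnlm import (
    NucleotideRNN,
    RNNParams,
    RNNSpec,
    TrainConfig,
    cell_forward,
    count_parameters,
    init_params,
    load_model,
    output_distribution,
    perplexity,
    prediction_error_rate,
    save_model,
    sequence_log_prob,
    sequence_log_probs,
    train_model,
)

UNITS = ["rnn", "gru", "lstm"]


def _zero(unit, hidden=10):
    return init_params(RNNSpec(unit, hidden), seed=0, init_scale=0.0)


class TestSpecAndParams:
    @pytest.mark.parametrize("unit", UNITS)
    @pytest.mark.parametrize("hidden", [1, 3, 10, 20])
    def test_count_matches_actual_scalars(self, unit, hidden):
        spec = RNNSpec(unit, hidden)
        assert count_parameters(spec) == init_params(spec, 0).n_parameters

    def test_vanilla_count_by_hand(self):
        # H*4 + H*H + H + 4*H + 4 for H=10
        assert count_parameters(RNNSpec("rnn", 10)) == 194

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            RNNSpec("tcn", 10)
        with pytest.raises(ValueError):
            RNNSpec("gru", 0)

    def test_init_deterministic_and_zero_scale(self):
        spec = RNNSpec("gru", 5)
        a = init_params(spec, seed=11)
        b = init_params(spec, seed=11)
        for k in a.arrays:
            np.testing.assert_array_equal(a[k], b[k])
        z = init_params(spec, seed=11, init_scale=0.0)
        assert all(np.all(v == 0) for v in z.arrays.values())


class TestCellForward:
    def test_zero_params_vanilla_gives_zero(self):
        h = cell_forward(_zero("rnn"), np.zeros(4), np.ones(10))
        np.testing.assert_array_equal(h, np.zeros(10))

    def test_zero_params_gru_halves_state(self):
        v = np.linspace(-1, 1, 10)
        h = cell_forward(_zero("gru"), np.zeros(4), v)
        np.testing.assert_allclose(h, 0.5 * v, rtol=1e-15)

    def test_zero_params_lstm_zero_states(self):
        h, c = cell_forward(_zero("lstm"), np.zeros(4), (np.zeros(10), np.zeros(10)))
        np.testing.assert_array_equal(h, np.zeros(10))
        np.testing.assert_array_equal(c, np.zeros(10))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            cell_forward(_zero("rnn"), np.zeros(4), np.zeros(7))
        with pytest.raises(ValueError):
            cell_forward(_zero("rnn"), np.zeros(5), np.zeros(10))


class TestOutputDistribution:
    def test_uniform_for_zero_weights(self):
        y = output_distribution(_zero("rnn"), np.zeros(10))
        np.testing.assert_allclose(y, 0.25, atol=1e-15)

    def test_ln2_logit(self):
        p = _zero("rnn")
        p.arrays["c"][:] = [math.log(2), 0, 0, 0]
        y = output_distribution(p, np.zeros(10))
        np.testing.assert_allclose(y, [0.4, 0.2, 0.2, 0.2], rtol=1e-14)

    def test_shift_invariance(self):
        p = init_params(RNNSpec("gru", 6), seed=2, init_scale=0.4)
        h = np.random.default_rng(0).normal(size=6)
        y1 = output_distribution(p, h)
        p.arrays["c"][:] += 3.7
        np.testing.assert_allclose(output_distribution(p, h), y1, rtol=1e-12)

    def test_sums_to_one(self):
        p = init_params(RNNSpec("lstm", 8), seed=9, init_scale=1.0)
        y = output_distribution(p, np.random.default_rng(1).normal(size=8))
        assert abs(y.sum() - 1.0) < 1e-12 and np.all(y > 0)


class TestSequenceProb:
    def test_zero_model_uniform_conditionals(self):
        lp = sequence_log_prob(_zero("gru"), "ACGTACGTACGTACGTACGTA")
        assert lp == pytest.approx(21 * math.log(0.25), rel=1e-15)

    def test_single_symbol_matches_first_step(self):
        p = init_params(RNNSpec("lstm", 5), seed=4, init_scale=0.5)
        state = cell_forward(p, np.zeros(4))
        y = output_distribution(p, state[0])
        assert sequence_log_prob(p, "G") == pytest.approx(math.log(y[2]), rel=1e-12)

    @pytest.mark.parametrize("unit", UNITS)
    def test_enumeration_normalization(self, unit):
        p = init_params(RNNSpec(unit, 4), seed=8, init_scale=0.7)
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
        assert np.exp(sequence_log_probs(p, seqs)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_illegal_character(self):
        with pytest.raises(ValueError):
            sequence_log_prob(_zero("rnn"), "ACGU")

    def test_mixed_lengths_scored_in_order(self):
        p = init_params(RNNSpec("gru", 4), seed=3, init_scale=0.3)
        seqs = ["ACGT", "AC", "GGGTTT", "AC"]
        lps = sequence_log_probs(p, seqs)
        assert lps[1] == lps[3]
        assert lps[0] == pytest.approx(sequence_log_prob(p, "ACGT"), rel=1e-14)


class TestPerplexity:
    def test_zero_model_is_chance_level(self):
        assert perplexity(_zero("lstm"), ["ACGTA" * 4 + "T"]) == pytest.approx(4.0, abs=1e-12)

    def test_change_of_base_consistency(self):
        p = init_params(RNNSpec("gru", 6), seed=6, init_scale=0.6)
        seqs = ["ACGTACGTAC", "TTGCAGGTCA"]
        mean_nll = -sequence_log_probs(p, seqs).sum() / 20
        assert perplexity(p, seqs) == pytest.approx(
            2 ** (mean_nll / math.log(2)), rel=1e-12
        )

    def test_at_least_one(self):
        p = init_params(RNNSpec("rnn", 8), seed=1, init_scale=1.5)
        assert perplexity(p, ["ACCGTTGA"]) >= 1.0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            perplexity(_zero("rnn"), [])


class TestPredictionErrorRate:
    def test_chance_level_on_uniform_data(self):
        rng = np.random.default_rng(0)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 21)) for _ in range(500)]
        err = prediction_error_rate(_zero("gru"), seqs)
        n = 500 * 21
        assert abs(err - 0.75) < 3 * math.sqrt(0.75 * 0.25 / n)

    def test_learned_deterministic_repeat(self):
        seqs = ["ACACACACACACACACACACA"] * 64
        res = NucleotideRNN(seqs, seqs[:8], unit="gru", hidden=4).fit(
            epochs=5, optimizer="adam", learning_rate=0.05, seed=0
        )
        assert res.prediction_error_rate(seqs[:8]) <= 1 / 21 + 1e-12

    def test_empty_input(self):
        with pytest.raises(ValueError):
            prediction_error_rate(_zero("rnn"), [])


def _markov_sequences(n, T=21, seed=0):
    rng = np.random.default_rng(seed)
    P = np.array([[.6, .2, .1, .1], [.1, .6, .2, .1], [.1, .1, .6, .2], [.2, .1, .1, .6]])
    out = []
    for _ in range(n):
        s = [int(rng.integers(0, 4))]
        for _ in range(T - 1):
            s.append(int(rng.choice(4, p=P[s[-1]])))
        out.append("".join("ACGT"[i] for i in s))
    return out


class TestTraining:
    def test_epochs_zero_returns_initial_params(self):
        seqs = _markov_sequences(50)
        model = NucleotideRNN(seqs, seqs[:5], unit="gru", hidden=5)
        res = model.fit(epochs=0, seed=13)
        rng = np.random.default_rng(13)
        ref = init_params(RNNSpec("gru", 5), rng, 0.08)
        for k in ref.arrays:
            np.testing.assert_array_equal(res.params[k], ref[k])
        assert res.history == [] and res.selected_epoch is None

    def test_best_validation_nll_improves_on_initial(self):
        seqs = _markov_sequences(400, seed=2)
        cfg = TrainConfig(epochs=3, seed=5)
        res = train_model(RNNSpec("gru", 8), (seqs[:300], seqs[300:]), cfg)
        rng = np.random.default_rng(5)
        init = init_params(RNNSpec("gru", 8), rng, cfg.init_scale)
        init_nll = -sequence_log_probs(init, seqs[300:]).sum() / (100 * 21)
        assert min(h["val_nll"] for h in res.history) <= init_nll

    def test_selected_epoch_is_argmin_val_error(self):
        seqs = _markov_sequences(300, seed=4)
        res = train_model(RNNSpec("rnn", 6), (seqs[:250], seqs[250:]), TrainConfig(epochs=4, seed=0))
        errs = [h["val_error_rate"] for h in res.history]
        assert res.selected_epoch == int(np.argmin(errs)) + 1

    def test_fit_is_deterministic(self):
        seqs = _markov_sequences(120, seed=9)
        kw = dict(epochs=2, batch_size=32, seed=21)
        a = NucleotideRNN(seqs, seqs[:10], hidden=5).fit(**kw)
        b = NucleotideRNN(seqs, seqs[:10], hidden=5).fit(**kw)
        for k in a.params.arrays:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        assert a.history == b.history

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            NucleotideRNN([], unit="gru", hidden=4)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            NucleotideRNN(["ACGT", "ACG"]).fit(epochs=1)


class TestSerialization:
    def test_round_trip_bit_identical(self, tmp_path):
        seqs = _markov_sequences(60)
        res = NucleotideRNN(seqs, seqs[:6], unit="lstm", hidden=4).fit(epochs=1, seed=3)
        path = tmp_path / "m.json"
        save_model(res, path)
        loaded = load_model(path)
        for k in res.params.arrays:
            np.testing.assert_array_equal(loaded.params[k], res.params[k])
        s = "ACGTACGTACGTACGTACGTA"
        assert loaded.log_prob(s) == res.log_prob(s)
        assert loaded.history == res.history
        assert loaded.selected_epoch == res.selected_epoch

    def test_tampered_shape_rejected(self, tmp_path):
        import json

        res = NucleotideRNN(["ACGT"] * 10, unit="gru", hidden=3).fit(epochs=0)
        path = tmp_path / "m.json"
        save_model(res, path)
        doc = json.loads(path.read_text())
        doc["params"]["V"] = [[0.0] * 3] * 5
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="shape"):
            load_model(path)

    def test_spec_mismatch_rejected(self, tmp_path):
        res = NucleotideRNN(["ACGT"] * 10, unit="rnn", hidden=3).fit(epochs=0)
        path = tmp_path / "m.json"
        save_model(res, path)
        with pytest.raises(ValueError, match="expected gru"):
            load_model(path, spec=RNNSpec("gru", 3))

    def test_not_a_model_file(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text('{"hello": 1}')
        with pytest.raises(ValueError):
            load_model(path)


def test_results_summary_mentions_architecture():
    res = NucleotideRNN(["ACGT"] * 20, ["ACGT"], unit="gru", hidden=10).fit(epochs=1)
    text = res.summary()
    assert "gru" in text and "524" in text
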