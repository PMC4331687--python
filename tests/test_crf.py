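import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemner.crf import (
    LABELS,
    LinearChainCRF,
    decode_bieo,
    decode_blocks,
    encode_bieo,
)
from chemner.preprocess import Token

from conftest import FORMULA_LABELS, FORMULA_TOKENS


def char_tokens(surfaces):
    toks, cursor = [], 0
    for s in surfaces:
        toks.append(Token(s, cursor, cursor + len(s)))
        cursor += len(s) + 1
    return toks


def random_model(rng, n_features):
    model = LinearChainCRF(c=1.0, cutoff=1)
    model.feature_index = {f"f{i}=1": i for i in range(n_features)}
    model.W_obs = rng.normal(size=(n_features, len(LABELS)))
    model.W_trans = rng.normal(size=(len(LABELS), len(LABELS)))
    return model


def random_sentence(rng, n_features, length):
    return [{f"f{int(rng.integers(n_features))}": 1} for _ in range(length)]


def brute_force(model, sent):
    """Exhaustive enumeration over all |labels|^N label sequences."""
    emit = model._emissions(sent)
    N, L = emit.shape
    best, best_score = None, -np.inf
    Z = 0.0
    marg = np.zeros((N, L))
    for labs in itertools.product(range(L), repeat=N):
        s = sum(emit[n, l] for n, l in enumerate(labs))
        s += sum(model.W_trans[i, j] for i, j in zip(labs, labs[1:]))
        w = np.exp(s)
        Z += w
        for n, l in enumerate(labs):
            marg[n, l] += w
        if s > best_score:
            best_score, best = s, labs
    return best_score, marg / Z


class TestEncode:
    def test_formula_mention_gets_b_i_e(self):
        # 13-token bracketed formula: B, eleven I, E.
        toks = char_tokens(FORMULA_TOKENS)
        span = (toks[0].start, toks[-1].end)
        assert encode_bieo(toks, [span]) == FORMULA_LABELS

    def test_no_mentions_all_outside(self):
        toks = char_tokens(["a", "b", "c"])
        assert encode_bieo(toks, []) == ["O", "O", "O"]

    def test_single_token_mention_lone_b(self):
        toks = char_tokens(["a", "bb", "c"])
        assert encode_bieo(toks, [(2, 4)]) == ["O", "B", "O"]

    def test_misaligned_span_snaps_outward(self):
        toks = char_tokens(["abc", "def"])  # spans (0,3), (4,7)
        assert encode_bieo(toks, [(1, 5)]) == ["B", "E"]


class TestDecode:
    def test_b_i_e_block(self):
        toks = [Token("a", 0, 1), Token("b", 1, 2), Token("c", 2, 3)]
        assert decode_bieo(["B", "I", "E"], toks) == [(0, 3)]

    def test_all_outside(self):
        toks = [Token("a", 0, 1)] * 3
        assert decode_bieo(["O", "O", "O"], toks) == []

    def test_orphan_block_repaired(self):
        assert decode_blocks(["O", "I", "E"]) == [(1, 2)]

    def test_adjacent_blocks_split_on_new_b(self):
        assert decode_blocks(["B", "B", "E"]) == [(0, 0), (1, 2)]

    @given(st.lists(st.sampled_from(LABELS), min_size=1, max_size=12))
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_identity_on_wellformed(self, labels):
        toks = char_tokens(["t"] * len(labels))
        spans = decode_bieo(labels, toks)
        reencoded = encode_bieo(toks, spans)
        # Re-encoding the decoded spans is a fixpoint of decode.
        assert decode_bieo(reencoded, toks) == spans

    def test_encode_then_decode_recovers_spans(self):
        toks = char_tokens(["a", "b", "c", "d", "e"])
        spans = [(toks[0].start, toks[1].end), (toks[3].start, toks[3].end)]
        labels = encode_bieo(toks, spans)
        assert decode_bieo(labels, toks) == spans


class TestInferenceOracle:
    def test_viterbi_and_marginals_match_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            F = int(rng.integers(2, 6))
            model = random_model(rng, F)
            sent = random_sentence(rng, F, int(rng.integers(1, 7)))
            best_score, marg = brute_force(model, sent)
            v = [LABELS.index(l) for l in model.viterbi(sent)]
            emit = model._emissions(sent)
            vscore = sum(emit[n, l] for n, l in enumerate(v))
            vscore += sum(model.W_trans[i, j] for i, j in zip(v, v[1:]))
            assert vscore == pytest.approx(best_score, abs=1e-9)
            assert np.allclose(model.marginals(sent), marg, atol=1e-9)

    def test_marginals_normalize(self):
        rng = np.random.default_rng(1)
        model = random_model(rng, 3)
        sent = random_sentence(rng, 3, 5)
        sums = model.marginals(sent).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_zero_weights_uniform_marginals_and_first_label(self):
        model = LinearChainCRF(cutoff=1)
        model.feature_index = {}
        model.W_obs = np.zeros((0, 4))
        sent = [{"f": 1}] * 3
        assert np.allclose(model.marginals(sent), 0.25)
        assert model.viterbi(sent) == ["B", "B", "B"]

    def test_deterministic_decoding(self):
        rng = np.random.default_rng(5)
        model = random_model(rng, 4)
        sent = random_sentence(rng, 4, 6)
        assert model.viterbi(sent) == model.viterbi(sent)


def toy_training_set():
    X, y = [], []
    for _ in range(4):
        X.append([{"w": "drugA"}, {"w": "drugB"}, {"w": "filler"}])
        y.append(["B", "E", "O"])
        X.append([{"w": "filler"}, {"w": "drugC"}, {"w": "filler"}])
        y.append(["O", "B", "O"])
    return X, y


class TestTraining:
    def test_separable_set_fit_exactly(self):
        X, y = toy_training_set()
        model = LinearChainCRF(c=1.0, cutoff=1).fit(X, y)
        assert all(model.viterbi(x) == labels for x, labels in zip(X, y))

    def test_larger_cost_fits_no_worse(self):
        X, y = toy_training_set()
        loose = LinearChainCRF(c=0.1, cutoff=1).fit(X, y)
        tight = LinearChainCRF(c=8.0, cutoff=1).fit(X, y)
        ll_loose = sum(loose.sequence_logprob(x, labels)
                       for x, labels in zip(X, y))
        ll_tight = sum(tight.sequence_logprob(x, labels)
                       for x, labels in zip(X, y))
        assert ll_tight >= ll_loose - 1e-6

    def test_objective_monotone_at_accepted_iterates(self):
        X, y = toy_training_set()
        model = LinearChainCRF(c=1.0, cutoff=1).fit(X, y)
        hist = model.objective_history_
        assert len(hist) >= 2
        assert all(b <= a + 1e-8 for a, b in zip(hist, hist[1:]))

    def test_cutoff_drops_rare_features(self):
        X, y = toy_training_set()
        X[0][0]["rare"] = "once"
        model = LinearChainCRF(c=1.0, cutoff=2).fit(X, y)
        assert not any(f.startswith("rare=") for f in model.feature_index)

    def test_invalid_cost_rejected(self):
        with pytest.raises(ValueError):
            LinearChainCRF(c=0.0)
        with pytest.raises(ValueError):
            LinearChainCRF(c=-1.0)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            LinearChainCRF().fit([], [])


class TestPersistence:
    def test_json_roundtrip_preserves_inference(self, tmp_path):
        X, y = toy_training_set()
        model = LinearChainCRF(c=1.0, cutoff=1).fit(X, y)
        p = tmp_path / "model.json"
        model.save(p)
        back = LinearChainCRF.load(p)
        for x in X:
            assert back.viterbi(x) == model.viterbi(x)
            assert np.allclose(back.marginals(x), model.marginals(x))
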