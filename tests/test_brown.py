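import itertools

import numpy as np
import pytest

from chemner.brown import (
    UNK,
    BrownModel,
    _merge_delta,
    cluster_prefix,
    mutual_information,
    train_brown,
)
from chemner.fixtures import generate_bigram_stream, planted_blocks


def partition_mi(sentences, partition):
    """AMI of an explicit partition (independent oracle path)."""
    index = {}
    for ci, block in enumerate(partition):
        for t in block:
            index[t] = ci
    k = len(partition)
    P = np.zeros((k, k))
    for s in sentences:
        for x, y in zip(s, s[1:]):
            P[index[x], index[y]] += 1
    return mutual_information(P)


def best_partition(sentences, k):
    """Exhaustive search over all partitions of the vocabulary into k
    non-empty blocks (feasible for tiny vocabularies only)."""
    vocab = sorted({t for s in sentences for t in s})
    best_val, best_part = -np.inf, None
    for assignment in itertools.product(range(k), repeat=len(vocab)):
        if len(set(assignment)) != k:
            continue
        blocks = [frozenset(v for v, a in zip(vocab, assignment) if a == ci)
                  for ci in range(k)]
        val = partition_mi(sentences, blocks)
        if val > best_val:
            best_val, best_part = val, frozenset(blocks)
    return best_val, best_part


def clusters_of(model: BrownModel) -> frozenset[frozenset[str]]:
    groups: dict[str, set[str]] = {}
    for tok, path in model.paths.items():
        groups.setdefault(path, set()).add(tok)
    return frozenset(frozenset(g) for g in groups.values())


class TestMergeDelta:
    def test_matches_explicit_merge(self):
        # Oracle: AMI of the explicitly merged matrix.
        rng = np.random.default_rng(3)
        for _ in range(20):
            C = int(rng.integers(3, 7))
            P = rng.integers(0, 8, size=(C, C)).astype(float)
            if P.sum() == 0:
                continue
            T, l, r = P.sum(), P.sum(1), P.sum(0)
            I_cur = mutual_information(P)
            a, b = sorted(rng.choice(C, size=2, replace=False))
            merged = P.copy()
            merged[a, :] += merged[b, :]
            merged[:, a] += merged[:, b]
            merged = np.delete(np.delete(merged, b, 0), b, 1)
            assert _merge_delta(P, l, r, T, I_cur, a, b) == pytest.approx(
                mutual_information(merged), abs=1e-10)


class TestTrainBrown:
    def test_two_types_single_merge(self):
        model = train_brown([["x", "y"]] * 5, 2)
        assert model.paths == {"x": "0", "y": "1"}

    def test_vocab_sized_clustering_gives_unique_prefix_free_paths(self):
        model = train_brown(["a b c a b c".split()], 3)
        paths = list(model.paths.values())
        assert len(set(paths)) == 3
        for p, q in itertools.permutations(paths, 2):
            assert not q.startswith(p)

    def test_alternating_stream_recovers_role_partition(self):
        # Exhaustive search over all 2-partitions of {a,b,c,d} confirms
        # {a,c}/{b,d} maximizes bigram mutual information.
        sents = ["a b a b a b c d c d c d".split()]
        opt_val, opt_part = best_partition(sents, 2)
        assert opt_part == frozenset(
            {frozenset({"a", "c"}), frozenset({"b", "d"})})
        model = train_brown(sents, 2)
        assert clusters_of(model) == opt_part

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_objective_bounded_by_exhaustive_optimum(self, seed):
        stream = generate_bigram_stream(6, 400, n_blocks=3, seed=seed)
        model = train_brown(stream, 3)
        opt_val, _ = best_partition(stream, 3)
        greedy_val = partition_mi(stream, list(clusters_of(model)))
        assert greedy_val <= opt_val + 1e-9

    def test_planted_two_block_structure_recovered(self):
        stream = generate_bigram_stream(6, 600, n_blocks=2,
                                        coupling=0.97, seed=4)
        model = train_brown(stream, 2)
        assert clusters_of(model) == frozenset(planted_blocks(6, 2))

    def test_ami_beats_random_partition(self):
        stream = generate_bigram_stream(8, 800, n_blocks=2, seed=7)
        model = train_brown(stream, 2)
        trained = partition_mi(stream, list(clusters_of(model)))
        rng = np.random.default_rng(0)
        vocab = sorted({t for s in stream for t in s})
        for _ in range(10):
            assignment = rng.integers(0, 2, size=len(vocab))
            if len(set(assignment.tolist())) < 2:
                continue
            blocks = [frozenset(v for v, a in zip(vocab, assignment) if a == ci)
                      for ci in range(2)]
            assert trained >= partition_mi(stream, blocks) - 1e-9

    def test_paths_prefix_free(self):
        stream = generate_bigram_stream(10, 500, n_blocks=2, seed=9)
        model = train_brown(stream, 4)
        distinct = sorted(set(model.paths.values()))
        assert len(distinct) <= 4
        for p, q in itertools.permutations(distinct, 2):
            assert not q.startswith(p)

    def test_same_cluster_same_path_and_count_invariants(self):
        stream = generate_bigram_stream(10, 500, n_blocks=2, seed=9)
        model = train_brown(stream, 4)
        assert set(model.paths) == set(model.vocabulary)
        assert len(set(model.paths.values())) <= model.n_clusters

    def test_clamps_to_vocabulary_size(self):
        with pytest.warns(UserWarning, match="clamp"):
            model = train_brown([["a", "b"]], 10)
        assert model.n_clusters == 2

    def test_min_count_maps_rare_types_to_unk(self):
        stream = [["a", "b", "a", "b", "rare"]] * 3 + [["a", "b"]]
        model = train_brown(stream, 2, min_count=4)
        assert "rare" not in model.paths
        assert UNK in model.paths

    def test_deterministic(self):
        stream = generate_bigram_stream(8, 400, seed=5)
        m1 = train_brown(stream, 3)
        m2 = train_brown(stream, 3)
        assert m1.paths == m2.paths

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            train_brown([], 2)


class TestClusterPrefix:
    def test_prefix_of_path(self):
        model = BrownModel(paths={"tok": "01100110110"}, n_clusters=1)
        assert cluster_prefix(model, "tok", 4) == "0110"

    def test_long_n_clamps_to_whole_path(self):
        model = BrownModel(paths={"tok": "0110"}, n_clusters=1)
        assert cluster_prefix(model, "tok", 99) == "0110"

    def test_oov_returns_sentinel(self):
        model = BrownModel(paths={}, n_clusters=1)
        assert cluster_prefix(model, "missing", 4) == UNK

    def test_nonpositive_n_rejected(self):
        model = BrownModel(paths={"t": "0"}, n_clusters=1)
        with pytest.raises(ValueError):
            cluster_prefix(model, "t", 0)


class TestPersistence:
    def test_tsv_roundtrip(self, tmp_path):
        stream = generate_bigram_stream(6, 300, seed=2)
        model = train_brown(stream, 3)
        p = tmp_path / "paths.tsv"
        model.save(p)
        back = BrownModel.load(p)
        assert back.paths == model.paths
        assert back.vocabulary == model.vocabulary
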