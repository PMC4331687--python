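"""Brown clustering: hierarchical word representations from bigram statistics.

Word types are greedily merged into clusters so as to maximize the average
mutual information (AMI) between adjacent clusters in the token stream,

    I = sum_{c,c'} p(c, c') * log( p(c, c') / (p(c) p(c')) ),

where ``p(c, c')`` is the empirical probability that a token of cluster
``c`` is immediately followed by one of cluster ``c'`` (sentence boundaries
break adjacency).  The classic restricted-window scheme is used: the
``n_clusters`` most frequent types seed singleton clusters; every remaining
type is added as a provisional extra cluster and the AMI-optimal pair of the
window is merged, keeping the window at ``n_clusters``.  Finally the window
is merged down to a single root, and that merge sequence defines a binary
tree whose leaves are the clusters: following the path from the root, a 0
for each left branch and a 1 for each right branch, gives every cluster —
and hence every type in it — a bit-string representation.  Types with
similar contexts end up with similar path prefixes, which is what the
tagger's prefix features exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Sentinel representation for out-of-vocabulary tokens.
UNK = "UNK"


@dataclass
class BrownModel:
    """Token-type → binary-path mapping from a cluster merge tree."""

    paths: dict[str, str]
    n_clusters: int
    vocabulary: dict[str, int] = field(default_factory=dict)

    def path_of(self, token: str) -> str | None:
        return self.paths.get(token)

    def save(self, path: str | Path) -> None:
        """Persist as the conventional ``path<TAB>token<TAB>count`` layout."""
        with open(path, "w", encoding="utf-8") as fh:
            for token in sorted(self.paths, key=lambda t: (self.paths[t], t)):
                count = self.vocabulary.get(token, 0)
                fh.write(f"{self.paths[token]}\t{token}\t{count}\n")

    @classmethod
    def load(cls, path: str | Path) -> "BrownModel":
        paths: dict[str, str] = {}
        vocab: dict[str, int] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                bits, token, count = line.split("\t")
                paths[token] = bits
                vocab[token] = int(count)
        return cls(paths=paths, n_clusters=len(set(paths.values())),
                   vocabulary=vocab)


def cluster_prefix(model: BrownModel, token: str, n: int) -> str:
    """First ``min(n, len(path))`` bits of the token's path; ``UNK`` if the
    token is out of vocabulary."""
    if n < 1:
        raise ValueError("prefix length must be >= 1")
    path = model.path_of(token)
    if path is None:
        return UNK
    return path[:n]


def mutual_information(P: np.ndarray) -> float:
    """AMI of a cluster-bigram count matrix (natural log)."""
    T = P.sum()
    if T <= 0:
        return 0.0
    q = P / T
    l = q.sum(axis=1)
    r = q.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = q / np.outer(l, r)
        terms = np.where(q > 0, q * np.log(ratio), 0.0)
    return float(terms.sum())


def _terms(x: np.ndarray, lx: np.ndarray, rx: np.ndarray, T: float) -> float:
    """Sum of q*log(q/(l r)) over the entries of ``x`` (vectorized, 0 if q=0)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(
            x > 0,
            (x / T) * (np.log(x) + np.log(T) - np.log(lx) - np.log(rx)),
            0.0,
        )
    return float(np.sum(vals))


def _cluster_contribution(P: np.ndarray, l: np.ndarray, r: np.ndarray,
                          T: float, a: int) -> float:
    """AMI contribution of row ``a`` plus column ``a``, entry (a,a) once."""
    return (
        _terms(P[a, :], l[a], r, T)
        + _terms(P[:, a], l, r[a], T)
        - _terms(P[a, a], l[a], r[a], T)
    )


def _merge_delta(P: np.ndarray, l: np.ndarray, r: np.ndarray, T: float,
                 I_cur: float, a: int, b: int) -> float:
    """AMI of the clustering after merging clusters ``a`` and ``b``.

    O(C): only the terms touching rows/columns a and b change.
    """
    keep = np.ones(len(l), dtype=bool)
    keep[[a, b]] = False
    row_m = P[a, keep] + P[b, keep]
    col_m = P[keep, a] + P[keep, b]
    self_m = P[a, a] + P[a, b] + P[b, a] + P[b, b]
    l_m = l[a] + l[b]
    r_m = r[a] + r[b]
    removed = (
        _cluster_contribution(P, l, r, T, a)
        + _cluster_contribution(P, l, r, T, b)
        - _terms(P[a, b], l[a], r[b], T)
        - _terms(P[b, a], l[b], r[a], T)
    )
    added = (
        _terms(row_m, l_m, r[keep], T)
        + _terms(col_m, l[keep], r_m, T)
        + _terms(self_m, l_m, r_m, T)
    )
    return I_cur - removed + added


class _Node:
    __slots__ = ("left", "right", "cluster")

    def __init__(self, cluster: int | None = None,
                 left: "_Node | None" = None, right: "_Node | None" = None):
        self.cluster = cluster
        self.left = left
        self.right = right


def train_brown(
    sentences: Iterable[Sequence[str]],
    n_clusters: int,
    min_count: int = 1,
) -> BrownModel:
    """Cluster the vocabulary of a token stream into ``n_clusters`` groups.

    ``sentences`` is an iterable of token sequences; bigrams never cross a
    sequence boundary.  Types occurring fewer than ``min_count`` times are
    replaced by the :data:`UNK` type before clustering.  Deterministic given
    the input: types are processed in (frequency desc, token asc) order and
    AMI ties in merge selection are broken toward the lexicographically
    smallest pair of cluster representatives.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    sents = [list(s) for s in sentences if s]
    if not sents:
        raise ValueError("token stream is empty")

    counts: dict[str, int] = {}
    for s in sents:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    if min_count > 1:
        mapped = [[t if counts[t] >= min_count else UNK for t in s] for s in sents]
        counts = {}
        for s in mapped:
            for t in s:
                counts[t] = counts.get(t, 0) + 1
        sents = mapped

    types = sorted(counts, key=lambda t: (-counts[t], t))
    V = len(types)
    if n_clusters > V:
        warnings.warn(
            f"n_clusters={n_clusters} exceeds vocabulary size {V}; clamping"
        )
        n_clusters = V

    bigrams: dict[tuple[str, str], int] = {}
    for s in sents:
        for x, y in zip(s, s[1:]):
            bigrams[(x, y)] = bigrams.get((x, y), 0) + 1

    # Active window state: clusters[i] = set of member types; reps[i] their
    # lexicographic representative; P the inter-cluster bigram count matrix.
    clusters: list[set[str]] = []
    reps: list[str] = []
    seed = types[:n_clusters]
    rest = types[n_clusters:]
    for t in seed:
        clusters.append({t})
        reps.append(t)

    def bigram_count(members_a: set[str], members_b: set[str]) -> float:
        return float(sum(bigrams.get((x, y), 0)
                         for x in members_a for y in members_b))

    C = len(clusters)
    P = np.zeros((C, C))
    for i in range(C):
        for j in range(C):
            P[i, j] = bigram_count(clusters[i], clusters[j])

    def best_pair() -> tuple[int, int]:
        T = P.sum()
        l = P.sum(axis=1)
        r = P.sum(axis=0)
        I_cur = mutual_information(P)
        order = sorted(range(len(clusters)), key=lambda i: reps[i])
        best: tuple[int, int] | None = None
        best_val = -np.inf
        for oi in range(len(order)):
            for oj in range(oi + 1, len(order)):
                a, b = order[oi], order[oj]
                if T > 0:
                    val = _merge_delta(P, l, r, T, I_cur, a, b)
                else:
                    val = 0.0
                if val > best_val + 1e-12:
                    best_val = val
                    best = (a, b)
        assert best is not None
        return best

    def merge(a: int, b: int) -> None:
        """Fold cluster b into a (row/col sums) and drop b."""
        nonlocal P
        if reps[b] < reps[a]:
            a, b = b, a
        P[a, :] += P[b, :]
        P[:, a] += P[:, b]
        P = np.delete(np.delete(P, b, axis=0), b, axis=1)
        clusters[a] |= clusters[b]
        reps[a] = min(reps[a], reps[b])
        del clusters[b]
        del reps[b]

    # --- phase 2: add remaining types one at a time, keep window size fixed.
    for t in rest:
        clusters.append({t})
        reps.append(t)
        C = len(clusters)
        newP = np.zeros((C, C))
        newP[: C - 1, : C - 1] = P
        for i in range(C - 1):
            newP[i, C - 1] = bigram_count(clusters[i], {t})
            newP[C - 1, i] = bigram_count({t}, clusters[i])
        newP[C - 1, C - 1] = bigram_count({t}, {t})
        P = newP
        a, b = best_pair()
        merge(a, b)

    # --- phase 3: merge the window down to one root, recording the tree.
    nodes = [_Node(cluster=i) for i in range(len(clusters))]
    leaf_members = [set(c) for c in clusters]
    while len(clusters) > 1:
        a, b = best_pair()
        if reps[b] < reps[a]:
            a, b = b, a
        parent = _Node(left=nodes[a], right=nodes[b])
        nodes[a] = parent
        del nodes[b]
        merge(a, b)

    paths: dict[str, str] = {}

    def assign(node: _Node, prefix: str) -> None:
        if node.cluster is not None:
            for tok in leaf_members[node.cluster]:
                paths[tok] = prefix
        else:
            assign(node.left, prefix + "0")
            assign(node.right, prefix + "1")

    assign(nodes[0], "")
    return BrownModel(paths=paths, n_clusters=n_clusters, vocabulary=counts)
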