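"""BIEO linear-chain CRF: span encoding/decoding, training, Viterbi
decoding, and forward–backward marginals.

The model is the standard linear-chain conditional random field

    Pr(y | x) ∝ exp( Σ_n  w · f(y_n, y_{n-1}, x) )

with indicator feature functions tying each observation feature to a state
label, plus a dense label-bigram transition matrix (the contextual family).
Training maximizes the L2-regularized conditional log-likelihood

    Σ log Pr(y | x)  −  ‖w‖² / (2c)

by L-BFGS from w = 0; the cost ``c`` trades data fit against regularization
(larger c fits the training data more tightly).  Observation features seen
fewer than ``cutoff`` times in the training set are dropped.

Spans are encoded over the label set {B, I, E, O}: a multi-token span is
B I* E, a single-token span a lone B, everything else O.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import logsumexp

from .preprocess import Token

LABELS: tuple[str, ...] = ("B", "I", "E", "O")
_LIDX = {lab: i for i, lab in enumerate(LABELS)}


# ---------------------------------------------------------------------------
# BIEO span encoding / decoding


def encode_bieo(tokens: Sequence[Token],
                spans: Sequence[tuple[int, int]]) -> list[str]:
    """Label each token of a sentence against character spans.

    ``spans`` are half-open character spans (already non-nested).  A span's
    tokens are every token overlapping it — boundaries that cut through a
    token snap outward to whole tokens.  Multi-token spans become B I* E,
    single-token spans a lone B.
    """
    labels = ["O"] * len(tokens)
    for start, end in spans:
        hit = [i for i, t in enumerate(tokens)
               if t.start < end and t.end > start]
        if not hit:
            continue
        if len(hit) == 1:
            labels[hit[0]] = "B"
        else:
            labels[hit[0]] = "B"
            for i in hit[1:-1]:
                labels[i] = "I"
            labels[hit[-1]] = "E"
    return labels


def decode_blocks(labels: Sequence[str]) -> list[tuple[int, int]]:
    """Token-index blocks (inclusive) of the spans a label sequence encodes.

    Well-formed blocks are ``B I* E`` and lone ``B``; malformed runs (I or E
    with no opening B) are repaired by treating the run's first token as B.
    """
    blocks: list[tuple[int, int]] = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] == "O":
            i += 1
            continue
        j = i
        while labels[j] != "E" and j + 1 < n and labels[j + 1] in ("I", "E"):
            j += 1
        blocks.append((i, j))
        i = j + 1
    return blocks


def decode_bieo(labels: Sequence[str],
                tokens: Sequence[Token]) -> list[tuple[int, int]]:
    """Character spans (half-open) of the mentions a label sequence encodes."""
    if len(labels) != len(tokens):
        raise ValueError("labels and tokens must have equal length")
    return [(tokens[i].start, tokens[j].end)
            for i, j in decode_blocks(labels)]


# ---------------------------------------------------------------------------
# Model


def _flatten(feature_map: dict[str, object]) -> list[str]:
    """Render a name→value map as indicator feature strings."""
    return [f"{k}={v}" for k, v in feature_map.items()]


class LinearChainCRF:
    """Linear-chain CRF over the BIEO label set.

    Parameters
    ----------
    c:
        Cost (regularization trade-off); the L2 penalty is ‖w‖²/(2c), so
        larger values fit the training data more tightly.  Must be > 0.
    cutoff:
        Minimum training-set frequency for an observation feature to be
        retained (default 2).
    max_iter, tol:
        L-BFGS stopping rule: relative objective change below ``tol`` or
        ``max_iter`` iterations, whichever first.
    """

    def __init__(self, c: float = 1.0, cutoff: int = 2,
                 max_iter: int = 300, tol: float = 1e-5):
        if c <= 0:
            raise ValueError("cost c must be positive")
        if cutoff < 1:
            raise ValueError("cutoff must be >= 1")
        self.c = float(c)
        self.cutoff = int(cutoff)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.labels = LABELS
        self.feature_index: dict[str, int] = {}
        self.W_obs = np.zeros((0, len(LABELS)))
        self.W_trans = np.zeros((len(LABELS), len(LABELS)))
        self.objective_history_: list[float] = []

    # -- training ----------------------------------------------------------

    def fit(self, X: Sequence[Sequence[dict[str, object]]],
            y: Sequence[Sequence[str]]) -> "LinearChainCRF":
        """Fit on sentences ``X`` (lists of per-token feature maps) with
        label sequences ``y``."""
        if not X:
            raise ValueError("training set is empty")
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        flat = [[_flatten(fm) for fm in sent] for sent in X]

        counts: dict[str, int] = {}
        for sent in flat:
            for feats in sent:
                for f in feats:
                    counts[f] = counts.get(f, 0) + 1
        self.feature_index = {
            f: i for i, f in enumerate(sorted(
                f for f, n in counts.items() if n >= self.cutoff))
        }
        F, L = len(self.feature_index), len(LABELS)

        lengths = np.array([len(sent) for sent in flat], dtype=int)
        if np.any(lengths == 0):
            raise ValueError("empty sentences are not trainable")
        B = len(flat)
        P = int(lengths.sum())
        N_max = int(lengths.max())

        rows, cols = [], []
        p = 0
        y_idx = np.empty(P, dtype=int)
        for sent, labs in zip(flat, y):
            if len(sent) != len(labs):
                raise ValueError("feature maps and labels length mismatch")
            for feats, lab in zip(sent, labs):
                for f in feats:
                    j = self.feature_index.get(f)
                    if j is not None:
                        rows.append(p)
                        cols.append(j)
                y_idx[p] = _LIDX[lab]
                p += 1
        Xmat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(P, F))

        # Padded (B, N_max) row-index grid; -1 marks padding.
        pad_idx = np.full((B, N_max), -1, dtype=int)
        p = 0
        for b, n in enumerate(lengths):
            pad_idx[b, :n] = np.arange(p, p + n)
            p += n
        valid = pad_idx >= 0

        y_pad = np.zeros((B, N_max), dtype=int)
        y_pad[valid] = y_idx[pad_idx[valid]]
        # Empirical transition counts.
        C_trans = np.zeros((L, L))
        for n in range(N_max - 1):
            both = valid[:, n + 1]
            np.add.at(C_trans, (y_pad[both, n], y_pad[both, n + 1]), 1.0)
        Y1 = np.zeros((P, L))
        Y1[np.arange(P), y_idx] = 1.0

        last = {"x": None, "f": None}

        def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
            W_obs = theta[: F * L].reshape(F, L)
            W_trans = theta[F * L:].reshape(L, L)
            emit_flat = Xmat @ W_obs                      # (P, L)
            emit = np.zeros((B, N_max, L))
            emit[valid] = emit_flat[pad_idx[valid]]

            alpha = np.full((B, N_max, L), -np.inf)
            alpha[:, 0] = emit[:, 0]
            for n in range(1, N_max):
                cand = (
                    logsumexp(alpha[:, n - 1][:, :, None]
                              + W_trans[None, :, :], axis=1)
                    + emit[:, n]
                )
                mask = valid[:, n]
                alpha[mask, n] = cand[mask]
            logZ = logsumexp(alpha[np.arange(B), lengths - 1], axis=1)

            beta = np.zeros((B, N_max, L))
            for n in range(N_max - 2, -1, -1):
                nxt = emit[:, n + 1] + beta[:, n + 1]
                cand = logsumexp(
                    W_trans[None, :, :] + nxt[:, None, :], axis=2)
                mask = valid[:, n + 1]
                beta[mask, n] = cand[mask]

            gold = float(emit_flat[np.arange(P), y_idx].sum()
                         + (C_trans * W_trans).sum())
            nll = float(logZ.sum()) - gold + float(theta @ theta) / (2 * self.c)

            # Node marginals.
            logmu = alpha + beta - logZ[:, None, None]
            mu = np.zeros((B, N_max, L))
            mu[valid] = np.exp(logmu[valid])
            mu_flat = np.zeros((P, L))
            mu_flat[pad_idx[valid]] = mu[valid]
            grad_obs = Xmat.T @ (mu_flat - Y1) + W_obs / self.c

            # Pairwise marginals -> expected transition counts.
            E_trans = np.zeros((L, L))
            for n in range(N_max - 1):
                mask = valid[:, n + 1]
                if not mask.any():
                    continue
                logxi = (
                    alpha[mask, n][:, :, None]
                    + W_trans[None, :, :]
                    + (emit[mask, n + 1] + beta[mask, n + 1])[:, None, :]
                    - logZ[mask, None, None]
                )
                E_trans += np.exp(logxi).sum(axis=0)
            grad_trans = E_trans - C_trans + W_trans / self.c

            grad = np.concatenate([grad_obs.ravel(), grad_trans.ravel()])
            last["x"], last["f"] = theta.copy(), nll
            return nll, grad

        self.objective_history_ = []

        def record(xk: np.ndarray) -> None:
            if last["x"] is not None and np.array_equal(xk, last["x"]):
                self.objective_history_.append(last["f"])
            else:
                self.objective_history_.append(objective(xk)[0])

        theta0 = np.zeros(F * L + L * L)
        res = minimize(
            objective, theta0, jac=True, method="L-BFGS-B",
            callback=record,
            options={"maxiter": self.max_iter, "ftol": self.tol,
                     "maxcor": 10},
        )
        self.W_obs = res.x[: F * L].reshape(F, L)
        self.W_trans = res.x[F * L:].reshape(L, L)
        return self

    # -- inference ---------------------------------------------------------

    def _emissions(self, sent: Sequence[dict[str, object]]) -> np.ndarray:
        L = len(LABELS)
        emit = np.zeros((len(sent), L))
        for n, fm in enumerate(sent):
            for f in _flatten(fm):
                j = self.feature_index.get(f)
                if j is not None:
                    emit[n] += self.W_obs[j]
        return emit

    def viterbi(self, sent: Sequence[dict[str, object]]) -> list[str]:
        """Most probable label sequence; ties resolve toward the label
        earlier in the fixed order (B, I, E, O)."""
        if not sent:
            return []
        emit = self._emissions(sent)
        N, L = emit.shape
        delta = np.empty((N, L))
        back = np.zeros((N, L), dtype=int)
        delta[0] = emit[0]
        for n in range(1, N):
            scores = delta[n - 1][:, None] + self.W_trans
            back[n] = np.argmax(scores, axis=0)
            delta[n] = scores[back[n], np.arange(L)] + emit[n]
        path = [int(np.argmax(delta[-1]))]
        for n in range(N - 1, 0, -1):
            path.append(int(back[n, path[-1]]))
        return [LABELS[i] for i in reversed(path)]

    def marginals(self, sent: Sequence[dict[str, object]]) -> np.ndarray:
        """Forward–backward marginals Pr(y_n = ℓ | x), shape (N, |labels|);
        each row sums to 1."""
        if not sent:
            return np.zeros((0, len(LABELS)))
        emit = self._emissions(sent)
        N, L = emit.shape
        alpha = np.empty((N, L))
        alpha[0] = emit[0]
        for n in range(1, N):
            alpha[n] = logsumexp(
                alpha[n - 1][:, None] + self.W_trans, axis=0) + emit[n]
        beta = np.zeros((N, L))
        for n in range(N - 2, -1, -1):
            beta[n] = logsumexp(
                self.W_trans + (emit[n + 1] + beta[n + 1])[None, :], axis=1)
        logZ = logsumexp(alpha[-1])
        return np.exp(alpha + beta - logZ)

    def sequence_logprob(self, sent: Sequence[dict[str, object]],
                         labels: Sequence[str]) -> float:
        """log Pr(labels | sent) under the model."""
        emit = self._emissions(sent)
        idx = [_LIDX[lab] for lab in labels]
        score = float(sum(emit[n, i] for n, i in enumerate(idx)))
        score += float(sum(self.W_trans[i, j] for i, j in zip(idx, idx[1:])))
        alpha = emit[0].copy()
        for n in range(1, len(labels)):
            alpha = logsumexp(alpha[:, None] + self.W_trans, axis=0) + emit[n]
        return score - float(logsumexp(alpha))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "chemner-crf-1",
            "labels": list(self.labels),
            "c": self.c,
            "cutoff": self.cutoff,
            "features": sorted(self.feature_index,
                               key=self.feature_index.get),
            "W_obs": self.W_obs.tolist(),
            "W_trans": self.W_trans.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "LinearChainCRF":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "chemner-crf-1":
            raise ValueError("unrecognized model container")
        model = cls(c=payload["c"], cutoff=payload["cutoff"])
        model.feature_index = {f: i for i, f in enumerate(payload["features"])}
        model.W_obs = np.asarray(payload["W_obs"], dtype=float)
        model.W_trans = np.asarray(payload["W_trans"], dtype=float)
        return model
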