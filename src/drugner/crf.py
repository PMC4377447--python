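"""A linear-chain conditional random field over binary indicator features.

The model assigns a tag sequence y to a token sequence with score

    score(x, y) = sum_t [ W[features(x, t), y_t] + A[y_{t-1}, y_t] ]
                  + b_start[y_1] + b_end[y_T]

and probability proportional to exp(score).  W holds one weight per
(feature, label) pair, A the label-transition weights, and b_start/b_end
boundary biases.  Training minimizes the L2-penalized negative conditional
log-likelihood

    NLL(theta) = sum_s [ log Z_s - score(x_s, y_s) ] + c2 * ||theta||^2

with exact gradients from the forward-backward recursions, optimized by
L-BFGS; decoding uses Viterbi.  The regularization coefficient ``c2`` is
the single training knob exposed to callers.

Features are serialized strings; sentences are vectorized against a fixed
vocabulary into sparse indicator matrices.  Training is deterministic for a
fixed corpus and configuration (the objective is convex and the optimizer
has no random component).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import logsumexp


def build_feature_vocab(sentences_features: Iterable[Sequence[Iterable[str]]]) -> dict[str, int]:
    """Deterministic feature -> column index map (first-seen order)."""
    vocab: dict[str, int] = {}
    for sent in sentences_features:
        for token_feats in sent:
            for f in token_feats:
                if f not in vocab:
                    vocab[f] = len(vocab)
    return vocab


def vectorize_sentence(
    token_features: Sequence[Iterable[str]], vocab: dict[str, int]
) -> sp.csr_matrix:
    """Sparse indicator matrix (tokens x vocabulary); unknown features drop."""
    indptr = [0]
    indices: list[int] = []
    for feats in token_features:
        cols = sorted({vocab[f] for f in set(feats) if f in vocab})
        indices.extend(cols)
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.float64)
    return sp.csr_matrix(
        (data, indices, indptr), shape=(len(token_features), len(vocab))
    )


@dataclass
class LinearChainCRF:
    """CRF tagger bound to a fixed label alphabet and feature vocabulary."""

    labels: list[str]
    vocab: dict[str, int]
    c2: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    W: np.ndarray | None = None
    A: np.ndarray | None = None
    b_start: np.ndarray | None = None
    b_end: np.ndarray | None = None
    converged: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty label alphabet")
        if self.c2 < 0:
            raise ValueError("c2 must be non-negative")
        self._label_idx = {lab: i for i, lab in enumerate(self.labels)}

    # -- parameter (un)flattening ----------------------------------------

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return len(self.vocab)

    def _split(self, theta: np.ndarray):
        F, L = self.n_features, self.n_labels
        W = theta[: F * L].reshape(F, L)
        A = theta[F * L : F * L + L * L].reshape(L, L)
        b_start = theta[F * L + L * L : F * L + L * L + L]
        b_end = theta[F * L + L * L + L :]
        return W, A, b_start, b_end

    # -- training ----------------------------------------------------------

    def fit(
        self,
        sentence_matrices: Sequence[sp.csr_matrix],
        sentence_labels: Sequence[Sequence[str]],
    ) -> "LinearChainCRF":
        """Estimate the weights from vectorized sentences and tag sequences."""
        if not sentence_matrices:
            raise ValueError("empty training set")
        if len(sentence_matrices) != len(sentence_labels):
            raise ValueError("matrix/label count mismatch")
        L = self.n_labels
        mats, ys, bounds = [], [], [0]
        for X, labs in zip(sentence_matrices, sentence_labels):
            if X.shape[0] != len(labs):
                raise ValueError("sentence length mismatch")
            if X.shape[0] == 0:
                continue
            mats.append(X)
            ys.append(np.array([self._label_idx[l] for l in labs], dtype=np.intp))
            bounds.append(bounds[-1] + X.shape[0])
        if not mats:
            raise ValueError("all sentences empty")
        X_all = sp.vstack(mats, format="csr")
        y_all = np.concatenate(ys)
        n_tokens = X_all.shape[0]
        starts, ends = bounds[:-1], bounds[1:]

        Y_onehot = sp.csr_matrix(
            (np.ones(n_tokens), (np.arange(n_tokens), y_all)),
            shape=(n_tokens, L),
        ).toarray()

        # empirical transition counts and boundary counts, fixed across iters
        emp_A = np.zeros((L, L))
        emp_bs = np.zeros(L)
        emp_be = np.zeros(L)
        for y, s, e in zip(ys, starts, ends):
            np.add.at(emp_A, (y[:-1], y[1:]), 1.0)
            emp_bs[y[0]] += 1.0
            emp_be[y[-1]] += 1.0

        F = self.n_features
        X_all_T = X_all.T.tocsr()

        def objective(theta: np.ndarray):
            W, A, b_start, b_end = self._split(theta)
            S = np.asarray(X_all @ W)  # (tokens, L) emission scores
            nll = 0.0
            D = np.empty((n_tokens, L))  # node marginals - gold one-hots
            grad_A = -emp_A.copy()
            grad_bs = -emp_bs.copy()
            grad_be = -emp_be.copy()
            for y, s, e in zip(ys, starts, ends):
                Ss = S[s:e]
                T = e - s
                # forward
                alpha = np.empty((T, L))
                alpha[0] = b_start + Ss[0]
                for t in range(1, T):
                    alpha[t] = Ss[t] + logsumexp(alpha[t - 1][:, None] + A, axis=0)
                logZ = logsumexp(alpha[-1] + b_end)
                # backward
                beta = np.empty((T, L))
                beta[-1] = b_end
                for t in range(T - 2, -1, -1):
                    beta[t] = logsumexp(A + (Ss[t + 1] + beta[t + 1])[None, :], axis=1)
                # gold path score
                gold = Ss[np.arange(T), y].sum() + A[y[:-1], y[1:]].sum()
                gold += b_start[y[0]] + b_end[y[-1]]
                nll += logZ - gold
                # marginals
                P = np.exp(alpha + beta - logZ)
                D[s:e] = P
                grad_bs += P[0]
                grad_be += P[-1]
                for t in range(T - 1):
                    grad_A += np.exp(
                        alpha[t][:, None] + A + (Ss[t + 1] + beta[t + 1])[None, :] - logZ
                    )
            D -= Y_onehot
            grad_W = np.asarray(X_all_T @ D)
            nll += self.c2 * float(theta @ theta)
            grad = np.concatenate(
                [grad_W.ravel(), grad_A.ravel(), grad_bs, grad_be]
            ) + 2.0 * self.c2 * theta
            return nll, grad

        theta0 = np.zeros(F * L + L * L + 2 * L)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-6},
        )
        self.W, self.A, self.b_start, self.b_end = self._split(res.x)
        self.converged = bool(res.success)
        return self

    # -- inference ---------------------------------------------------------

    def _require_fitted(self) -> None:
        if self.W is None:
            raise RuntimeError("model is not fitted")

    def predict(self, X: sp.csr_matrix) -> list[str]:
        """Viterbi-decode one vectorized sentence into label strings."""
        self._require_fitted()
        T = X.shape[0]
        if T == 0:
            return []
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} != vocabulary size {self.n_features}"
            )
        L = self.n_labels
        S = np.asarray(X @ self.W)
        delta = self.b_start + S[0]
        back = np.zeros((T, L), dtype=np.intp)
        for t in range(1, T):
            cand = delta[:, None] + self.A
            back[t] = cand.argmax(axis=0)
            delta = S[t] + cand.max(axis=0)
        delta = delta + self.b_end
        path = [int(delta.argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def sentence_log_likelihood(
        self, X: sp.csr_matrix, labels: Sequence[str]
    ) -> float:
        """log P(y | x) of one labeled sentence under the fitted model."""
        self._require_fitted()
        T = X.shape[0]
        if T != len(labels):
            raise ValueError("length mismatch")
        if T == 0:
            return 0.0
        y = np.array([self._label_idx[l] for l in labels])
        S = np.asarray(X @ self.W)
        alpha = self.b_start + S[0]
        for t in range(1, T):
            alpha = S[t] + logsumexp(alpha[:, None] + self.A, axis=0)
        logZ = logsumexp(alpha + self.b_end)
        gold = S[np.arange(T), y].sum() + self.A[y[:-1], y[1:]].sum()
        gold += self.b_start[y[0]] + self.b_end[y[-1]]
        return float(gold - logZ)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist weights plus label/vocabulary metadata to one .npz file."""
        self._require_fitted()
        meta = json.dumps(
            {
                "labels": self.labels,
                "vocab": list(self.vocab),  # insertion order = column order
                "c2": self.c2,
            }
        )
        np.savez_compressed(
            Path(path),
            W=self.W,
            A=self.A,
            b_start=self.b_start,
            b_end=self.b_end,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LinearChainCRF":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            model = cls(
                labels=list(meta["labels"]),
                vocab={f: i for i, f in enumerate(meta["vocab"])},
                c2=float(meta["c2"]),
                W=np.array(data["W"]),
                A=np.array(data["A"]),
                b_start=np.array(data["b_start"]),
                b_end=np.array(data["b_end"]),
            )
        return model
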