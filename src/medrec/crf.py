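"""Linear-chain conditional random field for BIO sequence labeling.

A standard first-order CRF: per-token indicator features feed an emission
weight matrix, plus a dense label-transition matrix.  Training minimizes the
L2-regularized negative log-likelihood with L-BFGS; gradients come from
forward-backward marginals.  Decoding is Viterbi with hard BIO constraints
(``I-x`` may only follow ``B-x`` or ``I-x``), so every decoded sequence is a
valid BIO tagging regardless of what the weights learned.

Training is deterministic for a fixed corpus: weights start at zero and
L-BFGS is deterministic, so the ``seed`` recorded on the model is metadata
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

from .errors import UsageError

OUTSIDE = "O"


def _bio_category(label: str) -> str | None:
    if label == OUTSIDE:
        return None
    return label[2:]


def valid_bio(labels: Sequence[str]) -> bool:
    """True iff ``I-x`` only ever follows ``B-x`` or ``I-x``."""
    prev = OUTSIDE
    for lab in labels:
        if lab.startswith("I-"):
            if not (prev == "B-" + lab[2:] or prev == lab):
                return False
        prev = lab
    return True


@dataclass
class CRFParams:
    """Training hyperparameters (the defaults are the package's stated choices)."""

    c2: float = 0.1  # L2 penalty on all weights
    max_iter: int = 100  # L-BFGS iteration cap
    min_feature_count: int = 1  # drop features rarer than this in training data


@dataclass
class LinearChainCRF:
    params: CRFParams = field(default_factory=CRFParams)
    labels: list[str] = field(default_factory=list)
    feature_index: dict[str, int] = field(default_factory=dict)
    w_emit: np.ndarray | None = None  # (n_features, n_labels)
    w_trans: np.ndarray | None = None  # (n_labels, n_labels)
    w_start: np.ndarray | None = None  # (n_labels,)

    # -- encoding ---------------------------------------------------------

    def _encode(self, feats: Sequence[Sequence[str]]) -> sparse.csr_matrix:
        rows, cols = [], []
        for t, fs in enumerate(feats):
            for f in fs:
                j = self.feature_index.get(f)
                if j is not None:
                    rows.append(t)
                    cols.append(j)
        data = np.ones(len(rows))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(feats), len(self.feature_index))
        )

    def _transition_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """(-inf masks) for disallowed transitions and start labels under BIO."""
        L = len(self.labels)
        trans = np.zeros((L, L))
        start = np.zeros(L)
        for j, lab in enumerate(self.labels):
            if lab.startswith("I-"):
                cat = lab[2:]
                start[j] = -np.inf
                for i, prev in enumerate(self.labels):
                    if prev not in ("B-" + cat, "I-" + cat):
                        trans[i, j] = -np.inf
        return trans, start

    # -- training ---------------------------------------------------------

    def fit(
        self,
        sequences: Sequence[Sequence[Sequence[str]]],
        label_sequences: Sequence[Sequence[str]],
    ) -> "LinearChainCRF":
        if not sequences:
            raise UsageError("cannot train a tagger on an empty corpus")
        if len(sequences) != len(label_sequences):
            raise UsageError("feature and label sequence counts differ")

        label_set = {OUTSIDE}
        for labs in label_sequences:
            label_set.update(labs)
        self.labels = sorted(label_set)
        lab_idx = {lab: i for i, lab in enumerate(self.labels)}

        counts: dict[str, int] = {}
        for seq in sequences:
            for fs in seq:
                for f in fs:
                    counts[f] = counts.get(f, 0) + 1
        self.feature_index = {
            f: i
            for i, f in enumerate(
                sorted(f for f, c in counts.items() if c >= self.params.min_feature_count)
            )
        }

        X = [self._encode(seq) for seq in sequences if len(seq) > 0]
        Y = [
            np.array([lab_idx[lab] for lab in labs], dtype=int)
            for labs in label_sequences
            if len(labs) > 0
        ]

        F, L = len(self.feature_index), len(self.labels)
        n_w = F * L + L * L + L
        B = len(X)
        lengths = np.array([x.shape[0] for x in X])
        Tmax = int(lengths.max())
        total = int(lengths.sum())

        # one stacked design matrix; rows of sequence b live at offsets[b]:offsets[b]+len
        offsets = np.concatenate([[0], np.cumsum(lengths[:-1])])
        Xall = sparse.vstack(X).tocsr()
        y_flat = np.concatenate(Y)
        # token mask in padded (B, Tmax) layout
        step = np.arange(Tmax)
        active = step[None, :] < lengths[:, None]  # (B, Tmax)
        flat_of_padded = (offsets[:, None] + step[None, :])[active]  # padded -> flat rows

        # gold sufficient statistics (constant across iterations)
        y_onehot = sparse.csr_matrix(
            (np.ones(total), (np.arange(total), y_flat)), shape=(total, L)
        )
        gold_emit = np.asarray((Xall.T @ y_onehot).todense())
        gold_trans = np.zeros((L, L))
        gold_start = np.zeros(L)
        for y in Y:
            gold_start[y[0]] += 1
            if len(y) > 1:
                np.add.at(gold_trans, (y[:-1], y[1:]), 1.0)
        n_transitions = int((lengths - 1).sum())

        def unpack(theta: np.ndarray):
            we = theta[: F * L].reshape(F, L)
            wt = theta[F * L : F * L + L * L].reshape(L, L)
            ws = theta[F * L + L * L :]
            return we, wt, ws

        first_token = offsets  # flat index of each sequence's first token

        def objective(theta: np.ndarray):
            we, wt, ws = unpack(theta)
            E_flat = np.asarray(Xall @ we)  # (total, L)
            gold_score = (
                ws[np.concatenate([[y[0]] for y in Y])].sum()
                + E_flat[np.arange(total), y_flat].sum()
                + (wt * gold_trans).sum()
            )
            # scores with the start weights folded into t = 0
            S_flat = E_flat.copy()
            S_flat[first_token] += ws
            # per-token shift for numerical range; exp-domain emissions
            m_flat = S_flat.max(axis=1)
            expS_flat = np.exp(S_flat - m_flat[:, None])
            expS = np.ones((B, Tmax, L))
            expS[active] = expS_flat
            wtmax = wt.max()
            M = np.exp(wt - wtmax)

            # scaled forward pass, batched over sequences
            ahat = np.empty((B, Tmax, L))
            c = np.ones((B, Tmax))
            a = expS[:, 0, :]
            c[:, 0] = a.sum(axis=1)
            ahat[:, 0, :] = a / c[:, 0, None]
            for t in range(1, Tmax):
                act = active[:, t]
                a = (ahat[:, t - 1, :] @ M) * expS[:, t, :]
                ct = a.sum(axis=1)
                ct = np.where(act, ct, 1.0)
                anew = a / ct[:, None]
                ahat[:, t, :] = np.where(act[:, None], anew, ahat[:, t - 1, :])
                c[:, t] = ct
            logZ = (
                np.log(c[active]).sum() + m_flat.sum() + wtmax * n_transitions
            )

            # scaled backward pass; bhat = 1 at and beyond each final token
            bhat = np.ones((B, Tmax, L))
            for t in range(Tmax - 2, -1, -1):
                inner = step[t + 1] < lengths  # t+1 is a real token
                b = ((expS[:, t + 1, :] * bhat[:, t + 1, :]) @ M.T) / c[:, t + 1, None]
                bhat[:, t, :] = np.where(inner[:, None], b, 1.0)

            # posterior marginals and gradients
            P_flat = (ahat * bhat)[active]  # (total, L), rows sum to 1
            g_emit = np.asarray(Xall.T @ P_flat) - gold_emit
            g_start = P_flat[first_token].sum(axis=0) - gold_start
            U = np.where(active[:, :, None], expS * bhat / c[:, :, None], 0.0)
            g_trans = (
                M * np.einsum("btl,btm->lm", ahat[:, :-1, :], U[:, 1:, :]) - gold_trans
            )

            c2 = self.params.c2
            nll = (logZ - gold_score) + c2 * np.dot(theta, theta)
            grad = np.concatenate([g_emit.ravel(), g_trans.ravel(), g_start])
            grad += 2.0 * c2 * theta
            return nll, grad

        res = optimize.minimize(
            objective,
            np.zeros(n_w),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.params.max_iter, "ftol": 1e-9},
        )
        self.w_emit, self.w_trans, self.w_start = unpack(res.x)
        return self

    # -- decoding ---------------------------------------------------------

    def predict(self, feats: Sequence[Sequence[str]]) -> list[str]:
        """Viterbi decode one sequence; always returns a valid BIO tagging."""
        if self.w_emit is None:
            raise UsageError("model is not trained")
        T = len(feats)
        if T == 0:
            return []
        L = len(self.labels)
        E = np.asarray(self._encode(feats) @ self.w_emit)
        mask_t, mask_s = self._transition_mask()
        trans = self.w_trans + mask_t
        delta = self.w_start + mask_s + E[0]
        back = np.zeros((T, L), dtype=int)
        for t in range(1, T):
            scores = delta[:, None] + trans
            back[t] = np.argmax(scores, axis=0)
            delta = E[t] + np.max(scores, axis=0)
        path = [int(np.argmax(delta))]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t][path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def marginals(self, feats: Sequence[Sequence[str]]) -> np.ndarray:
        """Posterior per-token label marginals (T, L) — diagnostic use."""
        if self.w_emit is None:
            raise UsageError("model is not trained")
        T, L = len(feats), len(self.labels)
        if T == 0:
            return np.zeros((0, L))
        E = np.asarray(self._encode(feats) @ self.w_emit)
        alpha = np.empty((T, L))
        alpha[0] = self.w_start + E[0]
        for t in range(1, T):
            alpha[t] = E[t] + logsumexp(alpha[t - 1][:, None] + self.w_trans, axis=0)
        beta = np.empty((T, L))
        beta[-1] = 0.0
        for t in range(T - 2, -1, -1):
            beta[t] = logsumexp(self.w_trans + (E[t + 1] + beta[t + 1])[None, :], axis=1)
        return np.exp(alpha + beta - logsumexp(alpha[-1]))
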