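"""Compact numpy sequence classifiers: CNN, LSTM, attention-BiLSTM, fastText-style.

All four models share the same contract: integer token sequences in, a
two-class softmax out, cross-entropy loss, minibatch Adam, a learned
embedding layer with dropout, and deterministic training given a seed
(single-threaded numpy). Inputs may optionally carry a per-position
character-embedding sequence (concatenated to the word embeddings before the
sequence layers) and a document-level side vector (concatenated before the
final dense layers). Padded positions (index 0) are masked throughout.

The implementations favour clarity and vectorized matmuls over generality:
float32 everywhere, full-matrix Adam updates, no GPU paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

PAD = 0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class Adam:
    """Per-parameter Adam with bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: Mapping[str, np.ndarray], grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for name, g in grads.items():
            p = params[name]
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


@dataclass
class TrainConfig:
    """Shared optimisation settings; batch size and epoch count follow the
    pipeline defaults (512 / 6), learning rate and dropout are tunable."""

    batch_size: int = 512
    epochs: int = 6
    lr: float = 1e-3
    embedding_dropout: float = 0.5
    seed: int = 0


class _SequenceModel:
    """Common fit/predict loop; subclasses implement forward/backward."""

    def __init__(self, vocab_size: int, embedding_dim: int = 100,
                 config: TrainConfig | None = None):
        self.V = vocab_size
        self.D = embedding_dim
        self.config = config or TrainConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.params: dict[str, np.ndarray] = {}
        self.params["E"] = (self.rng.random((self.V, self.D), dtype=np.float32) - 0.5) * 0.1
        self.params["E"][PAD] = 0.0
        self.validation_losses: list[float] = []

    # subclass hooks -----------------------------------------------------
    def _forward(self, ids, mask, char, side, train):
        raise NotImplementedError

    def _backward(self, dlogits, cache):
        raise NotImplementedError

    # shared machinery ---------------------------------------------------
    def _embed(self, ids: np.ndarray, char: np.ndarray | None,
               train: bool) -> tuple[np.ndarray, np.ndarray | None]:
        X = self.params["E"][ids]  # (B, L, D)
        if char is not None:
            X = np.concatenate([X, char], axis=2)
        drop = None
        p = self.config.embedding_dropout
        if train and p > 0:
            drop = (self.rng.random(X.shape, dtype=np.float32) >= p) / np.float32(1 - p)
            X = X * drop
        return X.astype(np.float32), drop

    def _embedding_grad(self, ids: np.ndarray, dX: np.ndarray,
                        drop: np.ndarray | None) -> np.ndarray:
        if drop is not None:
            dX = dX * drop
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, ids.ravel(), dX[..., : self.D].reshape(-1, self.D))
        dE[PAD] = 0.0
        return dE

    def fit(self, ids: np.ndarray, y: np.ndarray,
            char: np.ndarray | None = None, side: np.ndarray | None = None,
            val: tuple | None = None) -> "_SequenceModel":
        cfg = self.config
        opt = Adam(lr=cfg.lr)
        n = ids.shape[0]
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                b_ids = ids[sel]
                b_mask = (b_ids != PAD).astype(np.float32)
                b_char = char[sel] if char is not None else None
                b_side = side[sel] if side is not None else None
                logits, cache = self._forward(b_ids, b_mask, b_char, b_side, train=True)
                probs = _softmax(logits)
                batch_loss = -np.mean(np.log(probs[np.arange(len(sel)), y[sel]] + 1e-12))
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch + 1}, batch {start // cfg.batch_size + 1}")
                dlogits = probs
                dlogits[np.arange(len(sel)), y[sel]] -= 1.0
                dlogits = (dlogits / len(sel)).astype(np.float32)
                grads = self._backward(dlogits, cache)
                opt.step(self.params, grads)
            if val is not None:
                v_ids, v_y = val[0], val[1]
                v_char = val[2] if len(val) > 2 else None
                v_side = val[3] if len(val) > 3 else None
                p = self.predict_proba(v_ids, char=v_char, side=v_side)
                v_loss = -np.mean(np.log(np.where(v_y == 1, p, 1 - p) + 1e-12))
                self.validation_losses.append(float(v_loss))
        return self

    def predict_proba(self, ids: np.ndarray, char: np.ndarray | None = None,
                      side: np.ndarray | None = None) -> np.ndarray:
        """Probability of the positive class (label 1) per document."""
        out = np.empty(ids.shape[0], dtype=np.float64)
        bs = self.config.batch_size
        for start in range(0, ids.shape[0], bs):
            b_ids = ids[start:start + bs]
            b_mask = (b_ids != PAD).astype(np.float32)
            b_char = char[start:start + bs] if char is not None else None
            b_side = side[start:start + bs] if side is not None else None
            logits, _ = self._forward(b_ids, b_mask, b_char, b_side, train=False)
            out[start:start + bs] = _softmax(logits)[:, 1]
        return out


class TextCNN(_SequenceModel):
    """One-layer convolutional text classifier.

    Parallel 1-D convolutions with window sizes 3 and 8 (the wide filter
    suits long documents), ReLU, max-pooling over time, optional side-vector
    concatenation, one dense ReLU layer, then a two-unit softmax.
    """

    def __init__(self, vocab_size: int, embedding_dim: int = 100,
                 filter_sizes: tuple[int, ...] = (3, 8), n_filters: int = 100,
                 hidden: int = 100, side_dim: int = 0, char_dim: int = 0,
                 config: TrainConfig | None = None):
        super().__init__(vocab_size, embedding_dim, config)
        self.filter_sizes = tuple(filter_sizes)
        self.F = n_filters
        self.side_dim = side_dim
        self.in_dim = self.D + char_dim
        rng = self.rng
        for k in self.filter_sizes:
            scale = np.sqrt(2.0 / (k * self.in_dim))
            self.params[f"W{k}"] = (rng.standard_normal((k * self.in_dim, self.F))
                                    .astype(np.float32) * scale)
            self.params[f"b{k}"] = np.zeros(self.F, dtype=np.float32)
        pooled = self.F * len(self.filter_sizes) + side_dim
        self.params["Wh"] = (rng.standard_normal((pooled, hidden)).astype(np.float32)
                             * np.sqrt(2.0 / pooled))
        self.params["bh"] = np.zeros(hidden, dtype=np.float32)
        self.params["Wo"] = (rng.standard_normal((hidden, 2)).astype(np.float32)
                             * np.sqrt(1.0 / hidden))
        self.params["bo"] = np.zeros(2, dtype=np.float32)

    @staticmethod
    def _windows(X: np.ndarray, k: int) -> np.ndarray:
        """(B, L, D) -> (B, L-k+1, k*D) sliding windows (view-based)."""
        B, L, D = X.shape
        w = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, T, D, k)
        return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(B, L - k + 1, k * D)

    def _forward(self, ids, mask, char, side, train):
        X, drop = self._embed(ids, char, train)
        B, L, _ = X.shape
        pools, caches = [], []
        for k in self.filter_sizes:
            Xc = self._windows(X, k)                      # (B, T, kD)
            T = L - k + 1
            A = ((Xc.reshape(-1, k * X.shape[2]) @ self.params[f"W{k}"])
                 .reshape(B, T, self.F) + self.params[f"b{k}"])  # (B, T, F)
            R = np.maximum(A, 0.0)
            # forbid pooling from all-pad windows so padding cannot win
            win_valid = mask[:, :T] > 0
            R[~win_valid] = np.float32(-1.0)              # below any ReLU output
            arg = R.argmax(axis=1)                        # (B, F)
            pool = np.take_along_axis(R, arg[:, None, :], axis=1)[:, 0, :]
            pool = np.maximum(pool, 0.0)                  # all-pad docs pool to 0
            pools.append(pool.astype(np.float32))
            caches.append((Xc, A, arg, win_valid))
        feat = np.concatenate(pools + ([side] if side is not None else []), axis=1)
        H = np.maximum(feat @ self.params["Wh"] + self.params["bh"], 0.0)
        logits = H @ self.params["Wo"] + self.params["bo"]
        return logits, (ids, drop, X.shape, caches, feat, H, side)

    def _backward(self, dlogits, cache):
        ids, drop, xshape, caches, feat, H, side = cache
        B, L, Din = xshape
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = H.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dH = dlogits @ self.params["Wo"].T
        dH[H <= 0] = 0.0
        grads["Wh"] = feat.T @ dH
        grads["bh"] = dH.sum(axis=0)
        dfeat = dH @ self.params["Wh"].T
        dX = np.zeros((B, L, Din), dtype=np.float32)
        off = 0
        for k, (Xc, A, arg, win_valid) in zip(self.filter_sizes, caches):
            dpool = dfeat[:, off:off + self.F]
            off += self.F
            T = A.shape[1]
            dA = np.zeros_like(A)
            np.put_along_axis(dA, arg[:, None, :], dpool[:, None, :], axis=1)
            dA[A <= 0] = 0.0
            dA[~win_valid] = 0.0
            grads[f"W{k}"] = Xc.reshape(-1, k * Din).T @ dA.reshape(-1, self.F)
            grads[f"b{k}"] = dA.sum(axis=(0, 1))
            dXc = (dA.reshape(-1, self.F) @ self.params[f"W{k}"].T).reshape(B, T, k, Din)
            for j in range(k):
                dX[:, j:j + T] += dXc[:, :, j]
        if side is not None:
            pass  # side vector is an input, not a parameter
        grads["E"] = self._embedding_grad(ids, dX, drop)
        return grads


class LSTMClassifier(_SequenceModel):
    """Unidirectional LSTM; the hidden state at the last real token feeds a
    two-unit softmax. Padded steps carry state through unchanged."""

    def __init__(self, vocab_size: int, embedding_dim: int = 100, hidden: int = 100,
                 side_dim: int = 0, char_dim: int = 0, config: TrainConfig | None = None):
        super().__init__(vocab_size, embedding_dim, config)
        self.H = hidden
        self.side_dim = side_dim
        self.in_dim = self.D + char_dim
        self._init_cell("")
        self.params["Wo"] = (self.rng.standard_normal((hidden + side_dim, 2))
                             .astype(np.float32) * np.sqrt(1.0 / hidden))
        self.params["bo"] = np.zeros(2, dtype=np.float32)

    def _init_cell(self, tag: str) -> None:
        H, Din = self.H, self.in_dim
        scale = np.sqrt(1.0 / (Din + H))
        self.params[f"Wx{tag}"] = (self.rng.standard_normal((Din, 4 * H))
                                   .astype(np.float32) * scale)
        self.params[f"Wh{tag}"] = (self.rng.standard_normal((H, 4 * H))
                                   .astype(np.float32) * scale)
        b = np.zeros(4 * H, dtype=np.float32)
        b[H:2 * H] = 1.0  # forget-gate bias starts open
        self.params[f"bc{tag}"] = b

    def _run_cell(self, X: np.ndarray, mask: np.ndarray, tag: str):
        """Masked LSTM forward; returns all hidden states and the step cache."""
        B, L, _ = X.shape
        H = self.H
        Wx, Wh, b = self.params[f"Wx{tag}"], self.params[f"Wh{tag}"], self.params[f"bc{tag}"]
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        Hs = np.zeros((B, L, H), dtype=np.float32)
        XW = X @ Wx  # precompute input contributions (B, L, 4H)
        steps = []
        for t in range(L):
            z = XW[:, t] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            o = _sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            m = mask[:, t][:, None]
            steps.append((h.copy(), c.copy(), i, f, o, g, tanh_c, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
            Hs[:, t] = h
        return Hs, (X, steps, Wx, Wh)

    def _cell_backward(self, dHs: np.ndarray, cache, tag: str, grads: dict) -> np.ndarray:
        """Backprop through the masked cell given per-step dL/dh; returns dX."""
        X, steps, Wx, Wh = cache
        B, L, _ = X.shape
        H = self.H
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, dtype=np.float32)
        dX = np.zeros_like(X)
        dh = np.zeros((B, H), dtype=np.float32)
        dc = np.zeros((B, H), dtype=np.float32)
        for t in range(L - 1, -1, -1):
            h_prev, c_prev, i, f, o, g, tanh_c, m = steps[t]
            dh = dh + dHs[:, t]
            dh_new = m * dh
            dc_new = m * dc + dh_new * o * (1 - tanh_c ** 2)
            do = dh_new * tanh_c
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g ** 2),
            ], axis=1).astype(np.float32)
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ Wx.T
            dh = (1 - m) * dh + dz @ Wh.T
            dc = (1 - m) * dc + dc_new * f
        grads[f"Wx{tag}"] = dWx
        grads[f"Wh{tag}"] = dWh
        grads[f"bc{tag}"] = db
        return dX

    def _forward(self, ids, mask, char, side, train):
        X, drop = self._embed(ids, char, train)
        Hs, cell_cache = self._run_cell(X, mask, "")
        last = np.maximum(mask.sum(axis=1).astype(int) - 1, 0)
        h_last = Hs[np.arange(len(ids)), last]
        feat = np.concatenate([h_last, side], axis=1) if side is not None else h_last
        logits = feat @ self.params["Wo"] + self.params["bo"]
        return logits, (ids, drop, cell_cache, last, feat, side, mask.shape)

    def _backward(self, dlogits, cache):
        ids, drop, cell_cache, last, feat, side, mshape = cache
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = feat.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wo"].T
        dh_last = dfeat[:, : self.H]
        B, L = mshape
        dHs = np.zeros((B, L, self.H), dtype=np.float32)
        dHs[np.arange(B), last] = dh_last
        dX = self._cell_backward(dHs, cell_cache, "", grads)
        grads["E"] = self._embedding_grad(ids, dX, drop)
        return grads


class AttentionBiLSTM(LSTMClassifier):
    """Bidirectional LSTM with additive (tanh) attention over the per-step
    hidden states; the attention-weighted context vector feeds the softmax."""

    def __init__(self, vocab_size: int, embedding_dim: int = 100, hidden: int = 100,
                 attention_dim: int = 100, side_dim: int = 0, char_dim: int = 0,
                 config: TrainConfig | None = None):
        _SequenceModel.__init__(self, vocab_size, embedding_dim, config)
        self.H = hidden
        self.A = attention_dim
        self.side_dim = side_dim
        self.in_dim = self.D + char_dim
        self._init_cell("_f")
        self._init_cell("_b")
        rng = self.rng
        self.params["Wa"] = (rng.standard_normal((2 * hidden, attention_dim))
                             .astype(np.float32) * np.sqrt(1.0 / (2 * hidden)))
        self.params["ba"] = np.zeros(attention_dim, dtype=np.float32)
        self.params["va"] = (rng.standard_normal(attention_dim).astype(np.float32)
                             * np.sqrt(1.0 / attention_dim))
        self.params["Wo"] = (rng.standard_normal((2 * hidden + side_dim, 2))
                             .astype(np.float32) * np.sqrt(1.0 / (2 * hidden)))
        self.params["bo"] = np.zeros(2, dtype=np.float32)

    def _forward(self, ids, mask, char, side, train):
        X, drop = self._embed(ids, char, train)
        Hf, cache_f = self._run_cell(X, mask, "_f")
        Hb_rev, cache_b = self._run_cell(X[:, ::-1], mask[:, ::-1], "_b")
        Hb = Hb_rev[:, ::-1]
        Hall = np.concatenate([Hf, Hb], axis=2) * mask[:, :, None]  # (B, L, 2H)
        U = np.tanh(Hall @ self.params["Wa"] + self.params["ba"])   # (B, L, A)
        scores = U @ self.params["va"]                              # (B, L)
        scores = np.where(mask > 0, scores, -1e30)
        alpha = _softmax(scores)                                    # (B, L)
        context = np.einsum("bl,blh->bh", alpha, Hall)
        feat = np.concatenate([context, side], axis=1) if side is not None else context
        logits = feat @ self.params["Wo"] + self.params["bo"]
        return logits, (ids, drop, cache_f, cache_b, mask, Hall, U, alpha, feat, side)

    def _backward(self, dlogits, cache):
        ids, drop, cache_f, cache_b, mask, Hall, U, alpha, feat, side = cache
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = feat.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wo"].T
        dcontext = dfeat[:, : 2 * self.H]                           # (B, 2H)
        dalpha = np.einsum("bh,blh->bl", dcontext, Hall)
        dHall = alpha[:, :, None] * dcontext[:, None, :]
        # softmax backward
        dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dscores = (dscores * (mask > 0)).astype(np.float32)
        dU = dscores[:, :, None] * self.params["va"][None, None, :]
        dpre = (dU * (1 - U ** 2)).astype(np.float32)
        grads["va"] = np.einsum("bla,bl->a", U, dscores)
        grads["Wa"] = np.einsum("blh,bla->ha", Hall, dpre)
        grads["ba"] = dpre.sum(axis=(0, 1))
        dHall = (dHall + dpre @ self.params["Wa"].T) * mask[:, :, None]
        dHf = np.ascontiguousarray(dHall[:, :, : self.H])
        dHb = np.ascontiguousarray(dHall[:, ::-1, self.H:])
        dX = self._cell_backward(dHf, cache_f, "_f", grads)
        dX_rev = self._cell_backward(dHb, cache_b, "_b", grads)
        dX += dX_rev[:, ::-1]
        grads["E"] = self._embedding_grad(ids, dX, drop)
        return grads


class FastTextClassifier:
    """Shallow bag-of-n-grams classifier.

    Word (and optionally explicit bigram) representations are averaged into a
    single text vector and passed to a linear softmax layer. With unigrams
    only the prediction is exactly invariant to token order.
    """

    def __init__(self, vocab_size: int, embedding_dim: int = 100, ngrams: int = 2,
                 side_dim: int = 0, config: TrainConfig | None = None):
        self.V_uni = vocab_size
        self.D = embedding_dim
        self.ngrams = ngrams
        self.side_dim = side_dim
        self.config = config or TrainConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self._bigram_index: dict[tuple[int, int], int] = {}
        self.params: dict[str, np.ndarray] = {}
        self.validation_losses: list[float] = []

    def _bigram_ids(self, row: np.ndarray, build: bool) -> list[int]:
        ids: list[int] = []
        toks = row[row != PAD]
        for a, b in zip(toks, toks[1:]):
            key = (int(a), int(b))
            idx = self._bigram_index.get(key)
            if idx is None and build:
                idx = self.V_uni + len(self._bigram_index)
                self._bigram_index[key] = idx
            if idx is not None:
                ids.append(idx)
        return ids

    def _doc_ids(self, ids_matrix: np.ndarray, build: bool) -> list[np.ndarray]:
        docs = []
        for row in ids_matrix:
            uni = [int(t) for t in row[row != PAD]]
            bi = self._bigram_ids(row, build) if self.ngrams >= 2 else []
            docs.append(np.asarray(uni + bi, dtype=np.int64))
        return docs

    def fit(self, ids: np.ndarray, y: np.ndarray, char=None,
            side: np.ndarray | None = None, val=None) -> "FastTextClassifier":
        cfg = self.config
        docs = self._doc_ids(ids, build=True)
        V = self.V_uni + len(self._bigram_index)
        self.params["E"] = (self.rng.random((V, self.D), dtype=np.float32) - 0.5) * 0.1
        in_dim = self.D + (side.shape[1] if side is not None else 0)
        self.params["Wo"] = (self.rng.standard_normal((in_dim, 2)).astype(np.float32)
                             * np.sqrt(1.0 / in_dim))
        self.params["bo"] = np.zeros(2, dtype=np.float32)
        opt = Adam(lr=cfg.lr)
        n = len(docs)
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                avg = np.stack([
                    self.params["E"][docs[i]].mean(axis=0) if docs[i].size
                    else np.zeros(self.D, dtype=np.float32)
                    for i in sel
                ])
                feat = (np.concatenate([avg, side[sel]], axis=1)
                        if side is not None else avg)
                logits = feat @ self.params["Wo"] + self.params["bo"]
                probs = _softmax(logits)
                loss = -np.mean(np.log(probs[np.arange(len(sel)), y[sel]] + 1e-12))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch + 1}, batch {start // cfg.batch_size + 1}")
                dlogits = probs
                dlogits[np.arange(len(sel)), y[sel]] -= 1.0
                dlogits = (dlogits / len(sel)).astype(np.float32)
                grads = {
                    "Wo": feat.T @ dlogits,
                    "bo": dlogits.sum(axis=0),
                }
                davg = dlogits @ self.params["Wo"][: self.D].T
                dE = np.zeros_like(self.params["E"])
                for j, i in enumerate(sel):
                    if docs[i].size:
                        np.add.at(dE, docs[i], davg[j] / docs[i].size)
                grads["E"] = dE
                opt.step(self.params, grads)
        return self

    def predict_proba(self, ids: np.ndarray, char=None,
                      side: np.ndarray | None = None) -> np.ndarray:
        docs = self._doc_ids(ids, build=False)
        avg = np.stack([
            self.params["E"][d].mean(axis=0) if d.size else np.zeros(self.D, dtype=np.float32)
            for d in docs
        ])
        feat = np.concatenate([avg, side], axis=1) if side is not None else avg
        logits = feat @ self.params["Wo"] + self.params["bo"]
        return _softmax(logits)[:, 1]
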