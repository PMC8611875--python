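"""Sequence encoder: skip-gram k-mer embedding + segment CNN.

Genomes are split into fixed 2 kbp segments; each segment becomes a
(L-k+1) x d matrix of k-mer embeddings learned by a skip-gram model with
negative sampling.  A convolutional classifier with parallel filter widths
and global max pooling is trained to predict the genus of the segment's
genome; in encoding mode the 512-unit first dense layer (post-ReLU),
averaged over a genome's segments, is the genome's node feature vector.

Everything is implemented in NumPy with hand-derived gradients and an
in-repo Adam optimizer; the convolution exploits the fact that a segment
is a stream of vocabulary indices, so each filter column reduces to a
table lookup (a factor-d saving over dense convolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .sequence_io import SEGMENT_LENGTH, Segment, SeqRecord, segment_genome


# --------------------------------------------------------------------------
# k-mer tokenization
# --------------------------------------------------------------------------

def kmer_ids(seq: str, k: int) -> np.ndarray:
    """Vocabulary index of every overlapping k-mer; -1 where non-ACGT."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.zeros(arr.shape, dtype=np.int64)
    valid = np.zeros(arr.shape, dtype=bool)
    for code, ch in enumerate(b"ACGT"):
        m = arr == ch
        codes[m] = code
        valid |= m
    if len(arr) < k:
        raise ParameterError(f"sequence shorter than k={k}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ powers
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, vals, -1)


@dataclass
class KmerEmbedding:
    """Lookup table mapping each of the 4^k ACGT k-mers to a d-vector.

    Row ``4**k`` is a frozen zero vector used for k-mers containing
    non-ACGT characters (N padding embeds as zero).
    """

    k: int
    d: int
    table: np.ndarray  # (4**k + 1, d); last row all zeros

    def rows(self, ids: np.ndarray) -> np.ndarray:
        mapped = np.where(ids < 0, 4**self.k, ids)
        return self.table[mapped]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_skipgram(
    segments: list[Segment],
    k: int = 3,
    d: int = 100,
    window: int = 4,
    negatives: int = 5,
    epochs: int = 2,
    rng_seed: int = 0,
    pairs_per_epoch: int = 200_000,
    lr: float = 0.025,
    batch_size: int = 1024,
) -> KmerEmbedding:
    """Skip-gram with negative sampling over overlapping k-mer streams.

    Center/context pairs are sampled uniformly from all segments with
    offsets up to ``window``; negatives are drawn from the unigram
    distribution raised to 3/4.  Deterministic given ``rng_seed``.
    """
    if not segments:
        raise ParameterError("at least one segment required")
    if k < 1:
        raise ParameterError("k must be >= 1")
    for seg in segments:
        if len(seg.sequence) < k:
            raise ParameterError("k larger than segment length")
    rng = np.random.default_rng(rng_seed)
    vocab = 4**k

    streams = [kmer_ids(seg.sequence, k) for seg in segments]
    # concatenate with -1 separators so windows never cross segments
    sep = np.full(window, -1, dtype=np.int64)
    stream = np.concatenate([x for s in streams for x in (s, sep)])[: -window or None]
    counts = np.bincount(stream[stream >= 0], minlength=vocab).astype(np.float64)
    noise = counts**0.75
    if noise.sum() == 0:
        raise ParameterError("no valid k-mers in segments")
    noise /= noise.sum()

    W = (rng.random((vocab, d)) - 0.5) / d  # input vectors
    C = np.zeros((vocab, d))  # output vectors

    n_pairs = min(pairs_per_epoch, 8 * len(stream))
    for epoch in range(epochs):
        pos = rng.integers(0, len(stream), size=2 * n_pairs)
        off = rng.integers(1, window + 1, size=2 * n_pairs)
        sign = rng.choice([-1, 1], size=2 * n_pairs)
        ctx_pos = pos + sign * off
        ok = (ctx_pos >= 0) & (ctx_pos < len(stream))
        pos, ctx_pos = pos[ok], ctx_pos[ok]
        centers, contexts = stream[pos], stream[ctx_pos]
        ok = (centers >= 0) & (contexts >= 0)
        centers, contexts = centers[ok][:n_pairs], contexts[ok][:n_pairs]
        for start in range(0, len(centers), batch_size):
            c = centers[start : start + batch_size]
            o = contexts[start : start + batch_size]
            neg = rng.choice(vocab, size=(len(c), negatives), p=noise)
            step = lr * (1.0 - (epoch * len(centers) + start) / (epochs * len(centers)))
            step = max(step, lr * 1e-2)
            Wc, Co = W[c], C[o]
            g_pos = _sigmoid(np.sum(Wc * Co, axis=1)) - 1.0  # (B,)
            Cn = C[neg]  # (B, neg, d)
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", Wc, Cn))  # (B, neg)
            dWc = g_pos[:, None] * Co + np.einsum("bn,bnd->bd", g_neg, Cn)
            dCo = g_pos[:, None] * Wc
            dCn = g_neg[:, :, None] * Wc[:, None, :]
            np.add.at(W, c, -step * dWc)
            np.add.at(C, o, -step * dCo)
            np.add.at(C, neg.ravel(), -step * dCn.reshape(-1, d))
            # batched duplicate-index updates can overshoot on tiny
            # vocabularies; a generous clip keeps the iteration stable
            np.clip(W, -10.0, 10.0, out=W)
            np.clip(C, -10.0, 10.0, out=C)

    table = np.zeros((vocab + 1, d), dtype=np.float32)
    table[:vocab] = W
    return KmerEmbedding(k=k, d=d, table=table)


def embed_segment(segment: Segment, embedding: KmerEmbedding) -> np.ndarray:
    """(L-k+1) x d matrix of k-mer embeddings; N-containing rows are zero."""
    ids = kmer_ids(segment.sequence, embedding.k)
    return embedding.rows(ids)


# --------------------------------------------------------------------------
# CNN
# --------------------------------------------------------------------------

@dataclass
class EncoderConfig:
    """Hyperparameters of the embedding and the segment CNN."""

    k: int = 3
    d: int = 100
    widths: tuple[int, ...] = (4, 8, 16)
    n_filters: int = 64
    dense1: int = 512
    dense2: int = 256
    epochs: int = 25
    batch_size: int = 64
    lr: float = 3e-3
    dropout: float = 0.5
    segment_len: int = SEGMENT_LENGTH
    sg_window: int = 4
    sg_negatives: int = 5
    sg_epochs: int = 2
    sg_pairs: int = 200_000
    sg_lr: float = 0.025


@dataclass
class CNNModel:
    """Trained segment classifier; first dense layer is the node encoder."""

    config: EncoderConfig
    classes: list[str]
    conv_w: list[np.ndarray]  # per width: (w, d, F)
    conv_b: list[np.ndarray]  # per width: (F,)
    W0: np.ndarray  # (n_widths*F, dense1)
    b0: np.ndarray
    W1: np.ndarray  # (dense1, dense2)
    b1: np.ndarray
    W2: np.ndarray  # (dense2, C)
    b2: np.ndarray
    final_loss: float = math.nan

    def predict_from_encoding(self, vec: np.ndarray) -> np.ndarray:
        """SoftMax prediction from a (post-ReLU) first-dense encoding."""
        h2 = np.maximum(vec @ self.W1 + self.b1, 0.0)
        logits = h2 @ self.W2 + self.b2
        return _softmax(logits[None, :] if logits.ndim == 1 else logits)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _conv_forward(
    ids: np.ndarray,  # (B, T) with -1 for invalid
    table: np.ndarray,  # (V+1, d)
    conv_w: list[np.ndarray],
    conv_b: list[np.ndarray],
    widths: tuple[int, ...],
):
    """Parallel convolutions + global max pool; returns H0 and pool caches."""
    vocab_rows = table.shape[0]
    mapped = np.where(ids < 0, vocab_rows - 1, ids)
    pooled_parts = []
    caches = []
    for wi, w in enumerate(widths):
        T = ids.shape[1]
        t_out = T - w + 1
        # P[j, v, f] = table[v] . conv_w[j, :, f]
        P = np.einsum("vd,jdf->jvf", table, conv_w[wi], optimize=True)
        S = np.zeros((ids.shape[0], t_out, conv_w[wi].shape[2]), dtype=P.dtype)
        for j in range(w):
            S += P[j][mapped[:, j : j + t_out]]
        S += conv_b[wi]
        t_star = S.argmax(axis=1)  # (B, F)
        pooled = np.take_along_axis(S, t_star[:, None, :], axis=1)[:, 0, :]
        pooled_parts.append(pooled)
        caches.append((t_star, mapped))
    return np.concatenate(pooled_parts, axis=1), caches


def _forward(ids, table, model_params, widths):
    conv_w, conv_b, W0, b0, W1, b1, W2, b2 = model_params
    H0, caches = _conv_forward(ids, table, conv_w, conv_b, widths)
    h1 = np.maximum(H0 @ W0 + b0, 0.0)
    h2 = np.maximum(h1 @ W1 + b1, 0.0)
    logits = h2 @ W2 + b2
    return H0, caches, h1, h2, _softmax(logits)


def train_cnn(
    records: list[SeqRecord],
    labels: dict[str, str],
    embedding: KmerEmbedding,
    config: EncoderConfig | None = None,
    rng_seed: int = 0,
) -> CNNModel:
    """Train the segment CNN on genus-labeled virus genomes.

    Segments inherit their genome's label; training minimizes the
    cross-entropy of the SoftMax output with minibatch Adam.  The k-mer
    embedding table is frozen.  Deterministic given ``rng_seed``.
    """
    config = config or EncoderConfig()
    classes = sorted(set(labels.values()))
    if len(classes) < 2:
        raise ParameterError("need at least 2 genus classes to train the CNN")
    class_index = {c: i for i, c in enumerate(classes)}

    seg_ids: list[np.ndarray] = []
    seg_labels: list[int] = []
    for rec in records:
        if rec.id not in labels:
            raise ParameterError(f"record {rec.id!r} has no label")
        for seg in segment_genome(rec, config.segment_len):
            seg_ids.append(kmer_ids(seg.sequence, embedding.k))
            seg_labels.append(class_index[labels[rec.id]])
    X = np.stack(seg_ids)  # (n, T)
    y = np.array(seg_labels)
    n, _ = X.shape
    rng = np.random.default_rng(rng_seed)

    F = config.n_filters
    d = embedding.d

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)

    conv_w = [he((w, d, F), w * d) for w in config.widths]
    conv_b = [np.zeros(F, np.float32) for _ in config.widths]
    h0_dim = len(config.widths) * F
    W0 = he((h0_dim, config.dense1), h0_dim)
    b0 = np.zeros(config.dense1, np.float32)
    W1 = he((config.dense1, config.dense2), config.dense1)
    b1 = np.zeros(config.dense2, np.float32)
    W2 = he((config.dense2, len(classes)), config.dense2)
    b2 = np.zeros(len(classes), np.float32)

    params = [*conv_w, *conv_b, W0, b0, W1, b1, W2, b2]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step_count = 0
    table = embedding.table
    nw = len(config.widths)
    final_loss = math.nan

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            ids_b, y_b = X[batch], y[batch]
            B = len(batch)
            H0, caches = _conv_forward(ids_b, table, conv_w, conv_b, config.widths)
            if config.dropout > 0:
                keep = np.float32(1.0 - config.dropout)
                drop_mask = (rng.random(H0.shape) >= config.dropout).astype(np.float32) / keep
            else:
                drop_mask = np.float32(1.0)
            H0d = H0 * drop_mask
            h1 = np.maximum(H0d @ W0 + b0, 0.0)
            h2 = np.maximum(h1 @ W1 + b1, 0.0)
            probs = _softmax(h2 @ W2 + b2)
            epoch_loss += -np.log(probs[np.arange(B), y_b] + 1e-12).sum()

            dlogits = probs.copy()
            dlogits[np.arange(B), y_b] -= 1.0
            dlogits /= B
            gW2 = h2.T @ dlogits
            gb2 = dlogits.sum(axis=0)
            dh2 = dlogits @ W2.T
            dh2[h2 <= 0] = 0.0
            gW1 = h1.T @ dh2
            gb1 = dh2.sum(axis=0)
            dh1 = dh2 @ W1.T
            dh1[h1 <= 0] = 0.0
            gW0 = H0d.T @ dh1
            gb0 = dh1.sum(axis=0)
            dH0 = (dh1 @ W0.T) * drop_mask

            g_conv_w = []
            g_conv_b = []
            for wi, w in enumerate(config.widths):
                dPool = dH0[:, wi * F : (wi + 1) * F]  # (B, F)
                t_star, mapped = caches[wi]
                g_conv_b.append(dPool.sum(axis=0))
                gw = np.zeros_like(conv_w[wi])
                col = np.arange(F)[None, :]
                for j in range(w):
                    idx = np.take_along_axis(mapped, t_star + j, axis=1)  # (B, F)
                    dP = np.zeros((table.shape[0], F), dtype=np.float32)
                    # scatter dPool[b, f] into dP[idx[b, f], f]
                    np.add.at(dP.ravel(), (idx * F + col).ravel(), dPool.ravel())
                    gw[j] = table.T @ dP
                g_conv_w.append(gw)

            grads = [*g_conv_w, *g_conv_b, gW0, gb0, gW1, gb1, gW2, gb2]
            step_count += 1
            lr_t = config.lr * math.sqrt(1 - beta2**step_count) / (1 - beta1**step_count)
            for p, g, m, v in zip(params, grads, adam_m, adam_v):
                m += (1 - beta1) * (g - m)
                v += (1 - beta2) * (g * g - v)
                p -= lr_t * m / (np.sqrt(v) + eps)
        final_loss = epoch_loss / n

    return CNNModel(
        config=config,
        classes=classes,
        conv_w=conv_w,
        conv_b=conv_b,
        W0=W0,
        b0=b0,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        final_loss=final_loss,
    )


def _segment_matrix(record: SeqRecord, k: int, segment_len: int) -> np.ndarray:
    segs = segment_genome(record, segment_len)
    return np.stack([kmer_ids(s.sequence, k) for s in segs])


def encode_sequence(
    record: SeqRecord, embedding: KmerEmbedding, cnn: CNNModel
) -> np.ndarray:
    """512-dim node feature: first-dense ReLU outputs averaged over segments."""
    ids = _segment_matrix(record, embedding.k, cnn.config.segment_len)
    H0, _ = _conv_forward(ids, embedding.table, cnn.conv_w, cnn.conv_b, cnn.config.widths)
    h1 = np.maximum(H0 @ cnn.W0 + cnn.b0, 0.0)
    return h1.mean(axis=0)


def predict_segments(
    records: list[SeqRecord], embedding: KmerEmbedding, cnn: CNNModel
) -> dict[str, np.ndarray]:
    """Train-mode SoftMax outputs per genome (rows = its segments)."""
    out: dict[str, np.ndarray] = {}
    mp = (cnn.conv_w, cnn.conv_b, cnn.W0, cnn.b0, cnn.W1, cnn.b1, cnn.W2, cnn.b2)
    for rec in records:
        ids = _segment_matrix(rec, embedding.k, cnn.config.segment_len)
        *_, probs = _forward(ids, embedding.table, mp, cnn.config.widths)
        out[rec.id] = probs
    return out
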