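"""Token embeddings and fixed-length numeric encoding of patient sequences.

Tokens (submetric+category strings such as ``"bmipoor"``) are mapped to
dense vectors with a word2vec-style continuous bag-of-words (CBOW)
objective: each token is predicted from the mean of its context vectors
within a sliding window. The vocabulary here is tiny (at most 15 tokens),
so the exact full-softmax objective is used rather than negative sampling,
trained by plain SGD with the canonical linearly decaying learning rate.
Training is single-threaded and seeded, hence bit-reproducible.

Encoded datasets are left-padded to the maximum sequence length with a
boolean mask; each time step carries the token embedding concatenated with
a scaled time offset, and demographics (standardized age + sex one-hot)
travel separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .categorize import ValidationError
from .sequences import PatientSequence

SEX_LEVELS = ("female", "male", "unknown")


@dataclass
class EmbeddingConfig:
    dimension: int = 32
    window: int = 5
    min_count: int = 1
    algorithm: str = "cbow"       # or "skipgram"
    epochs: int = 20
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    seed: int = 0
    #: days -> decade fraction for the time channel
    time_scale: float = 1.0 / 3650.0
    age_center: float = 50.0
    age_scale: float = 20.0

    def validate(self) -> None:
        if self.dimension < 1 or self.window < 1 or self.min_count < 1:
            raise ValidationError("dimension, window and min_count must all be >= 1")
        if self.algorithm not in ("cbow", "skipgram"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")


def train_embeddings(corpus: list[list[str]],
                     config: EmbeddingConfig | None = None) -> dict[str, np.ndarray]:
    """Train CBOW (or skip-gram) embeddings on a corpus of token sequences.

    Returns a mapping from every token occurring at least ``min_count``
    times to a ``dimension``-length float32 vector.
    """
    config = config or EmbeddingConfig()
    config.validate()
    sentences = [s for s in corpus if s]
    if not sentences:
        raise ValidationError("empty corpus")

    freq: dict[str, int] = {}
    for s in sentences:
        for tok in s:
            freq[tok] = freq.get(tok, 0) + 1
    vocab = sorted((t for t, n in freq.items() if n >= config.min_count),
                   key=lambda t: (-freq[t], t))
    if not vocab:
        raise ValidationError("no token reaches min_count")
    index = {t: i for i, t in enumerate(vocab)}
    V, D = len(vocab), config.dimension

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
    w_in = (rng.random((V, D), dtype=np.float64) - 0.5) / D
    w_out = np.zeros((V, D))

    encoded = [np.array([index[t] for t in s if t in index], dtype=np.int64)
               for s in sentences]
    encoded = [s for s in encoded if len(s)]
    total = config.epochs * sum(len(s) for s in encoded)
    step = 0
    for _ in range(config.epochs):
        for sent in encoded:
            n = len(sent)
            # dynamic window shrinkage as in the reference word2vec recipe
            shrink = rng.integers(0, config.window, size=n)
            for pos in range(n):
                lr = max(config.min_lr,
                         config.initial_lr * (1 - step / max(total, 1)))
                step += 1
                w = config.window - int(shrink[pos])
                lo, hi = max(0, pos - w), min(n, pos + w + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1:hi]])
                if len(ctx) == 0:
                    continue
                center = sent[pos]
                if config.algorithm == "cbow":
                    h = w_in[ctx].mean(axis=0)
                    scores = w_out @ h
                    scores -= scores.max()
                    p = np.exp(scores)
                    p /= p.sum()
                    p[center] -= 1.0
                    grad_h = p @ w_out
                    w_out -= lr * np.outer(p, h)
                    w_in[ctx] -= lr * grad_h / len(ctx)
                else:  # skip-gram: each context token predicted from center
                    h = w_in[center]
                    scores = w_out @ h
                    scores -= scores.max()
                    sm = np.exp(scores)
                    sm /= sm.sum()
                    p = sm * len(ctx)
                    np.subtract.at(p, ctx, 1.0)
                    grad_h = p @ w_out
                    w_out -= lr * np.outer(p, h)
                    w_in[center] -= lr * grad_h
    return {t: w_in[i].astype(np.float32) for t, i in index.items()}


def save_embeddings(vectors: dict[str, np.ndarray], path) -> Path:
    """Write vectors in the de-facto word-vector text format
    (header line ``V D``, then one ``token v1 v2 ...`` line per token)."""
    path = Path(path)
    toks = sorted(vectors)
    dim = len(next(iter(vectors.values())))
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(toks)} {dim}\n")
        for t in toks:
            fh.write(t + " " + " ".join(f"{x:.7g}" for x in vectors[t]) + "\n")
    return path


def load_embeddings(path) -> dict[str, np.ndarray]:
    out = {}
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValidationError(f"{path}: malformed word-vector header")
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            out[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=np.float32)
    return out


@dataclass
class EncodedDataset:
    """Fixed-shape arrays for model consumption.

    ``features``: (n, max_len, dimension + 1) float32, left-padded, the
    trailing channel being the scaled time offset. ``mask``: (n, max_len)
    bool, True on real positions. ``demographics``: (n, 4) float32 —
    standardized age and a three-level sex one-hot. ``labels``: submetric
    -> (n,) int ordinal codes, in the order the sequences were given.
    """

    features: np.ndarray
    mask: np.ndarray
    demographics: np.ndarray
    labels: dict[str, np.ndarray]
    max_len: int
    patient_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(self.features[idx], self.mask[idx],
                              self.demographics[idx],
                              {k: v[idx] for k, v in self.labels.items()},
                              self.max_len,
                              [self.patient_ids[i] for i in idx])

    def multilabel_matrix(self, submetric_order) -> np.ndarray:
        """(n, 3 * n_submetrics) one-hot block matrix, submetric-major."""
        blocks = []
        for sm in submetric_order:
            y = self.labels[sm]
            blocks.append(np.eye(3, dtype=np.float32)[y])
        return np.concatenate(blocks, axis=1)


def encode(sequences: list[PatientSequence], vectors: dict[str, np.ndarray],
           config: EmbeddingConfig | None = None,
           max_len: int | None = None) -> EncodedDataset:
    """Pack sequences into an :class:`EncodedDataset`.

    ``max_len`` defaults to the maximum token count in ``sequences`` (the
    model input length); pass the training value when encoding new data.
    """
    config = config or EmbeddingConfig()
    if not sequences:
        raise ValidationError("no sequences to encode")
    dim = len(next(iter(vectors.values())))
    if max_len is None:
        max_len = max(len(s.tokens) for s in sequences)
    n = len(sequences)
    feats = np.zeros((n, max_len, dim + 1), dtype=np.float32)
    mask = np.zeros((n, max_len), dtype=bool)
    demo = np.zeros((n, 1 + len(SEX_LEVELS)), dtype=np.float32)
    label_keys = sorted({k for s in sequences for k in s.labels})
    labels = {k: np.full(n, -1, dtype=np.int64) for k in label_keys}
    for i, s in enumerate(sequences):
        if len(s.tokens) > max_len:
            raise ValidationError(
                f"{s.patient_id}: sequence length {len(s.tokens)} exceeds max_len {max_len}")
        start = max_len - len(s.tokens)
        for j, (tok, off) in enumerate(zip(s.tokens, s.time_offsets)):
            if tok not in vectors:
                raise ValidationError(f"{s.patient_id}: unknown token {tok!r}")
            feats[i, start + j, :dim] = vectors[tok]
            feats[i, start + j, dim] = off * config.time_scale
            mask[i, start + j] = True
        demo[i, 0] = (s.age_years - config.age_center) / config.age_scale
        if s.sex not in SEX_LEVELS:
            raise ValidationError(f"{s.patient_id}: unknown sex {s.sex!r}")
        demo[i, 1 + SEX_LEVELS.index(s.sex)] = 1.0
        for k, v in s.labels.items():
            labels[k][i] = v
    return EncodedDataset(feats, mask, demo, labels, max_len,
                          [s.patient_id for s in sequences])
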