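"""Global life-course embeddings.

The primary trainer is a skip-gram model with hierarchical softmax: each
event token predicts its surrounding tokens inside a context window, with
the output distribution factorized over a Huffman tree built from token
frequencies.  After training, the input-layer (hidden) vectors are the
embeddings.  Defaults follow the study settings: 200 dimensions, window
100, learning rate 0.05 with linear decay, 25 epochs, min_count 20.

The inner loop is numba-jitted and strictly sequential with an explicit
xorshift random stream, so training is bit-reproducible given the seed
(the single-worker contract).

A second, count-based backend (within-window co-occurrence counts ->
positive PMI -> truncated SVD) embeds the same vocabulary and serves as the
cross-algorithm robustness comparator.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .sequences import LifeCourseSentence, Vocabulary

__all__ = [
    "EmbeddingConfig",
    "EmbeddingMatrix",
    "train_embeddings",
    "train_alternative_embeddings",
]

_MAX_EXP = 6.0


@dataclass(frozen=True)
class EmbeddingConfig:
    """Skip-gram training hyperparameters (study defaults)."""

    dim: int = 200
    window: int = 100
    epochs: int = 25
    learning_rate: float = 0.05
    min_alpha: float = 1e-4
    min_count: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if self.dim <= 0 or self.window < 1 or self.epochs < 1:
            raise ValueError("dim > 0, window >= 1, epochs >= 1 required")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def replace(self, **kwargs) -> "EmbeddingConfig":
        return replace(self, **kwargs)


class EmbeddingMatrix:
    """Term x dimension matrix with its vocabulary index.

    Rows are the learned vectors whose pairwise cosine similarities drive
    every downstream stage.
    """

    def __init__(self, vocabulary: Vocabulary, vectors: np.ndarray):
        vectors = np.asarray(vectors)
        if vectors.shape[0] != len(vocabulary):
            raise ValueError("one row per vocabulary term required")
        if not np.isfinite(vectors).all():
            raise ValueError("non-finite entries in embedding matrix")
        self.vocabulary = vocabulary
        self.vectors = vectors

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.vocabulary.index[token]]

    def subset(self, tokens: list[str]) -> np.ndarray:
        return self.vectors[[self.vocabulary.index[t] for t in tokens]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.vectors, columns=[f"d{i}" for i in range(self.dim)])
        df.insert(0, "token", self.vocabulary.tokens)
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_word2vec(self, path) -> None:
        """Plain-text vector format: header ``V dim``, then one term per line."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)} {self.dim}\n")
            for token, row in zip(self.vocabulary.tokens, self.vectors):
                fh.write(token + " " + " ".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Huffman tree for hierarchical softmax
# ---------------------------------------------------------------------------

def _build_huffman(counts: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binary Huffman coding of the vocabulary by frequency.

    Returns (codes_flat, points_flat, offsets): for word w the tree path is
    points_flat[offsets[w]:offsets[w+1]] (inner-node ids, root first) with
    binary targets codes_flat at the same positions.
    """
    n = len(counts)
    if n < 2:
        raise ValueError("vocabulary smaller than 2")
    # heap entries: (count, tie_index, node_id); leaves 0..n-1, inner >= n
    heap = [(c, i, i) for i, c in enumerate(counts)]
    heapq.heapify(heap)
    parent = {}
    binary = {}
    next_id = n
    while len(heap) > 1:
        c1, _, a = heapq.heappop(heap)
        c2, _, b = heapq.heappop(heap)
        parent[a] = next_id
        parent[b] = next_id
        binary[a] = 0
        binary[b] = 1
        heapq.heappush(heap, (c1 + c2, next_id, next_id))
        next_id += 1
    root = heap[0][2]

    codes: list[list[int]] = []
    points: list[list[int]] = []
    for w in range(n):
        code: list[int] = []
        point: list[int] = []
        node = w
        while node != root:
            code.append(binary[node])
            point.append(parent[node] - n)  # inner-node row in syn1
            node = parent[node]
        code.reverse()
        point.reverse()
        codes.append(code)
        points.append(point)

    offsets = np.zeros(n + 1, dtype=np.int64)
    for w in range(n):
        offsets[w + 1] = offsets[w] + len(codes[w])
    codes_flat = np.array([b for c in codes for b in c], dtype=np.int8)
    points_flat = np.array([p for pt in points for p in pt], dtype=np.int32)
    return codes_flat, points_flat, offsets


# ---------------------------------------------------------------------------
# Jitted training loop
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=False)
def _xorshift(state: np.uint64) -> np.uint64:
    state ^= state << np.uint64(13)
    state ^= state >> np.uint64(7)
    state ^= state << np.uint64(17)
    return state


@njit(cache=True, fastmath=False)
def _train_sg_hs(
    tokens: np.ndarray,        # int32 corpus, concatenated sentences
    sent_off: np.ndarray,      # int64 sentence offsets, len n_sent+1
    codes_flat: np.ndarray,
    points_flat: np.ndarray,
    path_off: np.ndarray,
    syn0: np.ndarray,          # (V, dim) float32, modified in place
    syn1: np.ndarray,          # (V-1, dim) float32 inner nodes
    window: int,
    epochs: int,
    alpha0: float,
    min_alpha: float,
    seed: np.uint64,
):
    dim = syn0.shape[1]
    n_sent = sent_off.shape[0] - 1
    total = np.float64(tokens.shape[0]) * epochs + 1.0
    processed = 0.0
    state = seed | np.uint64(1)
    neu1e = np.zeros(dim, dtype=np.float32)
    for _epoch in range(epochs):
        for s in range(n_sent):
            start = sent_off[s]
            end = sent_off[s + 1]
            for pos in range(start, end):
                center = tokens[pos]
                alpha = alpha0 * (1.0 - processed / total)
                if alpha < min_alpha:
                    alpha = min_alpha
                processed += 1.0
                state = _xorshift(state)
                b = int(state % np.uint64(window))  # dynamic window reduction
                lo = pos - (window - b)
                if lo < start:
                    lo = start
                hi = pos + (window - b) + 1
                if hi > end:
                    hi = end
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = tokens[cpos]
                    # input vector is the context word; walk the center
                    # word's Huffman path (reference skip-gram convention)
                    for d in range(dim):
                        neu1e[d] = 0.0
                    for k in range(path_off[center], path_off[center + 1]):
                        node = points_flat[k]
                        code = codes_flat[k]
                        f = 0.0
                        for d in range(dim):
                            f += syn0[context, d] * syn1[node, d]
                        if f > _MAX_EXP:
                            fs = 1.0
                        elif f < -_MAX_EXP:
                            fs = 0.0
                        else:
                            fs = 1.0 / (1.0 + math.exp(-f))
                        g = np.float32((1.0 - code - fs) * alpha)
                        for d in range(dim):
                            neu1e[d] += g * syn1[node, d]
                        for d in range(dim):
                            syn1[node, d] += g * syn0[context, d]
                    for d in range(dim):
                        syn0[context, d] += neu1e[d]


def train_embeddings(
    corpus: list[LifeCourseSentence] | list[list[str]],
    vocabulary: Vocabulary,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> EmbeddingMatrix:
    """Train skip-gram/hierarchical-softmax embeddings on a sentence corpus.

    ``corpus`` holds :class:`LifeCourseSentence` objects or plain token
    lists; tokens must come from ``vocabulary`` (out-of-vocabulary tokens
    are dropped, which cannot happen when the corpus was built with the same
    min_count).  Returns the input-layer vectors for every vocabulary term.
    Deterministic given the config seed.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if len(vocabulary) < 2:
        raise ValueError("vocabulary smaller than 2")

    index = vocabulary.index
    encoded: list[np.ndarray] = []
    for sentence in corpus:
        toks = sentence.tokens if isinstance(sentence, LifeCourseSentence) else sentence
        ids = [index[t] for t in toks if t in index]
        if ids:
            encoded.append(np.array(ids, dtype=np.int32))
    if not encoded:
        raise ValueError("corpus contains no in-vocabulary tokens")

    tokens = np.concatenate(encoded)
    sent_off = np.zeros(len(encoded) + 1, dtype=np.int64)
    np.cumsum([len(e) for e in encoded], out=sent_off[1:])

    codes_flat, points_flat, path_off = _build_huffman(vocabulary.counts)

    rng = np.random.default_rng(config.seed)
    V = len(vocabulary)
    syn0 = ((rng.random((V, config.dim)) - 0.5) / config.dim).astype(np.float32)
    syn1 = np.zeros((V - 1, config.dim), dtype=np.float32)

    _train_sg_hs(
        tokens,
        sent_off,
        codes_flat,
        points_flat,
        path_off,
        syn0,
        syn1,
        int(config.window),
        int(config.epochs),
        float(config.learning_rate),
        float(config.min_alpha),
        np.uint64(config.seed % (2**63) + 11),
    )
    return EmbeddingMatrix(vocabulary, syn0.astype(np.float64))


# ---------------------------------------------------------------------------
# Alternative backend: co-occurrence counts -> PPMI -> truncated SVD
# ---------------------------------------------------------------------------

def train_alternative_embeddings(
    corpus: list[LifeCourseSentence] | list[list[str]],
    vocabulary: Vocabulary,
    config: EmbeddingConfig = EmbeddingConfig(),
) -> EmbeddingMatrix:
    """Count-based embedding of the same vocabulary for robustness checks.

    Builds the symmetric within-window co-occurrence matrix, converts it to
    positive pointwise mutual information, and factorizes with a truncated
    SVD (rows scaled by the square root of the singular values).  Fully
    deterministic; shares ``config.dim`` and ``config.window`` with the
    primary model.
    """
    if not corpus:
        raise ValueError("empty corpus")
    V = len(vocabulary)
    if V < 2:
        raise ValueError("vocabulary smaller than 2")
    index = vocabulary.index

    counts = np.zeros((V, V), dtype=np.float64)
    window = int(config.window)
    for sentence in corpus:
        toks = sentence.tokens if isinstance(sentence, LifeCourseSentence) else sentence
        ids = [index[t] for t in toks if t in index]
        n = len(ids)
        for i in range(n):
            hi = min(n, i + window + 1)
            for j in range(i + 1, hi):
                counts[ids[i], ids[j]] += 1.0
                counts[ids[j], ids[i]] += 1.0

    total = counts.sum()
    if total == 0:
        # degenerate corpus of isolated tokens: fall back to tiny noise so
        # downstream cosine math stays defined
        rng = np.random.default_rng(config.seed)
        return EmbeddingMatrix(vocabulary, rng.normal(scale=1e-3, size=(V, min(config.dim, V))))
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / (row * row.T))
    ppmi = np.where(np.isfinite(pmi) & (pmi > 0), pmi, 0.0)

    dim = min(config.dim, V - 1)
    # deterministic dense SVD; vocabulary sizes here are modest (<= ~10^4)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    vectors = u[:, :dim] * np.sqrt(s[:dim])
    # fix sign convention for determinism across BLAS builds
    signs = np.sign(vectors[np.abs(vectors).argmax(axis=0), np.arange(dim)])
    signs[signs == 0] = 1.0
    vectors = vectors * signs
    if not np.isfinite(vectors).all():
        vectors = np.nan_to_num(vectors)
    return EmbeddingMatrix(vocabulary, vectors)
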