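"""Cosine similarity, distance matrices and nearest-neighbor queries.

Cosine similarity between two embedding vectors A and B is

    cos(A, B) = sum_i A_i B_i / (sqrt(sum_i A_i^2) * sqrt(sum_i B_i^2))

ranging from -1 to 1 with 1 meaning full similarity.  Neighborhood queries
(the 10 closest neighbors of each sleep-problem term, and the adversities
most closely associated with them) are exact searches over the vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .embedding import EmbeddingMatrix
from .sequences import truncate_code

__all__ = [
    "cosine_similarity",
    "cosine_similarity_matrix",
    "DistanceMatrix",
    "NeighborSet",
    "knn",
    "QueryTermSet",
    "default_query_terms",
    "closest_adversities",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors; raises on zero norm.

    The result is clipped to the mathematical range [-1, 1], and identical
    inputs return exactly 1 (self-similarity is 1 by definition; floating
    rounding must not leak through the contract).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal dimension")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    if np.array_equal(a, b):
        return 1.0
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def cosine_similarity_matrix(vectors: np.ndarray) -> np.ndarray:
    """All-pairs cosine similarities of the rows of ``vectors``."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm row in vector matrix")
    unit = vectors / norms[:, None]
    sim = unit @ unit.T
    return np.clip(sim, -1.0, 1.0)


@dataclass
class DistanceMatrix:
    """Symmetric cosine-distance matrix (1 - cosine similarity) over terms."""

    terms: list[str]
    values: np.ndarray

    @classmethod
    def from_embeddings(cls, matrix: EmbeddingMatrix, terms: list[str] | None = None):
        terms = list(terms) if terms is not None else list(matrix.vocabulary.tokens)
        vectors = matrix.subset(terms)
        dist = 1.0 - cosine_similarity_matrix(vectors)
        np.fill_diagonal(dist, 0.0)
        return cls(terms, dist)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.terms), len(self.terms)):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(v).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric")
        self.values = (v + v.T) / 2.0

    def condensed(self) -> np.ndarray:
        """Upper triangle (excluding diagonal), scipy condensed order."""
        iu = np.triu_indices(len(self.terms), k=1)
        return self.values[iu]


@dataclass
class NeighborSet:
    """Ranked cosine-similarity neighbors of one query term."""

    query: str
    neighbors: list[tuple[str, float]]

    def terms(self) -> list[str]:
        return [t for t, _ in self.neighbors]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query": self.query,
                "rank": np.arange(1, len(self.neighbors) + 1),
                "neighbor": [t for t, _ in self.neighbors],
                "similarity": [s for _, s in self.neighbors],
            }
        )


def knn(
    query: str,
    matrix: EmbeddingMatrix,
    k: int = 10,
    restrict_to: set[str] | None = None,
) -> NeighborSet:
    """Top-k vocabulary terms by cosine similarity to ``query``.

    Ties break by vocabulary index for determinism.  ``restrict_to``
    optionally limits candidates to given code systems.
    """
    if query not in matrix.vocabulary:
        raise KeyError(f"query term not in vocabulary: {query!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab = matrix.vocabulary
    qv = matrix.vector(query)
    qn = np.linalg.norm(qv)
    if qn == 0:
        raise ValueError("query vector has zero norm")
    norms = np.linalg.norm(matrix.vectors, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = (matrix.vectors @ qv) / (norms * qn)
    order = []
    for i in np.argsort(-sims, kind="stable"):
        tok = vocab.tokens[i]
        if tok == query or not np.isfinite(sims[i]):
            continue
        if restrict_to is not None and vocab.systems[i] not in restrict_to:
            continue
        order.append((tok, float(sims[i])))
        if len(order) == k:
            break
    return NeighborSet(query, order)


# ---------------------------------------------------------------------------
# Query-term configuration (sleep diagnoses/medications + adversities)
# ---------------------------------------------------------------------------

@dataclass
class QueryTermSet:
    """Sleep-problem query codes plus childhood-adversity labels.

    ``sleep_terms`` holds (label, code, system) triples; a code ending in
    ``.x`` matches every vocabulary token sharing its (undotted) prefix.
    """

    sleep_terms: list[tuple[str, str, str]] = field(default_factory=list)
    adversity_terms: list[str] = field(default_factory=list)

    def resolve(self, matrix: EmbeddingMatrix) -> tuple[dict[str, str], list[str]]:
        """Map query codes to vocabulary tokens.

        Returns (token -> label, missing_descriptions).  Missing terms are
        reported, never silently dropped.
        """
        vocab = matrix.vocabulary
        resolved: dict[str, str] = {}
        missing: list[str] = []
        for label, code, system in self.sleep_terms:
            if code.endswith(".x"):
                prefix = code[:-2].replace(".", "")
                hits = [t for t in vocab.tokens if t.startswith(prefix)]
                if hits:
                    for t in hits:
                        resolved.setdefault(t, label)
                else:
                    missing.append(f"{label} ({code})")
            else:
                token = truncate_code(code, system)
                if token in vocab:
                    resolved.setdefault(token, label)
                else:
                    missing.append(f"{label} ({code})")
        for adv in self.adversity_terms:
            if adv not in vocab and adv not in resolved:
                missing.append(f"adversity ({adv})")
        if missing:
            warnings.warn(
                "query terms not in vocabulary: " + ", ".join(missing), stacklevel=2
            )
        return resolved, missing

    def resolved_sleep_tokens(self, matrix: EmbeddingMatrix) -> list[str]:
        resolved, _ = self.resolve(matrix)
        return list(resolved)

    def resolved_adversities(self, matrix: EmbeddingMatrix) -> list[str]:
        return [a for a in self.adversity_terms if a in matrix.vocabulary]

    @classmethod
    def from_yaml(cls, path) -> "QueryTermSet":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            sleep_terms=[tuple(t) for t in data.get("sleep_terms", [])],
            adversity_terms=list(data.get("adversity_terms", [])),
        )


def default_query_terms() -> QueryTermSet:
    """Packaged query configuration: sleep codes and adversity labels."""
    text = resources.files("lifecourse").joinpath("query_terms.yaml").read_text()
    data = yaml.safe_load(text)
    return QueryTermSet(
        sleep_terms=[tuple(t) for t in data["sleep_terms"]],
        adversity_terms=list(data["adversity_terms"]),
    )


def closest_adversities(
    query: QueryTermSet,
    matrix: EmbeddingMatrix,
    m: int = 3,
    aggregation: str = "max",
) -> list[tuple[str, str, float]]:
    """The m adversities most closely associated with the sleep terms.

    Association of an adversity is the maximum (default) or mean cosine
    similarity over the resolved sleep-term vectors; the arg-max sleep term
    is reported alongside.  Returns (adversity, best sleep term, similarity)
    sorted by descending association, ties by label.
    """
    sleep_tokens = query.resolved_sleep_tokens(matrix)
    adversities = query.resolved_adversities(matrix)
    if len(adversities) < m:
        raise ValueError(f"only {len(adversities)} adversities in vocabulary, need {m}")
    if not sleep_tokens:
        raise ValueError("no sleep query terms resolved in vocabulary")
    scored = []
    for adv in adversities:
        av = matrix.vector(adv)
        sims = [(cosine_similarity(av, matrix.vector(t)), t) for t in sleep_tokens]
        best_sim, best_term = max(sims, key=lambda p: (p[0], p[1]))
        score = best_sim if aggregation == "max" else float(np.mean([s for s, _ in sims]))
        scored.append((score, adv, best_term, best_sim))
    scored.sort(key=lambda r: (-r[0], r[1]))
    return [(adv, term, sim) for _, adv, term, sim in scored[:m]]
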