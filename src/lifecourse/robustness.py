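"""Embedding-space stability diagnostics.

Two checks mirror the validation a practitioner runs before trusting an
embedding geometry:

* subsample stability — retrain the whole sentence-to-embedding pipeline on
  disjoint (or bootstrap) person-level subsets with different seeds, and
  correlate the cosine-distance matrices over the shared vocabulary
  (Spearman on the vectorized upper triangle),
* cross-algorithm agreement — the same Spearman correlation between the
  primary skip-gram embedding and the count-based alternative backend.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .embedding import EmbeddingConfig, EmbeddingMatrix, train_embeddings
from .sequences import build_sentences

__all__ = ["StabilityReport", "subsample_stability", "cross_model_agreement"]


def _condensed_distances(matrix: EmbeddingMatrix, tokens: list[str]) -> np.ndarray:
    vectors = matrix.subset(tokens)
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    unit = vectors / norms
    dist = 1.0 - unit @ unit.T
    iu = np.triu_indices(len(tokens), k=1)
    return dist[iu]


@dataclass
class StabilityReport:
    """Pairwise Spearman correlations between runs' cosine-distance matrices."""

    shared_vocabulary: list[str]
    correlations: np.ndarray  # (n_runs, n_runs), diagonal 1
    run_metadata: list[dict] = field(default_factory=list)

    def pairwise(self) -> list[float]:
        iu = np.triu_indices(self.correlations.shape[0], k=1)
        return [float(v) for v in self.correlations[iu]]

    def to_frame(self) -> pd.DataFrame:
        n = self.correlations.shape[0]
        rows = [
            (i, j, float(self.correlations[i, j]))
            for i, j in itertools.combinations(range(n), 2)
        ]
        return pd.DataFrame(rows, columns=["run_a", "run_b", "spearman"])

    def to_json(self, path=None) -> str:
        payload = {
            "n_shared_terms": len(self.shared_vocabulary),
            "runs": self.run_metadata,
            "correlations": self.correlations.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def subsample_stability(
    events: pd.DataFrame,
    config: EmbeddingConfig,
    n_runs: int = 5,
    fraction: float | None = None,
    mode: str = "disjoint",
    seed: int = 0,
    identical_seeds: bool = False,
) -> StabilityReport:
    """Retrain on person-level subsets and correlate distance geometries.

    ``mode="disjoint"`` (default) splits persons into ``n_runs`` disjoint
    subsets (``fraction`` defaults to 1/n_runs and must not exceed it);
    ``mode="bootstrap"`` draws ``fraction`` of persons with replacement per
    run; ``mode="full"`` retrains on the complete cohort every run.  Each
    run gets its own shuffle/training seed derived from ``seed`` unless
    ``identical_seeds`` is set (with ``mode="full"`` that reproduces the
    same model n_runs times, a correlation-1 sanity case).  Correlations
    are Spearman over the vectorized upper-triangle cosine distances on the
    vocabulary shared by all runs.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    persons = np.array(sorted(events["person_id"].unique()))
    rng = np.random.default_rng(seed)

    if mode == "disjoint":
        if fraction is None:
            fraction = 1.0 / n_runs
        if not 0 < fraction <= 1.0 / n_runs + 1e-12:
            raise ValueError("disjoint mode needs fraction in (0, 1/n_runs]")
        perm = rng.permutation(persons)
        size = max(1, int(round(fraction * len(persons))))
        subsets = [perm[i * size:(i + 1) * size] for i in range(n_runs)]
    elif mode == "bootstrap":
        if fraction is None:
            fraction = 1.0
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        size = max(1, int(round(fraction * len(persons))))
        subsets = [rng.choice(persons, size=size, replace=True) for _ in range(n_runs)]
    elif mode == "full":
        fraction = 1.0
        subsets = [persons.copy() for _ in range(n_runs)]
    else:
        raise ValueError(f"unknown mode: {mode!r}")

    matrices: list[EmbeddingMatrix] = []
    metadata: list[dict] = []
    for r, subset in enumerate(subsets):
        run_seed = int(seed) if identical_seeds else int(seed + 1000 * (r + 1))
        sub_events = events[events["person_id"].isin(set(subset.tolist()))]
        if sub_events.empty:
            raise ValueError(f"run {r}: subset contains no events")
        sentences, vocab = build_sentences(
            sub_events, min_count=config.min_count, seed=run_seed
        )
        emb = train_embeddings(sentences, vocab, config.replace(seed=run_seed))
        matrices.append(emb)
        metadata.append(
            {"run": r, "n_persons": int(len(subset)), "seed": run_seed,
             "fraction": float(fraction), "mode": mode,
             "vocabulary_size": len(vocab)}
        )

    shared = set(matrices[0].vocabulary.tokens)
    for m in matrices[1:]:
        shared &= set(m.vocabulary.tokens)
    shared_tokens = sorted(shared)
    if len(shared_tokens) < 3:
        raise ValueError(f"shared vocabulary too small: {len(shared_tokens)} terms")

    condensed = [_condensed_distances(m, shared_tokens) for m in matrices]
    corr = np.eye(n_runs)
    for i, j in itertools.combinations(range(n_runs), 2):
        rho = spearmanr(condensed[i], condensed[j]).statistic
        corr[i, j] = corr[j, i] = rho
    return StabilityReport(shared_tokens, corr, metadata)


def cross_model_agreement(emb_a: EmbeddingMatrix, emb_b: EmbeddingMatrix) -> float:
    """Spearman correlation of two embeddings' cosine-distance geometries.

    Computed over the vectorized upper-triangle distances on the vocabulary
    intersection; invariant to vocabulary ordering and per-vector scaling.
    """
    shared = sorted(set(emb_a.vocabulary.tokens) & set(emb_b.vocabulary.tokens))
    if len(shared) < 3:
        raise ValueError(f"vocabulary intersection too small: {len(shared)} terms")
    da = _condensed_distances(emb_a, shared)
    db = _condensed_distances(emb_b, shared)
    return float(spearmanr(da, db).statistic)
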