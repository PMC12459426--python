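"""End-to-end run: simulate -> sentences -> embed -> cluster -> network -> incidence.

One seeded call produces every TSV artifact of the analysis.  The run is
fully deterministic: simulation, within-year shuffling, skip-gram training
(single worker), clustering restarts and the projection all derive from the
given seeds, so two runs with identical inputs write byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .clustering import consensus_cluster, upgma_cluster
from .embedding import EmbeddingConfig, train_embeddings
from .incidence import incidence_rates, quantile_categorize
from .network import build_network, network_edges_frame
from .projection import project_2d
from .sequences import build_sentences, write_corpus
from .similarity import DistanceMatrix, closest_adversities, default_query_terms, knn
from .synthetic import CohortSpec, cohort_census, generate_cohort, write_events_tsv

__all__ = ["run_pipeline"]


def run_pipeline(
    spec: CohortSpec,
    config: EmbeddingConfig,
    outdir,
    k_clusters: int = 5,
    knn_k: int = 10,
    n_adversities: int = 3,
    period: tuple[int, int] = (2010, 2021),
) -> dict[str, Path]:
    """Run the full analysis on a synthetic cohort and write TSV outputs.

    Returns a name -> path map of the written artifacts (events, corpus,
    vocabulary, embeddings, clusters with consensus scores, network edge
    list, incidence table, 2D projection).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    events = generate_cohort(spec)
    paths["events"] = outdir / "events.tsv"
    write_events_tsv(events, paths["events"])

    sentences, vocab = build_sentences(events, min_count=config.min_count, seed=spec.seed)
    paths["corpus"] = outdir / "corpus.txt"
    write_corpus(sentences, paths["corpus"])
    paths["vocabulary"] = outdir / "vocabulary.tsv"
    vocab.write_tsv(paths["vocabulary"])

    emb = train_embeddings(sentences, vocab, config)
    paths["embeddings"] = outdir / "embeddings.tsv"
    emb.write_tsv(paths["embeddings"])

    query = default_query_terms()
    sleep_tokens = query.resolved_sleep_tokens(emb)
    adversities = [a for a, _, _ in closest_adversities(query, emb, m=n_adversities)]

    # selected-term set: sleep queries + their knn neighborhoods + adversities
    selected = sorted(
        set(sleep_tokens)
        | {n for t in sleep_tokens for n in knn(t, emb, k=knn_k).terms()}
        | set(adversities)
    )
    distance = DistanceMatrix.from_embeddings(emb, selected)
    assignment = upgma_cluster(distance, k=min(k_clusters, len(selected)))
    _, scores = consensus_cluster(
        emb.subset(selected), distance, k=assignment.k,
        reference=assignment, seed=spec.seed,
    )
    clusters = assignment.to_frame()
    clusters["consensus_score"] = clusters["term"].map(scores).round(6)
    paths["clusters"] = outdir / "clusters.tsv"
    clusters.to_csv(paths["clusters"], sep="\t", index=False)
    paths["dendrogram"] = outdir / "dendrogram.nwk"
    paths["dendrogram"].write_text(assignment.to_newick() + "\n")

    net = build_network(sorted(set(sleep_tokens) | set(adversities)), emb, k=knn_k)
    paths["network"] = outdir / "network_edges.tsv"
    network_edges_frame(net).round(6).to_csv(paths["network"], sep="\t", index=False)

    census = cohort_census(spec)
    ir = incidence_rates(events, census, selected, period=period)
    ir = quantile_categorize(ir)
    ir["ir_per_100k"] = ir["ir_per_100k"].round(4)
    paths["incidence"] = outdir / "incidence.tsv"
    ir.to_csv(paths["incidence"], sep="\t", index=False)

    proj = project_2d(emb, n_neighbors=min(20, len(emb) - 1), seed=spec.seed)
    paths["projection"] = outdir / "projection.tsv"
    frame = proj.to_frame(systems=vocab.systems)
    frame[["x", "y"]] = frame[["x", "y"]].round(6)
    frame.to_csv(paths["projection"], sep="\t", index=False)

    return paths
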