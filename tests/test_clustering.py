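"""UPGMA clustering, cluster-number diagnostics, consensus clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from lifecourse import (
    DistanceMatrix,
    cluster_number_diagnostics,
    consensus_cluster,
    consensus_from_assignments,
    upgma_cluster,
)
from lifecourse.clustering import hierarchical_cluster
from lifecourse.synthetic import planted_labels

# 5-point matrix with two well-separated blocks {A,B} and {C,D,E}.
# Hand-executed UPGMA trace:
#   merge (A,B) at 0.1 ; merge (C,D) at 0.2 ;
#   merge (CD,E) at mean(0.3, 0.4) = 0.35 ;
#   final merge at mean of the six cross distances (all 1.0) = 1.0.
BLOCK_TERMS = ["A", "B", "C", "D", "E"]
BLOCK_MATRIX = np.array(
    [
        [0.0, 0.1, 1.0, 1.0, 1.0],
        [0.1, 0.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.2, 0.3],
        [1.0, 1.0, 0.2, 0.0, 0.4],
        [1.0, 1.0, 0.3, 0.4, 0.0],
    ]
)
HAND_TRACE_HEIGHTS = [0.1, 0.2, 0.35, 1.0]


def block_distance():
    return DistanceMatrix(BLOCK_TERMS, BLOCK_MATRIX)


class TestUpgma:
    def test_k_equals_n_gives_singletons(self):
        assignment = upgma_cluster(block_distance(), k=5)
        assert assignment.k == 5

    def test_k_one_gives_single_cluster(self):
        assignment = upgma_cluster(block_distance(), k=1)
        assert assignment.k == 1

    def test_merge_heights_match_hand_executed_trace(self):
        assignment = upgma_cluster(block_distance(), k=2)
        heights = sorted(assignment.linkage_matrix[:, 2])
        assert heights == pytest.approx(HAND_TRACE_HEIGHTS)
        groups = assignment.as_dict()
        assert groups["A"] == groups["B"]
        assert groups["C"] == groups["D"] == groups["E"]
        assert groups["A"] != groups["C"]

    def test_merge_heights_non_decreasing_on_random_cosine_matrices(self, rng):
        for _ in range(5):
            x = rng.normal(size=(12, 4))
            xn = x / np.linalg.norm(x, axis=1, keepdims=True)
            d = 1 - xn @ xn.T
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix([f"t{i}" for i in range(12)], (d + d.T) / 2)
            heights = upgma_cluster(dm, k=3).linkage_matrix[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            upgma_cluster(block_distance(), k=6)

    def test_asymmetric_matrix_rejected(self):
        bad = BLOCK_MATRIX.copy()
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            DistanceMatrix(BLOCK_TERMS, bad)

    def test_newick_export_contains_all_terms(self):
        assignment = upgma_cluster(block_distance(), k=2)
        newick = assignment.to_newick()
        assert newick.endswith(";")
        for term in BLOCK_TERMS:
            assert term in newick


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(5)
    centers = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
    return np.vstack([c + rng.normal(scale=0.3, size=(20, 3)) for c in centers])


class TestDiagnostics:

    def test_silhouette_maximized_at_true_k(self, blobs):
        table = cluster_number_diagnostics(blobs, k_range=range(2, 7), n_ref=10, seed=0)
        best = table.loc[table["silhouette"].idxmax(), "k"]
        assert best == 3

    def test_all_indices_reported_per_k(self, blobs):
        table = cluster_number_diagnostics(blobs, k_range=range(2, 5), n_ref=5, seed=0)
        assert list(table.columns) == ["k", "calinski_harabasz", "silhouette", "gap_statistic"]
        assert table.notna().all().all()

    def test_k_bounds_respected(self, rng):
        x = rng.normal(size=(4, 3))
        cluster_number_diagnostics(x, k_range=[3], n_ref=3, seed=0)  # k = n-1 fine
        with pytest.raises(ValueError, match="outside"):
            cluster_number_diagnostics(x, k_range=[4], n_ref=3, seed=0)

    def test_gap_statistic_deterministic_under_seed(self, blobs):
        a = cluster_number_diagnostics(blobs, k_range=[3], n_ref=10, seed=1)
        b = cluster_number_diagnostics(blobs, k_range=[3], n_ref=10, seed=1)
        assert a["gap_statistic"].iloc[0] == b["gap_statistic"].iloc[0]

    def test_degenerate_identical_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cluster_number_diagnostics(np.ones((6, 3)), k_range=[2], seed=0)


class TestConsensus:
    def test_unanimous_methods_give_zero_one_frequencies(self):
        terms = list("abcdef")
        labels = np.array([1, 1, 1, 2, 2, 2])
        cm = consensus_from_assignments(terms, [labels, labels, labels + 5, 2 * labels])
        within = cm.values[np.ix_(range(3), range(3))]
        cross = cm.values[np.ix_(range(3), range(3, 6))]
        assert (within == 1).all()
        assert (cross == 0).all()

    def test_single_method_gives_co_membership_indicator(self):
        terms = list("abcd")
        labels = np.array([1, 2, 1, 2])
        cm = consensus_from_assignments(terms, [labels])
        expected = (labels[:, None] == labels[None, :]).astype(float)
        assert np.array_equal(cm.values, expected)

    def test_two_of_four_method_flip_gives_half(self):
        """A term assigned to one group by 2 of 4 methods and to the other by
        the remaining 2 has pairwise frequency exactly 0.5 with both groups."""
        terms = list("abcde")
        stay = np.array([1, 1, 1, 2, 2])
        flip = np.array([1, 1, 2, 2, 2])  # term 'c' switches group
        cm = consensus_from_assignments(terms, [stay, stay, flip, flip])
        c = terms.index("c")
        for other in [0, 1, 3, 4]:
            assert cm.values[c, other] == 0.5
        assert cm.values[0, 1] == 1.0
        assert cm.values[3, 4] == 1.0

    def test_invariant_to_label_permutation(self, rng):
        terms = [f"t{i}" for i in range(8)]
        labels = rng.integers(1, 4, size=8)
        relabeled = np.array([{1: 7, 2: 5, 3: 1}[v] for v in labels])
        a = consensus_from_assignments(terms, [labels])
        b = consensus_from_assignments(terms, [relabeled])
        assert np.array_equal(a.values, b.values)

    def test_consensus_matrix_bounds_and_diagonal(self, small_embedding):
        d = DistanceMatrix.from_embeddings(small_embedding)
        cm, scores = consensus_cluster(small_embedding.vectors, d, k=3, seed=0)
        assert np.allclose(np.diag(cm.values), 1.0)
        assert ((cm.values >= 0) & (cm.values <= 1)).all()
        assert np.allclose(cm.values, cm.values.T)
        assert scores.between(0, 1).all()

    def test_planted_communities_receive_higher_within_consensus(
        self, small_embedding, small_spec
    ):
        labels = planted_labels(small_spec)
        d = DistanceMatrix.from_embeddings(small_embedding)
        cm, _ = consensus_cluster(small_embedding.vectors, d, k=3, seed=0)
        lab = np.array([labels[t] for t in cm.terms])
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert cm.values[same & off].mean() > cm.values[~same].mean()

    def test_consensus_methods_recover_planted_partition(self, small_embedding, small_spec):
        labels = planted_labels(small_spec)
        d = DistanceMatrix.from_embeddings(small_embedding)
        assignment = upgma_cluster(d, k=3)
        truth = [labels[t] for t in assignment.terms]
        assert adjusted_rand_score(truth, assignment.labels) > 0.8

    def test_rarer_terms_get_lower_consensus_on_frequency_graded_communities(self):
        """With planted communities whose member frequencies are graded, rare
        terms co-cluster less stably across subsample-retrained embeddings;
        asserted as the sign of a rank correlation, not a fixed value."""
        from scipy.stats import spearmanr
        from sklearn.cluster import KMeans

        from lifecourse import EmbeddingConfig, build_sentences, generate_cohort, train_embeddings
        from lifecourse.synthetic import AGE_BANDS, CodeDef, CohortSpec, Community

        flat = tuple([1.0] * len(AGE_BANDS))
        scales = [32, 16, 8, 4, 1, 0.5, 0.25, 0.12]
        codes, comms = [], []
        for letter in "ABC":
            members = []
            for i, s in enumerate(scales):
                code = f"{letter}{i:03d}"
                codes.append(CodeDef(code, "diagnosis", tuple(s * w for w in flat)))
                members.append(code)
            comms.append(Community(tuple(members), 20.0))
        seed = 41
        spec = CohortSpec(
            n_individuals=600, birth_year_range=(1990, 2010),
            observation_end_year=2020, vocabulary=tuple(codes),
            communities=tuple(comms), background_rate=0.5, seed=seed,
        )
        events = generate_cohort(spec)
        persons = np.array(sorted(events["person_id"].unique()))
        rng = np.random.default_rng(seed)
        full_sents, full_vocab = build_sentences(events, min_count=2, seed=seed)
        counts = dict(zip(full_vocab.tokens, full_vocab.counts))

        embeddings, shared = [], set(full_vocab.tokens)
        for r in range(5):
            sub = set(rng.choice(persons, size=len(persons) // 2, replace=False).tolist())
            s, v = build_sentences(events[events["person_id"].isin(sub)], min_count=2, seed=seed + r)
            e = train_embeddings(s, v, EmbeddingConfig(dim=20, epochs=3, min_count=2, seed=seed + r))
            embeddings.append(e)
            shared &= set(v.tokens)
        shared = sorted(shared)
        assigns = []
        for e in embeddings:
            x = e.subset(shared)
            xn = x / np.linalg.norm(x, axis=1, keepdims=True)
            assigns.append(KMeans(n_clusters=3, n_init=10, random_state=0).fit(xn).labels_)
        cm = consensus_from_assignments(shared, assigns)
        emb_full = train_embeddings(full_sents, full_vocab,
                                    EmbeddingConfig(dim=20, epochs=3, min_count=2, seed=seed))
        ref = upgma_cluster(DistanceMatrix.from_embeddings(emb_full, shared), k=3)
        scores = cm.per_term_scores(ref)
        rho = spearmanr([counts[t] for t in scores.index], scores.values).statistic
        assert rho > 0

    def test_fewer_than_two_methods_rejected(self, small_embedding):
        d = DistanceMatrix.from_embeddings(small_embedding)
        with pytest.raises(ValueError, match="2 methods"):
            consensus_cluster(small_embedding.vectors, d, k=3, methods=("kmeans",))

    def test_single_linkage_chain_failure_excluded_with_warning(self):
        """A method constrained to k clusters that returns fewer is excluded."""
        terms = list("abcd")
        # equidistant points: single linkage maxclust cut may fail to split
        values = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(terms, values)
        x = np.eye(4)
        with pytest.warns(UserWarning, match="excluded"):
            cm, _ = consensus_cluster(x, d, k=3, methods=("single", "kmeans", "gmm"), seed=0)
        assert cm.n_methods <= 3
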