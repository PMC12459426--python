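# Methods

## Life-course sentences

An individual's register history is flattened into one token sequence.
Codes are first truncated to the granularity registers are analyzed at:
ICD-10 diagnoses to 4 significant characters (dots stripped, so
`G47.3` → `G473`), ATC medication codes to 5, SKS procedure codes to 6;
adversity indicators are opaque labels and pass through unchanged. Tokens
are ordered by calendar year; because within-year recording order in
registers reflects administrative delay rather than clinical sequence,
the tokens inside each (person, year) block are shuffled uniformly at
random (seeded). Shuffling happens once, at corpus construction.

Tokens whose corpus-wide count falls below `min_count` (default 20) are
removed *before* sentences are emitted, so no training context ever
contains a dropped token; this mirrors the vocabulary-pruning order of
standard word2vec pipelines. Persons left with no retained token produce
no sentence.

## Skip-gram embedding

The trainer is a from-scratch skip-gram model with hierarchical softmax:
a Huffman tree over token frequencies factorizes the output distribution,
and for each (center, context) pair within the window the context
vector's path through the center token's tree nodes is updated by
stochastic gradient descent on the cross-entropy loss. The inner loop is
numba-compiled, strictly sequential, and draws its window-size jitter
from an explicit xorshift stream, so training is bit-reproducible given
the seed (the single-worker contract). The *input-layer* vectors are the
embeddings.

Defaults: 200 dimensions, window 100 (wider than almost every sentence,
so context is effectively the whole life course), initial learning rate
0.05 with linear decay to 1e-4, 25 epochs, `min_count` 20. The effective
window per center token is dynamic (uniform on 1..window), the standard
skip-gram convention. The learning-rate schedule is the reference linear
decay rather than a per-parameter adaptive scheme; the cosine geometry
the pipeline consumes is insensitive to this choice, and the schedule is
exposed through `EmbeddingConfig`.

A second, count-based backend (`train_alternative_embeddings`) embeds the
same vocabulary for cross-algorithm robustness checks: symmetric
within-window co-occurrence counts → positive pointwise mutual
information → truncated SVD with rows scaled by √singular values, with a
deterministic sign convention. It shares `dim` and `window` with the
primary model and has no stochastic component.

## Similarity, clustering, network

Cosine similarity follows the usual dot-product-over-norms definition,
clipped to [−1, 1]; identical vectors return exactly 1, and zero-norm
vectors raise rather than returning 0. Nearest-neighbor queries are exact
searches with ties broken by vocabulary index. The adversities "most
closely associated" with sleep terms are ranked by their *maximum* cosine
similarity over the resolved sleep tokens (the arg-max sleep term is
reported); mean aggregation is available via the `aggregation` argument.
Query codes written `F51.x` expand to every vocabulary token with that
prefix; query terms missing from the vocabulary (e.g. filtered by
`min_count`) are reported through the warnings channel, never silently
dropped.

The primary grouping is UPGMA — average-linkage agglomerative clustering
on the cosine-distance matrix — cut into k = 5 flat clusters by default;
the diagnostics table (Calinski-Harabasz, silhouette with cosine metric,
gap statistic) is always computable alongside, and the cut remains a user
choice. The gap statistic uses B = 50 reference datasets drawn uniformly
in the bounding box of the L2-normalized vectors, seeded. K-means and
Gaussian-mixture steps run on L2-normalized embedding rows (Euclidean ≈
cosine geometry) with 10 seeded restarts; hierarchical methods run on the
distance matrix directly. Consensus clustering counts, over the method
set (single, complete, K-means, GMM by default, one assignment each),
the fraction of methods co-assigning each term pair; a method that fails
to produce k non-empty clusters is excluded with a warning. A term's
consensus score is its mean co-clustering frequency with the other
members of its reference (UPGMA) cluster.

The neighborhood network joins each seed term (sleep queries plus the
selected adversities) to its k nearest neighbors with cosine-weighted
edges; by default only seed-neighbor edges are drawn, with an optional
threshold rule adding any node pair above a similarity cutoff. Centrality
is plain degree, ties broken by label.

## 2D landscape

The projection is visualization-only; no downstream statistic consumes
the coordinates. The default backend is a deterministic PCA of the
L2-normalized embeddings (first two principal components, sign-fixed),
which preserves the community-level separation the tests assert; a
neighbor-based nonlinear backend (`method="umap"`, 20 neighbors, 450
optimization epochs, cosine metric, seeded) is available where a
landscape layout closer to manifold methods is wanted. The density
surface is a Gaussian KDE (Scott's-rule bandwidth by default) evaluated
on a padded grid; padding of 3 marginal standard deviations keeps the
captured mass within 1% of 1.

## Incidence and prevalence

Incidence is first-event incidence: a person is at risk for a term until
the calendar year of their first event of that term (inclusive) and is
counted once, in the 5-year age group of that year; `recurrent=True`
counts every event without exit. Age is event year minus birth year;
person-years accrue in whole-year increments at annual register
granularity. IR = events / person-years × 100,000 per (term, age group)
over the analysis period (2010–2021 default). Cells with zero
person-years are flagged undefined, not zero. Within each term the
defined IRs are mapped to q = 5 quantile categories by rank-then-bin
(category = ⌈q·rank/n⌉ with min-ranks), which is monotone, invariant
under strictly monotone IR transformations, and collapses ties to a
shared category. Prevalence trends divide yearly affected counts by
population denominators, per 1,000 persons or as a percentage.

## Stability diagnostics

Subsample stability retrains the full sentence→embedding pipeline on
person-level subsets — disjoint fifths by default ("distinct data
subsets"), bootstrap or full-cohort modes optional — each with its own
derived seed, then reports all pairwise Spearman correlations between the
runs' cosine-distance matrices, vectorized over the upper triangle on the
vocabulary shared by all runs. Cross-backend agreement is the same
statistic between the skip-gram and the count-based embedding. Identical
full-cohort runs with identical seeds correlate at exactly 1, a sanity
anchor the tests pin.

## The synthetic register simulator

The simulator emulates the features of register data the pipeline
exploits, with known ground truth. Per person: a birth year uniform on
1980–2015, observation through 2022 (ages 0–42, the study's span). Per
person-year: a Poisson number of events with rate `background_rate`
(default 0.6 events/person-year, register-plausible for combined
diagnosis + prescription + procedure streams) modulated by the
age-profile weight of the vocabulary in that 5-year age band; each
event's code is drawn proportionally to its age-profile weight.
Adversity codes are hard-zeroed at ages ≥ 16. *Communities* are planted
sets of codes: once a person has accrued any member of a community, other
members' sampling weights are multiplied by the community's boost
(default 20), producing the within-person co-occurrence structure that
skip-gram converts into geometric proximity.

The packaged 60-code default cohort has three equal communities — a
sleep community (the F51.x/G47.x/N05CH/N05CF/R06AD query codes,
sleep-adjacent procedures, psychiatric comorbidity codes, and the three
familial-dysfunction adversities), a cardiometabolic community with
material-deprivation adversities, and a musculoskeletal community with
loss-related adversities. What the simulator does **not** model:
mortality/emigration censoring beyond the fixed end year, sibling/parent
linkage microstructure (adversities are direct person-level events),
sub-annual timing, code frequency distributions of real registers
(marginals are order-of-magnitude choices, all configurable), or
prevalence drift over calendar time. Passing tests therefore demonstrate
that the pipeline recovers structure *of the kind planted*, at synthetic
scale — not that real register geometry would be equally clean.

## Problem sizes and numerical conventions

The reference conditions used by the acceptance script and the heaviest
tests are 5,000 persons × 60 codes × 3 communities at boost 20 with the
full embedding defaults (~75,000 events, ~1 minute of training on one
CPU); unit tests run reduced cohorts (200–800 persons, dim 16–50, 1–5
epochs), and the byte-level determinism check runs the end-to-end
pipeline twice at 800 persons / 5 epochs. Determinism everywhere rests
on seeded PCG64 streams (simulation, shuffling, subsampling), the
sequential jitted trainer with its explicit RNG, seeded scikit-learn
restarts, and deterministic sign conventions in both SVD-based
components. Distance matrices are symmetrized to tolerance 1e-10 and
validated against NaN before clustering; KMeans/GMM failures to produce
the requested k are excluded from consensus with a warning rather than
silently rescaled.

## Known limitations

* The skip-gram trainer is single-threaded by design (reproducibility
  over speed); vocabularies around 10⁴ terms train in hours, not
  minutes, at register scale.
* The alternative backend is a count-based factorization, not a
  gradient-trained model; cross-backend Spearman values are therefore
  indicative of geometry agreement across model *families*, not a
  benchmark of any specific second algorithm.
* PCA landscapes preserve community separation but compress nonlinear
  structure a neighbor-based projection would unfold; use the `umap`
  backend for presentation-grade landscapes.
* Aggregate prevalence inputs are taken as published (no survey
  reweighting); incidence assumes presence in the cohort for the whole
  period apart from first-event exit.
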