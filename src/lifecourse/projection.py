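"""2D landscape projection and kernel-density surface of the embeddings.

The projection is visualization-only: no downstream statistic depends on
the coordinates, only topology-level properties (planted communities stay
closer to their own members than to other communities' members) are
asserted.  The default backend is a deterministic PCA of the L2-normalized
(cosine-geometry) embeddings; a neighbor-based manifold backend ("umap")
is available where a nonlinear layout is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .embedding import EmbeddingMatrix
from .similarity import QueryTermSet

__all__ = ["Projection2D", "project_2d", "landscape_density", "highlight_terms"]


@dataclass
class Projection2D:
    """Per-term 2D coordinates plus the projection metadata."""

    terms: list[str]
    coords: np.ndarray  # (n, 2)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.terms), 2):
            raise ValueError("coords must be (n_terms, 2)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite projection coordinates")
        self._index = {t: i for i, t in enumerate(self.terms)}

    def coordinate(self, term: str) -> np.ndarray:
        return self.coords[self._index[term]]

    def to_frame(self, systems: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"term": self.terms, "x": self.coords[:, 0], "y": self.coords[:, 1]}
        )
        if systems is not None:
            df["system"] = systems
        return df


def project_2d(
    matrix: EmbeddingMatrix,
    n_neighbors: int = 20,
    iterations: int = 450,
    metric: str = "cosine",
    seed: int = 0,
    method: str = "pca",
) -> Projection2D:
    """Project the embedding matrix to two dimensions.

    ``method="pca"`` (default): first two principal components of the
    mean-centered vectors — after row L2-normalization when
    ``metric="cosine"`` — with a deterministic sign convention.
    ``method="umap"``: neighbor-based nonlinear layout using ``n_neighbors``,
    ``iterations`` optimization epochs and the given metric, seeded.
    """
    n = len(matrix)
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} terms, have {n}")
    x = np.asarray(matrix.vectors, dtype=float)
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("zero-norm embedding row")
        x = x / norms

    if method == "pca":
        centered = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        coords = u[:, :2] * s[:2]
        for j in range(2):
            i_max = np.abs(coords[:, j]).argmax()
            if coords[i_max, j] < 0:
                coords[:, j] = -coords[:, j]
    elif method == "umap":
        import umap  # optional backend

        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            n_epochs=iterations,
            metric=metric,
            random_state=seed,
        )
        coords = np.asarray(reducer.fit_transform(matrix.vectors), dtype=float)
    else:
        raise ValueError(f"unknown projection method: {method!r}")

    return Projection2D(
        list(matrix.vocabulary.tokens),
        coords,
        metadata={
            "method": method,
            "n_neighbors": n_neighbors,
            "iterations": iterations,
            "metric": metric,
            "seed": seed,
        },
    )


def landscape_density(
    proj: Projection2D,
    grid: int = 100,
    bandwidth: str | float = "scott",
    padding: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian KDE surface of the projected landscape.

    Returns (x_grid, y_grid, density) with density evaluated on a
    ``grid`` x ``grid`` lattice covering the padded bounding box; the
    surface is non-negative and integrates to ~1 over the plane (the grid
    captures almost all mass when the padding is generous).
    """
    pts = proj.coords
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for a density")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("zero-variance coordinates: density undefined")
    try:
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate point configuration: {exc}") from exc
    span = pts.max(axis=0) - pts.min(axis=0)
    pad = padding * np.where(span > 0, span, 1.0) + 3.0 * pts.std(axis=0)
    xs = np.linspace(pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0], grid)
    ys = np.linspace(pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1], grid)
    xx, yy = np.meshgrid(xs, ys)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid, grid)
    return xs, ys, density


def highlight_terms(proj: Projection2D, query: QueryTermSet, matrix: EmbeddingMatrix):
    """Overlay coordinates for the resolvable query terms.

    Returns (overlay DataFrame with term/label/x/y, list of missing terms).
    """
    resolved, missing = query.resolve(matrix)
    proj_terms = set(proj.terms)
    rows = []
    for token, label in resolved.items():
        if token in proj_terms:
            x, y = proj.coordinate(token)
            rows.append((token, label, x, y))
        else:
            missing.append(f"{label} ({token}: not projected)")
    for adv in query.adversity_terms:
        if adv in proj_terms and adv in matrix.vocabulary:
            x, y = proj.coordinate(adv)
            rows.append((adv, "adversity", x, y))
    overlay = pd.DataFrame(rows, columns=["term", "label", "x", "y"])
    return overlay, missing
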