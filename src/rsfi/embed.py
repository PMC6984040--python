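"""2-D embedding diagnostics (t-SNE, Isomap) and cluster-metadata checks.

The embeddings are exploratory: they reveal whether feature vectors fall
into apparent clusters, and the association test then asks whether such
clusters line up with group labels or demographics (age, sex, hearing
status) -- or are structure of another origin entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE, Isomap


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n_samples, 2)
    method: str
    params: dict
    sample_ids: list = field(default_factory=list)
    cluster_assignments: np.ndarray | None = None
    association: pd.DataFrame | None = None


def embed_2d(
    vectors: np.ndarray,
    method: str = "tsne",
    perplexity: float = 30.0,
    n_neighbors: int = 10,
    seed: int = 0,
    sample_ids=None,
) -> EmbeddingResult:
    """Map feature vectors to 2-D with t-SNE or Isomap (seeded)."""
    X = np.asarray(vectors, dtype=float)
    n = X.shape[0]
    if n < 5:
        raise ValueError("need at least 5 samples to embed")
    if method == "tsne":
        limit = n / 3.0
        if not 0 < perplexity < limit:
            raise ValueError(
                f"perplexity must lie in (0, n_samples/3) = (0, {limit:.1f})"
            )
        model = TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        )
        coords = model.fit_transform(X)
        params = {"perplexity": perplexity, "seed": seed}
    elif method == "isomap":
        k = min(n_neighbors, n - 1)
        coords = Isomap(n_components=2, n_neighbors=k).fit_transform(X)
        params = {"n_neighbors": k, "seed": seed}
    else:
        raise ValueError("method must be 'tsne' or 'isomap'")
    return EmbeddingResult(
        np.asarray(coords, dtype=float), method, params,
        list(sample_ids) if sample_ids is not None else list(range(n)),
    )


def _is_categorical(values: pd.Series) -> bool:
    if values.dtype == object or values.dtype == bool:
        return True
    return values.nunique() <= max(2, int(np.sqrt(len(values))) // 2)


def cluster_and_associate(
    result: EmbeddingResult, metadata: pd.DataFrame, seed: int = 0
) -> EmbeddingResult:
    """2-means on the embedded coordinates, then per-field association.

    Categorical metadata are tested against the cluster label with a
    chi-squared contingency test, continuous metadata with a two-sided
    Mann-Whitney U across clusters; p values are Bonferroni-adjusted over
    the tested fields. Constant fields are skipped with a warning.
    """
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    clusters = km.fit_predict(result.coords)
    rows = []
    for col in metadata.columns:
        values = metadata[col]
        if values.nunique(dropna=True) < 2:
            warnings.warn(f"metadata field {col!r} is constant: skipped",
                          stacklevel=2)
            continue
        if _is_categorical(values):
            table = pd.crosstab(clusters, values)
            chi2, p, _, _ = stats.chi2_contingency(table)
            rows.append({"field": col, "test": "chi2", "statistic": float(chi2),
                         "p": float(p)})
        else:
            a = values[clusters == 0].to_numpy(dtype=float)
            b = values[clusters == 1].to_numpy(dtype=float)
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"field": col, "test": "mannwhitneyu",
                         "statistic": float(u), "p": float(p)})
    if not rows:
        raise ValueError("no testable metadata fields")
    table = pd.DataFrame(rows)
    table["p_adj"] = np.minimum(1.0, table["p"] * len(table))
    result.cluster_assignments = clusters
    result.association = table
    return result


def plot_embedding(result: EmbeddingResult, path, color_by=None) -> None:
    """Optional scatter-plot export (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    c = None
    if color_by is not None:
        uniq = sorted(set(color_by))
        c = [uniq.index(v) for v in color_by]
    ax.scatter(result.coords[:, 0], result.coords[:, 1], c=c, cmap="coolwarm", s=18)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title(f"{result.method} embedding")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
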