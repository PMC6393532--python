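"""Sample landscape: embedding ensemble, density clustering, consensus.

An ensemble of 2-D t-SNE embeddings of the samples is computed (each run
differently seeded but reproducible from one master seed), each embedding
is clustered with HDBSCAN, and the per-run labelings are combined through
a co-association matrix: entry (i, j) is the fraction of runs in which
samples i and j share a non-noise cluster.  Consensus clusters come from
average-linkage hierarchical clustering of 1 - co-association, cut at
the number of clusters maximizing the mean silhouette; clusters below
the minimum size dissolve to "unassigned".  Finally each consensus
cluster is tested for enrichment of every sample-attribute value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import HDBSCAN
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .enrichment import SampleAnnotations

__all__ = [
    "ConsensusClustering",
    "embed_ensemble",
    "density_cluster",
    "consensus_clusters",
    "cluster_attribute_enrichment",
]

UNASSIGNED = -1


@dataclass
class ConsensusClustering:
    """Consensus labels plus the co-association evidence behind them.

    ``labels`` is indexed by sample ID; -1 means unassigned.
    ``co_association`` is symmetric with unit diagonal.
    """

    labels: pd.Series
    co_association: np.ndarray
    n_runs: int
    min_cluster_size: int

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in self.labels.unique() if c != UNASSIGNED)


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_runs) % 2**31


def embed_ensemble(
    gem: pd.DataFrame,
    n_runs: int = 1000,
    perplexity: float = 30.0,
    seed: int = 0,
    top_n_variance: int | None = None,
) -> list[np.ndarray]:
    """t-SNE the samples ``n_runs`` times with derived per-run seeds.

    Samples are the points (the GEM is transposed); an optional
    top-N-by-variance gene filter can shrink the input.  Requires
    ``n_samples > 3 * perplexity``.
    """
    n_samples = gem.shape[1]
    if n_samples <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n_samples} samples "
            f"(need n_samples > 3*perplexity)"
        )
    x = gem.to_numpy(dtype=float).T
    x = np.nan_to_num(x, nan=0.0)
    if top_n_variance is not None and top_n_variance < gem.shape[0]:
        keep = np.argsort(x.var(axis=0))[::-1][:top_n_variance]
        x = x[:, keep]
    out = []
    for run_seed in _run_seeds(seed, n_runs):
        # random (seeded) init: the ensemble needs run-to-run variation,
        # which a deterministic PCA init would suppress
        ts = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=int(run_seed),
            init="random",
        )
        out.append(ts.fit_transform(x))
    return out


def density_cluster(embedding: np.ndarray, min_cluster_size: int = 10) -> np.ndarray:
    """HDBSCAN labels for one 2-D embedding; -1 marks noise points."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.shape[0] < 2 * min_cluster_size:
        raise ValueError("too few points for density clustering")
    if np.allclose(embedding, embedding[0]):
        return np.zeros(embedding.shape[0], dtype=int)  # degenerate: one cluster
    return HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(embedding)


def consensus_clusters(
    label_matrix: np.ndarray,
    sample_ids: list[str],
    min_cluster_size: int = 10,
    max_clusters: int = 10,
) -> ConsensusClustering:
    """Consensus from a runs x samples label matrix.

    Noise labels (-1) never co-associate.  The co-association matrix is
    clustered by average linkage on 1 - co-association; candidate cluster
    counts 2..max_clusters are scored by mean silhouette (precomputed
    distances) and the best is kept, then clusters below
    ``min_cluster_size`` dissolve to unassigned.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    labels = np.asarray(label_matrix)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("need a runs x samples matrix with >= 2 runs")
    n_runs, n_samples = labels.shape
    if n_samples != len(sample_ids):
        raise ValueError("sample_ids length mismatch")
    co = np.zeros((n_samples, n_samples))
    for r in range(n_runs):
        lab = labels[r]
        ok = lab != UNASSIGNED
        same = (lab[:, None] == lab[None, :]) & ok[:, None] & ok[None, :]
        co += same
    co /= n_runs
    np.fill_diagonal(co, 1.0)

    if not np.any(labels != UNASSIGNED):
        warnings.warn("all runs produced only noise; no consensus clusters",
                      RuntimeWarning, stacklevel=2)
        out = pd.Series(UNASSIGNED, index=pd.Index(sample_ids, name="sample_id"))
        return ConsensusClustering(out, co, n_runs, min_cluster_size)

    dist = 1.0 - co
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if np.allclose(dist, 0.0):
        assigned = np.zeros(n_samples, dtype=int)  # unanimous single cluster
    else:
        z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        best = None
        for k in range(2, min(max_clusters, n_samples - 1) + 1):
            cand = hierarchy.fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(cand)) < 2:
                continue
            score = silhouette_score(dist, cand, metric="precomputed")
            if best is None or score > best[0]:
                best = (score, cand)
        assigned = (best[1] if best is not None else np.ones(n_samples, dtype=int)) - 0
    # dissolve small clusters, relabel 1..K by decreasing size
    final = np.full(n_samples, UNASSIGNED, dtype=int)
    ids, counts = np.unique(assigned, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    next_id = 1
    for pos in order:
        if counts[pos] >= min_cluster_size:
            final[assigned == ids[pos]] = next_id
            next_id += 1
    out = pd.Series(final, index=pd.Index(sample_ids, name="sample_id"))
    return ConsensusClustering(out, co, n_runs, min_cluster_size)


def cluster_attribute_enrichment(
    cc: ConsensusClustering, ann: SampleAnnotations
) -> pd.DataFrame:
    """Fisher enrichment of every attribute value in every consensus cluster.

    One-sided (enrichment) tests on [in cluster vs not] x [has value vs
    not] over all samples, Benjamini-Hochberg adjusted jointly across the
    whole (cluster x attribute value) family.  Attribute values constant
    across samples yield p = 1 and are flagged degenerate.
    """
    ann = ann.reindex(list(cc.labels.index))
    rows = []
    n = len(cc.labels)
    for cluster in cc.cluster_ids:
        in_cluster = (cc.labels == cluster).to_numpy()
        for col in ann.attributes.columns:
            series = ann.attributes[col].astype(str)
            for val in pd.unique(series.dropna()):
                has = (series == val).to_numpy()
                n_has = int(has.sum())
                degenerate = n_has in (0, n)
                if degenerate:
                    p = 1.0
                else:
                    overlap = int((in_cluster & has).sum())
                    p = float(stats.hypergeom.sf(
                        overlap - 1, n, n_has, int(in_cluster.sum())
                    ))
                rows.append(
                    {
                        "cluster": cluster,
                        "attribute": col,
                        "value": val,
                        "n_cluster": int(in_cluster.sum()),
                        "n_value": n_has,
                        "n_overlap": int((in_cluster & has).sum()),
                        "n_samples": n,
                        "p": min(p, 1.0),
                        "degenerate": degenerate,
                    }
                )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
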