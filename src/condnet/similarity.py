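"""Pairwise similarity with Gaussian-mixture sample clustering.

For every gene pair the 2-D expression scatter across samples is
decomposed into sample clusters by bivariate Gaussian mixtures (model
selection by ICL over 1..max_modes components); each sufficiently large
cluster is then scored with a Spearman correlation computed over *its*
samples only.  A pair may therefore emit several candidate edges, each
carrying the mask of supporting samples — the basis of all downstream
condition annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._em import fit_gmm, icl_score

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityConfig",
    "PairCluster",
    "pair_points",
    "fit_gmm_icl",
    "score_clusters",
    "similarity_scan",
    "n_pairs",
    "mask_to_rle",
    "rle_to_mask",
    "write_pair_clusters",
    "read_pair_clusters",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Knobs of the pair sweep.

    ``min_obs``: minimum pairwise-complete observations for a pair to be
    evaluated at all; ``min_csize``: minimum cluster size for a cluster
    to be scored; ``max_modes``: largest mixture size tried;
    ``prefilter_threshold``: |rho| floor for retaining a cluster (0 keeps
    everything, deferring the cut to thresholding); ``n_restarts``:
    seeded EM restarts per component count.
    """

    min_obs: int = 30
    min_csize: int = 30
    max_modes: int = 5
    prefilter_threshold: float = 0.0
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.min_csize < 3:
            raise ValueError("min_csize must be >= 3")
        if not 1 <= self.max_modes <= 10:
            raise ValueError("max_modes must be in 1..10")


@dataclass
class PairCluster:
    """One sample cluster of one gene pair: a candidate edge.

    ``gene_a < gene_b`` in the GEM's gene order (canonical).  ``mask`` is
    a boolean vector over the full sample universe; ``n`` its popcount;
    ``rho`` the Spearman correlation over the masked samples.
    """

    gene_a: str
    gene_b: str
    cluster_index: int
    mask: np.ndarray
    rho: float

    @property
    def n(self) -> int:
        return int(self.mask.sum())

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def n_pairs(n_genes: int) -> int:
    return n_genes * (n_genes - 1) // 2


def pair_points(
    gem: pd.DataFrame, gene_a: str, gene_b: str, min_obs: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-complete 2-D points for one gene pair.

    Returns ``(points, sample_idx)`` where ``sample_idx`` are positions
    in the GEM's column order.  Empty arrays if fewer than ``min_obs``
    complete observations (the pair is skipped).
    """
    for g in (gene_a, gene_b):
        if g not in gem.index:
            raise KeyError(f"unknown gene: {g!r}")
    x = gem.loc[gene_a].to_numpy(dtype=float)
    y = gem.loc[gene_b].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if int(ok.sum()) < min_obs:
        return np.empty((0, 2)), np.empty(0, dtype=np.intp)
    idx = np.flatnonzero(ok)
    return np.column_stack([x[idx], y[idx]]), idx


def fit_gmm_icl(
    points: np.ndarray,
    max_modes: int = 5,
    seed: int = 0,
    n_restarts: int = 3,
) -> tuple[np.ndarray, int]:
    """Cluster the 2-D points; choose the component count by ICL.

    For each k in 1..max_modes a full-covariance bivariate mixture is fit
    (best of ``n_restarts`` seeded k-means++-initialized EM runs); the k
    minimizing ICL = BIC + 2*entropy wins.  Hard labels are maximum
    posterior responsibility (ties toward the lower cluster index).
    Covariances carry a small diagonal ridge, so collinear or otherwise
    degenerate point sets fit without failure.
    """
    n = points.shape[0]
    best_icl = np.inf
    best_labels = np.zeros(n, dtype=np.intp)
    best_k = 1
    for k in range(1, max_modes + 1):
        ll, w, mu, cov, resp = fit_gmm(points, k, seed=seed + 101 * k,
                                       n_restarts=n_restarts)
        if not np.isfinite(ll):
            continue
        icl = icl_score(ll, resp, n, k)
        if icl < best_icl:
            best_icl = icl
            best_labels = np.argmax(resp, axis=1)
            best_k = k
    if not np.isfinite(best_icl):
        logger.warning("all mixture fits failed; falling back to one cluster")
        return np.zeros(n, dtype=np.intp), 1
    # relabel clusters to dense 0..k'-1 in order of first appearance
    uniq, labels = np.unique(best_labels, return_inverse=True)
    return labels, int(uniq.size) if uniq.size else best_k


def score_clusters(
    points: np.ndarray,
    labels: np.ndarray,
    sample_idx: np.ndarray,
    n_samples: int,
    gene_a: str,
    gene_b: str,
    config: SimilarityConfig,
) -> list[PairCluster]:
    """Spearman-score each cluster of one pair; keep the qualifying ones.

    Clusters below ``min_csize`` points are dropped; so are clusters
    where either gene is constant within the cluster (rank correlation
    undefined) and clusters with ``|rho|`` below the prefilter threshold.
    """
    out: list[PairCluster] = []
    emitted = 0
    for lbl in np.unique(labels):
        sel = labels == lbl
        if int(sel.sum()) < config.min_csize:
            continue
        xs = points[sel, 0]
        ys = points[sel, 1]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            logger.debug("constant gene within cluster of (%s,%s); dropped",
                         gene_a, gene_b)
            continue
        rho = stats.spearmanr(xs, ys).statistic
        if not np.isfinite(rho):
            continue
        if abs(rho) < config.prefilter_threshold:
            continue
        mask = np.zeros(n_samples, dtype=bool)
        mask[sample_idx[sel]] = True
        out.append(PairCluster(gene_a, gene_b, emitted, mask, float(rho)))
        emitted += 1
    return out


def _pair_seed(base_seed: int, pair_index: int) -> int:
    # stable per-pair seed, independent of sharding
    return int(np.random.SeedSequence((base_seed, pair_index)).generate_state(1)[0]
               % 2**31)


def similarity_scan(
    gem: pd.DataFrame,
    config: SimilarityConfig | None = None,
    pair_range: tuple[int, int] | None = None,
    progress: bool = False,
) -> list[PairCluster]:
    """Run the GMM+Spearman stage over all gene pairs.

    Pairs are enumerated lexicographically on gene index; ``pair_range``
    restricts to linear pair indices ``[lo, hi)`` so the sweep can be
    sharded — per-pair seeds depend only on the global seed and the pair
    index, so sharded and unsharded runs produce identical results.
    """
    config = config or SimilarityConfig()
    genes = list(gem.index)
    total = n_pairs(len(genes))
    lo, hi = pair_range if pair_range is not None else (0, total)
    if not (0 <= lo <= hi <= total):
        raise ValueError(f"pair_range out of bounds for {total} pairs")
    values = gem.to_numpy(dtype=float)
    n_samples = gem.shape[1]
    results: list[PairCluster] = []
    p = 0
    for i in range(len(genes)):
        if p >= hi:
            break
        row_pairs = len(genes) - i - 1
        if p + row_pairs <= lo:
            p += row_pairs
            continue
        xi = values[i]
        for j in range(i + 1, len(genes)):
            if p >= hi:
                break
            if p < lo:
                p += 1
                continue
            ok = np.isfinite(xi) & np.isfinite(values[j])
            if int(ok.sum()) >= config.min_obs:
                idx = np.flatnonzero(ok)
                pts = np.column_stack([xi[idx], values[j][idx]])
                labels, _k = fit_gmm_icl(
                    pts, config.max_modes, seed=_pair_seed(config.seed, p),
                    n_restarts=config.n_restarts,
                )
                results.extend(
                    score_clusters(pts, labels, idx, n_samples,
                                   genes[i], genes[j], config)
                )
            p += 1
        if progress and (i + 1) % 25 == 0:
            logger.info("similarity_scan: gene %d/%d, %d candidate edges",
                        i + 1, len(genes), len(results))
    return results


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a 0/1 mask as e.g. ``"5x0,3x1,2x0"``."""
    bits = np.asarray(mask, dtype=np.int8)
    if bits.size == 0:
        return ""
    change = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [bits.size]])
    return ",".join(f"{e - s}x{bits[s]}" for s, e in zip(starts, ends))


def rle_to_mask(rle: str) -> np.ndarray:
    if not rle:
        return np.zeros(0, dtype=bool)
    parts = []
    for tok in rle.split(","):
        count, bit = tok.split("x")
        parts.append(np.full(int(count), bit == "1"))
    return np.concatenate(parts)


def write_pair_clusters(pairs: list[PairCluster], path) -> None:
    rows = [
        {
            "gene_a": pc.gene_a,
            "gene_b": pc.gene_b,
            "cluster_index": pc.cluster_index,
            "n": pc.n,
            "rho": f"{pc.rho:.10g}",
            "mask": mask_to_rle(pc.mask),
        }
        for pc in pairs
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "cluster_index",
                                "n", "rho", "mask"]).to_csv(
        path, sep="\t", index=False
    )


def read_pair_clusters(path) -> list[PairCluster]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        PairCluster(r.gene_a, r.gene_b, int(r.cluster_index),
                    rle_to_mask(r.mask), float(r.rho))
        for r in df.itertuples()
    ]
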