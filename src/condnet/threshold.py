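"""Random-matrix-theory network thresholding and topology statistics.

The significance cutoff tau for |Spearman rho| is chosen by scanning
downward from a high starting value and testing, at each tau, whether the
nearest-neighbour spacing distribution (NNSD) of the thresholded
similarity matrix's unfolded eigenvalues still follows the Poisson law
``e^(-s)`` (modular, signal-like spectra) rather than the GOE/Wigner law
(noise; level repulsion).  The scan stops at the first tau whose NNSD
chi-square against Poisson exceeds the critical value; the chosen tau is
the last accepted one, optionally refined at a tenth of the step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .similarity import PairCluster

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdScan",
    "NetworkStats",
    "ConditionNetwork",
    "build_matrix",
    "unfolded_spacings",
    "spacings_chi2",
    "nnsd_chi2",
    "find_threshold",
    "extract_network",
    "topology_stats",
    "default_chi2_crit",
]

N_BINS = 60
S_MAX = 3.0
MIN_EIGENVALUES = 50


@dataclass
class ConditionNetwork:
    """Thresholded edge set with (optional) per-condition p-values.

    ``edges`` are the surviving :class:`PairCluster` objects, each still
    carrying its supporting-sample mask.  ``pvalues``/``adj_pvalues`` are
    edge x condition DataFrames filled in by the enrichment stage.
    """

    edges: list[PairCluster]
    sample_ids: list[str]
    tau: float
    pvalues: pd.DataFrame | None = None
    adj_pvalues: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.gene_a)
            seen.setdefault(e.gene_b)
        return list(seen)

    def simple_graph(self) -> nx.Graph:
        """Underlying simple graph (parallel condition-edges collapsed)."""
        g = nx.Graph()
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b)
        return g


@dataclass
class ThresholdScan:
    tau_grid: list[float] = field(default_factory=list)
    sizes: list[int] = field(default_factory=list)
    n_unique: list[int] = field(default_factory=list)
    chi2: list[float] = field(default_factory=list)
    chosen_tau: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"tau": self.tau_grid, "size": self.sizes,
             "n_unique_eigenvalues": self.n_unique, "chi2": self.chi2}
        )


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    scale_free_r2: float | None


def default_chi2_crit(alpha: float = 0.001, df: int = N_BINS - 1) -> float:
    return float(stats.chi2.ppf(1.0 - alpha, df))


def build_matrix(
    pairs: list[PairCluster], tau: float
) -> tuple[np.ndarray, list[str]]:
    """Thresholded similarity matrix at |rho| >= tau.

    Entry (a, b) is the signed rho of the pair's strongest cluster (max
    |rho|) when that magnitude reaches tau, else 0.  Genes with no
    surviving entry are dropped; the diagonal is 0.  Returns the matrix
    and its gene order.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    best: dict[tuple[str, str], float] = {}
    for pc in pairs:
        cur = best.get(pc.key)
        if cur is None or abs(pc.rho) > abs(cur):
            best[pc.key] = pc.rho
    surviving = {k: r for k, r in best.items() if abs(r) >= tau}
    genes: dict[str, int] = {}
    for a, b in surviving:
        genes.setdefault(a, len(genes))
        genes.setdefault(b, len(genes))
    m = np.zeros((len(genes), len(genes)))
    for (a, b), r in surviving.items():
        i, j = genes[a], genes[b]
        m[i, j] = m[j, i] = r
    return m, list(genes)


def _unique_within_tol(values: np.ndarray, tol: float) -> np.ndarray:
    """Deduplicate a sorted array, keeping one value per tol-cluster."""
    if values.size == 0:
        return values
    keep = [values[0]]
    for v in values[1:]:
        if v - keep[-1] > tol:
            keep.append(v)
    return np.asarray(keep)


def unfolded_spacings(
    matrix: np.ndarray,
    dedup_tol: float = 1e-8,
    spline_stride: int = 5,
    min_unique: int = MIN_EIGENVALUES,
) -> np.ndarray | None:
    """Eigenvalue spacings after spectrum unfolding; mean forced to 1.

    Eigenvalues are deduplicated (tolerance ``dedup_tol``), the cumulative
    spectral function is smoothed by a monotone cubic through every
    ``spline_stride``-th point, the eigenvalues are mapped through it, and
    consecutive differences are rescaled to unit mean.  Returns ``None``
    when fewer than ``min_unique`` unique eigenvalues exist (insufficient
    spectrum).

    The knot stride trades smoothing against fidelity of the unfolding:
    a sparse stride is fine for spectra of many hundreds of eigenvalues
    but badly underfits the cumulative spectral function of the ~50-150
    eigenvalue matrices a compact network produces, inflating the
    chi-square; every 5th point keeps >= 10 knots at the minimum usable
    spectrum size.
    """
    ev = np.sort(np.linalg.eigvalsh(matrix))
    ev = _unique_within_tol(ev, dedup_tol)
    if ev.size < min_unique:
        return None
    n = ev.size
    cdf = np.arange(1, n + 1) / n
    knots = np.arange(0, n, spline_stride)
    if knots[-1] != n - 1:
        knots = np.append(knots, n - 1)
    # monotone cubic keeps the unfolded spectrum ordered
    spline = interpolate.PchipInterpolator(ev[knots], cdf[knots])
    unfolded = n * spline(ev)
    s = np.diff(unfolded)
    s = s[np.isfinite(s)]
    s = s[s >= 0]
    mean = s.mean()
    if mean <= 0:
        return None
    return s / mean


def spacings_chi2(spacings: np.ndarray, n_bins: int = N_BINS,
                  s_max: float = S_MAX) -> float:
    """Chi-square of observed spacings against the Poisson NNSD e^(-s).

    Spacings are histogrammed over [0, s_max] in ``n_bins`` bins with
    values beyond ``s_max`` pooled into the last bin; expected counts come
    from the exponential law (with the tail mass folded into the last
    bin).
    """
    s = np.asarray(spacings, dtype=float)
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.minimum(s, s_max - 1e-12), bins=edges)
    probs = np.exp(-edges[:-1]) - np.exp(-edges[1:])
    probs[-1] += np.exp(-s_max)
    exp = probs * s.size
    return float(np.sum((obs - exp) ** 2 / exp))


def nnsd_chi2(matrix: np.ndarray, **kwargs) -> float | None:
    """NNSD chi-square vs Poisson for one thresholded matrix.

    ``None`` signals an insufficient spectrum.
    """
    s = unfolded_spacings(matrix, **kwargs)
    if s is None:
        return None
    return spacings_chi2(s)


def find_threshold(
    pairs: list[PairCluster],
    start: float = 0.95,
    step: float = 0.001,
    chi2_crit: float | None = None,
    stop: float = 0.82,
    persistence: float = 0.025,
    refine: bool = True,
) -> ThresholdScan:
    """Scan tau downward until the NNSD turns GOE-like; keep the last
    Poisson-consistent tau.

    At each tau (``start``, ``start - step``, ...) with a sufficient
    spectrum the NNSD chi-square against Poisson is computed.  The scan
    stops at the Poisson-to-GOE crossing: the first point where the
    chi-square exceeds ``chi2_crit`` *and stays above it* for a tau
    interval of width ``persistence`` — small matrices show transient
    finite-size chi-square excursions that a bare first-exceedance rule
    would mistake for the transition, whereas the true noise transition
    persists for the rest of the scan.  ``chosen_tau`` is the smallest
    accepted tau before the crossing.  If no crossing occurs above
    ``stop`` the last accepted tau is chosen: a compact network may stay
    modular (Poisson) over the whole scanned range, so ``stop`` bounds
    how weak a correlation is ever admitted as an edge.  Its default
    sits where, in a matched null cohort, fewer than 0.1% of gene pairs
    produce a qualifying sample cluster — below that the spectrum stops
    discriminating and edges become chance clusters.  With ``refine`` a second
    pass at ``step / 10`` between the chosen tau and the crossing
    sharpens the estimate.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if chi2_crit is None:
        chi2_crit = default_chi2_crit()

    def _scan(tau0: float, tau_stop: float, dtau: float, scan: ThresholdScan):
        need = max(1, int(round(persistence / dtau)))
        last_ok = None
        run_start = None
        run_len = 0
        tau = tau0
        while tau >= tau_stop - 1e-12:
            m, genes = build_matrix(pairs, tau)
            chi2 = nnsd_chi2(m) if len(genes) else None
            scan.tau_grid.append(round(tau, 10))
            scan.sizes.append(len(genes))
            if chi2 is None:
                scan.n_unique.append(0)
                scan.chi2.append(np.nan)
            else:
                scan.n_unique.append(len(genes))
                scan.chi2.append(chi2)
                if chi2 <= chi2_crit:
                    last_ok = tau
                    run_start = None
                    run_len = 0
                else:
                    if run_start is None:
                        run_start = tau
                    run_len += 1
                    if run_len >= need and last_ok is not None:
                        return last_ok, run_start
            tau -= dtau
        return last_ok, None

    scan = ThresholdScan()
    chosen, crossing = _scan(start, stop, step, scan)
    if chosen is None:
        raise RuntimeError(
            "no tau with a sufficient, Poisson-consistent spectrum; "
            "try a smaller start or more candidate pairs"
        )
    if refine and crossing is not None and step > 1e-4:
        fine_chosen, _ = _scan(chosen, crossing, step / 10.0, scan)
        if fine_chosen is not None:
            chosen = fine_chosen
    scan.chosen_tau = round(float(chosen), 10)
    return scan


def extract_network(
    pairs: list[PairCluster], tau: float, sample_ids: list[str]
) -> ConditionNetwork:
    """All pair clusters with |rho| >= tau become edges (masks retained)."""
    if not 0 < tau <= 1:
        raise ValueError("tau must be in (0, 1]")
    edges = [pc for pc in pairs if abs(pc.rho) >= tau]
    return ConditionNetwork(edges=edges, sample_ids=list(sample_ids), tau=tau)


def write_graphml(net: ConditionNetwork, path) -> None:
    """Export the simple graph with per-pair strongest rho as GraphML."""
    g = nx.Graph()
    for e in net.edges:
        cur = g.get_edge_data(e.gene_a, e.gene_b)
        if cur is None or abs(e.rho) > abs(cur["rho"]):
            g.add_edge(e.gene_a, e.gene_b, rho=float(e.rho), n=int(e.n))
    g.graph["tau"] = float(net.tau)
    nx.write_graphml(g, path)


def topology_stats(net: ConditionNetwork) -> NetworkStats:
    """Node/edge counts, mean degree, and the scale-free log-log R^2.

    Degrees come from the simple graph underlying the edge set.  R^2 is
    from the least-squares line of log10 P(k) on log10 k over degrees
    with P(k) > 0; undefined (None) when fewer than two distinct degree
    values exist.
    """
    g = net.simple_graph()
    if g.number_of_nodes() < 2:
        raise ValueError("topology stats need at least 2 nodes")
    degrees = np.array([d for _, d in g.degree()])
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    ks, counts = np.unique(degrees[degrees > 0], return_counts=True)
    r2 = None
    if ks.size >= 2:
        pk = counts / n_nodes
        fit = stats.linregress(np.log10(ks), np.log10(pk))
        r2 = float(fit.rvalue**2)
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        mean_degree=2.0 * n_edges / n_nodes,
        scale_free_r2=r2,
    )
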