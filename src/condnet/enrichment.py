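"""Edge/condition enrichment.

Every network edge carries the mask of samples supporting it.  This
module asks, per edge and per condition (a clinical attribute value such
as "Solid Tissue Normal", a driver-gene mutation flag, or a mutation
co-occurrence group such as VHL+PBRM1-without-BAP1), whether the edge's
samples are enriched for that condition: a one-sided Fisher's exact test
over the full sample universe, with Hochberg step-up correction within
each condition's family of edge tests.  Condition subnetworks (e.g. a
"tumor" network of Primary-Tumor-enriched edges) are extracted from the
adjusted p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .threshold import ConditionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MUTATION",
    "NO_MUTATION",
    "SampleAnnotations",
    "code_mutations",
    "code_co_occurrence",
    "edge_condition_test",
    "enrich_network",
    "extract_subnetwork",
]

MUTATION = "Mutation"
NO_MUTATION = "No Mutation"

# raw cell values that mean "no disruptive variant observed"
_NEGATIVE_TOKENS = {"", "na", "nan", "none", "no mutation", "0", "wt", "wild type"}


@dataclass
class SampleAnnotations:
    """Per-sample categorical attributes and binary mutation flags.

    ``attributes``: samples x categorical columns (cancer type, tissue
    type, tumor stage, vital status, ...).  ``mutations``: samples x
    panel-gene columns with values ``"Mutation"`` / ``"No Mutation"``;
    derived co-occurrence columns live here too and are listed in
    ``co_occurrence_columns`` (they get the cluster-size filter during
    enrichment).
    """

    attributes: pd.DataFrame
    mutations: pd.DataFrame | None = None
    co_occurrence_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.mutations is not None and not self.mutations.empty:
            bad = set(np.unique(self.mutations.to_numpy(dtype=object))) - {
                MUTATION, NO_MUTATION
            }
            if bad:
                raise ValueError(f"mutation flags must be binary; got {sorted(map(str, bad))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.attributes.index)

    def conditions(self) -> list[tuple[str, str, str]]:
        """All testable conditions as (key, column, value) triples.

        Attribute conditions are keyed ``column=value`` (one per observed
        value); mutation conditions are keyed by the gene/group name and
        test the ``"Mutation"`` value.
        """
        out = []
        for col in self.attributes.columns:
            for val in pd.unique(self.attributes[col].dropna()):
                out.append((f"{col}={val}", col, str(val)))
        if self.mutations is not None:
            for col in self.mutations.columns:
                out.append((col, col, MUTATION))
        return out

    def condition_mask(self, column: str, value: str) -> np.ndarray:
        if self.mutations is not None and column in self.mutations.columns:
            return (self.mutations[column] == value).to_numpy()
        if column in self.attributes.columns:
            return (self.attributes[column].astype(str) == value).to_numpy()
        raise KeyError(f"unknown annotation column: {column!r}")

    def reindex(self, sample_ids: list[str]) -> "SampleAnnotations":
        mut = None
        if self.mutations is not None:
            mut = self.mutations.reindex(sample_ids, fill_value=NO_MUTATION)
        return SampleAnnotations(
            self.attributes.reindex(sample_ids),
            mut,
            list(self.co_occurrence_columns),
        )


def code_mutations(
    raw: pd.DataFrame, samples: list[str], panel: list[str]
) -> pd.DataFrame:
    """Binary-code a raw sample x gene mutation table.

    Any disruptive variant-type string counts as ``"Mutation"``; empty /
    NA / "No Mutation"-like cells count as ``"No Mutation"``.  Samples
    absent from the table default to ``"No Mutation"`` on the whole panel
    (logged).  Duplicate sample rows must agree after coding.
    """
    if not panel:
        raise ValueError("mutation panel must be non-empty")
    missing_cols = [g for g in panel if g not in raw.columns]
    present = [g for g in panel if g in raw.columns]

    def code_cell(v) -> str:
        if pd.isna(v):
            return NO_MUTATION
        return NO_MUTATION if str(v).strip().lower() in _NEGATIVE_TOKENS else MUTATION

    coded = raw[present].map(code_cell) if present else pd.DataFrame(index=raw.index)
    if coded.index.has_duplicates:
        for sid, group in coded.groupby(level=0):
            if len(group) > 1 and (group.nunique() > 1).any():
                raise ValueError(f"conflicting duplicate mutation rows for sample {sid!r}")
        coded = coded[~coded.index.duplicated()]
    out = coded.reindex(index=samples, fill_value=NO_MUTATION)
    for g in missing_cols:
        out[g] = NO_MUTATION
    out = out[panel]
    n_absent = len(set(samples) - set(raw.index))
    if n_absent:
        logger.info("code_mutations: %d samples absent from the mutation table "
                    "defaulted to No Mutation", n_absent)
    return out


def code_co_occurrence(ann: SampleAnnotations) -> SampleAnnotations:
    """Derive the VHL_PBRM1 and VHL_BAP1 co-occurrence groups.

    A sample is ``VHL_PBRM1 = Mutation`` iff it has VHL and PBRM1
    mutations but no BAP1 mutation; ``VHL_BAP1`` symmetrically requires
    VHL and BAP1 without PBRM1 (the two driver paths are coded as
    mutually exclusive).  Idempotent.
    """
    if ann.mutations is None:
        raise ValueError("no mutation flags present")
    for g in ("VHL", "PBRM1", "BAP1"):
        if g not in ann.mutations.columns:
            raise ValueError(f"co-occurrence coding requires {g} flags")
    mut = ann.mutations.copy()
    vhl = mut["VHL"] == MUTATION
    pbrm1 = mut["PBRM1"] == MUTATION
    bap1 = mut["BAP1"] == MUTATION
    mut["VHL_PBRM1"] = np.where(vhl & pbrm1 & ~bap1, MUTATION, NO_MUTATION)
    mut["VHL_BAP1"] = np.where(vhl & bap1 & ~pbrm1, MUTATION, NO_MUTATION)
    co = list(dict.fromkeys(ann.co_occurrence_columns + ["VHL_PBRM1", "VHL_BAP1"]))
    return SampleAnnotations(ann.attributes, mut, co)


def edge_condition_test(edge_mask: np.ndarray, condition_mask: np.ndarray) -> float:
    """One-sided Fisher's exact p for edge-samples x condition.

    The 2x2 table is [in edge mask vs not] x [has condition vs not] over
    the full sample universe; the alternative is enrichment (more
    condition-positive samples in the edge than chance).  Equivalent to
    the hypergeometric upper tail.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    condition_mask = np.asarray(condition_mask, dtype=bool)
    if edge_mask.shape != condition_mask.shape:
        raise ValueError("mask shapes differ")
    if not edge_mask.any():
        raise ValueError("empty edge mask")
    n_total = edge_mask.size
    n_cond = int(condition_mask.sum())
    if n_cond in (0, n_total):
        return 1.0  # condition constant: no contrast
    n_edge = int(edge_mask.sum())
    overlap = int((edge_mask & condition_mask).sum())
    return float(stats.hypergeom.sf(overlap - 1, n_total, n_cond, n_edge))


def enrich_network(
    net: ConditionNetwork,
    ann: SampleAnnotations,
    alpha: float = 0.001,
    max_cluster: int | None = 250,
) -> ConditionNetwork:
    """Test every edge against every condition; Hochberg-adjust per condition.

    Each condition's family is the set of its eligible edges (per-column
    correction).  Co-occurrence conditions only test edges whose cluster
    size n is at most ``max_cluster`` — their positive groups are small,
    so huge sample clusters cannot be specific to them.  Untested cells
    are NaN.  Returns a new network carrying ``pvalues`` and
    ``adj_pvalues`` (edges x conditions).
    """
    ann = ann.reindex(net.sample_ids)
    conds = ann.conditions()
    n_edges = len(net.edges)
    keys = [key for key, _, _ in conds]
    p = pd.DataFrame(np.nan, index=range(n_edges), columns=keys)
    padj = pd.DataFrame(np.nan, index=range(n_edges), columns=keys)
    edge_ns = np.array([e.n for e in net.edges])
    for key, col, val in conds:
        cmask = ann.condition_mask(col, val)
        if max_cluster is not None and key in ann.co_occurrence_columns:
            eligible = np.flatnonzero(edge_ns <= max_cluster)
        else:
            eligible = np.arange(n_edges)
        if eligible.size == 0:
            continue
        pvals = np.array(
            [edge_condition_test(net.edges[i].mask, cmask) for i in eligible]
        )
        adj = multipletests(pvals, method="simes-hochberg")[1]
        p.loc[eligible, key] = pvals
        padj.loc[eligible, key] = adj
    out = replace(net)
    out.pvalues = p
    out.adj_pvalues = padj
    return out


def _resolve_condition(net: ConditionNetwork, condition: str) -> str:
    cols = list(net.adj_pvalues.columns)
    if condition in cols:
        return condition
    matches = [c for c in cols if c.endswith(f"={condition}")]
    if len(matches) == 1:
        return matches[0]
    if not matches:
        raise KeyError(f"condition never tested: {condition!r}")
    raise KeyError(f"ambiguous condition {condition!r}: {matches}")


def extract_subnetwork(
    net: ConditionNetwork, condition: str, alpha: float = 0.001
) -> ConditionNetwork:
    """Edges significantly enriched (adj p < alpha) for one condition.

    ``condition`` may be a full key (``"tissue_type=Primary Tumor"``, a
    mutation group name) or a bare attribute value when unambiguous.
    """
    if net.adj_pvalues is None:
        raise KeyError("network has no enrichment results")
    key = _resolve_condition(net, condition)
    sel = np.flatnonzero(net.adj_pvalues[key].to_numpy() < alpha)
    sub = ConditionNetwork(
        edges=[net.edges[i] for i in sel],
        sample_ids=list(net.sample_ids),
        tau=net.tau,
    )
    if len(sel):
        sub.pvalues = net.pvalues.iloc[sel].reset_index(drop=True)
        sub.adj_pvalues = net.adj_pvalues.iloc[sel].reset_index(drop=True)
    return sub
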