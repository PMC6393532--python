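"""Edge/condition enrichment: mutation coding rules, VHL/PBRM1/BAP1
co-occurrence logic, Fisher tests against an exact enumeration oracle,
Hochberg step-up against a hand oracle, null calibration, and condition
subnetwork extraction."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from condnet.enrichment import (
    MUTATION,
    NO_MUTATION,
    SampleAnnotations,
    code_co_occurrence,
    code_mutations,
    edge_condition_test,
    enrich_network,
    extract_subnetwork,
)
from condnet.similarity import PairCluster
from condnet.threshold import ConditionNetwork


def enumeration_hypergeom_tail(n_total, n_cond, n_edge, overlap):
    """P(X >= overlap) by direct summation of hypergeometric terms."""
    total = 0
    for x in range(overlap, min(n_cond, n_edge) + 1):
        total += comb(n_cond, x) * comb(n_total - n_cond, n_edge - x)
    return total / comb(n_total, n_edge)


def hochberg_oracle(pvals):
    """Step-up adjustment by direct enumeration of the definition."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        factor = rank_from_top + 1
        prev = min(prev, factor * pvals[idx])
        adj[idx] = prev
    return adj


def make_ann(samples, **columns):
    attrs = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"))
    return SampleAnnotations(attrs)


class TestCodeMutations:
    def test_disruptive_type_becomes_mutation(self):
        raw = pd.DataFrame({"VHL": ["Missense_Mutation"]}, index=["s1"])
        out = code_mutations(raw, ["s1", "s2"], ["VHL"])
        assert out.loc["s1", "VHL"] == MUTATION
        assert out.loc["s2", "VHL"] == NO_MUTATION  # absent sample defaults

    def test_absent_sample_gets_no_mutation_panel_wide(self):
        raw = pd.DataFrame({"VHL": ["Nonsense"], "BAP1": ["Frame_Shift_Del"]},
                           index=["s1"])
        out = code_mutations(raw, ["s1", "s2"], ["VHL", "BAP1", "PBRM1"])
        assert (out.loc["s2"] == NO_MUTATION).all()
        assert out.loc["s1", "PBRM1"] == NO_MUTATION  # panel gene not in table

    def test_empty_table_all_no_mutation(self):
        raw = pd.DataFrame(columns=["VHL"], dtype=str)
        out = code_mutations(raw, ["s1", "s2"], ["VHL"])
        assert (out == NO_MUTATION).all().all()

    def test_conflicting_duplicate_rows_error(self):
        raw = pd.DataFrame({"VHL": ["Missense", None]}, index=["s1", "s1"])
        with pytest.raises(ValueError, match="s1"):
            code_mutations(raw, ["s1"], ["VHL"])

    def test_empty_panel_error(self):
        with pytest.raises(ValueError, match="panel"):
            code_mutations(pd.DataFrame(), ["s1"], [])


class TestCodeCoOccurrence:
    def ann_with(self, vhl, pbrm1, bap1):
        attrs = pd.DataFrame(index=pd.Index(["s"], name="sample_id"))
        mut = pd.DataFrame(
            {
                "VHL": [MUTATION if vhl else NO_MUTATION],
                "PBRM1": [MUTATION if pbrm1 else NO_MUTATION],
                "BAP1": [MUTATION if bap1 else NO_MUTATION],
            },
            index=attrs.index,
        )
        return SampleAnnotations(attrs, mut)

    @pytest.mark.parametrize(
        "vhl,pbrm1,bap1,expect_vp,expect_vb",
        [
            (1, 1, 0, MUTATION, NO_MUTATION),
            (1, 0, 1, NO_MUTATION, MUTATION),
            (1, 1, 1, NO_MUTATION, NO_MUTATION),  # mutually exclusive rule
            (0, 1, 0, NO_MUTATION, NO_MUTATION),  # VHL required
            (1, 0, 0, NO_MUTATION, NO_MUTATION),
        ],
    )
    def test_rule_table(self, vhl, pbrm1, bap1, expect_vp, expect_vb):
        out = code_co_occurrence(self.ann_with(vhl, pbrm1, bap1))
        assert out.mutations.loc["s", "VHL_PBRM1"] == expect_vp
        assert out.mutations.loc["s", "VHL_BAP1"] == expect_vb

    def test_idempotent(self):
        once = code_co_occurrence(self.ann_with(1, 1, 0))
        twice = code_co_occurrence(once)
        pd.testing.assert_frame_equal(once.mutations, twice.mutations)
        assert twice.co_occurrence_columns == ["VHL_PBRM1", "VHL_BAP1"]

    def test_missing_flags_error(self):
        attrs = pd.DataFrame(index=["s"])
        mut = pd.DataFrame({"VHL": [MUTATION]}, index=["s"])
        with pytest.raises(ValueError, match="PBRM1"):
            code_co_occurrence(SampleAnnotations(attrs, mut))


class TestEdgeConditionTest:
    def test_matches_enumeration_oracle(self):
        n = 100
        edge = np.zeros(n, bool)
        edge[:30] = True
        cond = np.zeros(n, bool)
        cond[:30] = True  # edge mask = exactly the condition-positive set
        p = edge_condition_test(edge, cond)
        oracle = enumeration_hypergeom_tail(100, 30, 30, 30)
        assert p == pytest.approx(oracle, rel=1e-10)

    def test_matches_scipy_fisher(self, rng):
        for _ in range(10):
            edge = rng.random(60) < 0.4
            cond = rng.random(60) < 0.3
            if not edge.any():
                continue
            a = int((edge & cond).sum())
            b = int((edge & ~cond).sum())
            c = int((~edge & cond).sum())
            d = int((~edge & ~cond).sum())
            expected = sps.fisher_exact([[a, b], [c, d]],
                                        alternative="greater").pvalue
            assert edge_condition_test(edge, cond) == pytest.approx(
                expected, rel=1e-9
            )

    def test_constant_condition_gives_p_one(self):
        edge = np.array([True, False, True])
        assert edge_condition_test(edge, np.ones(3, bool)) == 1.0
        assert edge_condition_test(edge, np.zeros(3, bool)) == 1.0

    def test_null_pvalues_match_exact_null_law(self, rng):
        # the exact test is discrete, so its null p-values are not
        # U(0,1); they must instead match the exact hypergeometric null
        # law of the p-value and be valid (P(p <= a) <= a)
        n, k_cond, k_edge = 200, 60, 50
        cond = np.zeros(n, bool)
        cond[:k_cond] = True
        pvals = []
        for _ in range(1000):
            edge = np.zeros(n, bool)
            edge[rng.choice(n, k_edge, replace=False)] = True
            pvals.append(edge_condition_test(edge, cond))
        pvals = np.asarray(pvals)
        support = np.arange(0, min(k_cond, k_edge) + 1)
        pmf = sps.hypergeom.pmf(support, n, k_cond, k_edge)
        p_of_x = sps.hypergeom.sf(support - 1, n, k_cond, k_edge)
        for alpha in (0.05, 0.01, 0.001):
            exact = pmf[p_of_x <= alpha].sum()
            assert exact <= alpha + 1e-12  # validity of the exact test
            observed = (pvals <= alpha).mean()
            assert observed == pytest.approx(exact, abs=0.02)
        # empirical distribution matches the exact discrete law
        for t in np.linspace(0.05, 0.95, 10):
            exact_cdf = pmf[p_of_x <= t].sum()
            assert abs((pvals <= t).mean() - exact_cdf) < 0.05


def build_network(masks, sample_ids, rhos=None):
    rhos = rhos or [0.9] * len(masks)
    edges = [
        PairCluster(f"g{2*i}", f"g{2*i+1}", 0, m, r)
        for i, (m, r) in enumerate(zip(masks, rhos))
    ]
    return ConditionNetwork(edges, list(sample_ids), 0.8)


class TestEnrichNetwork:
    def test_hochberg_oracle_two_pvalues(self):
        # family [0.01, 0.04] must adjust to [0.02, 0.04]
        assert hochberg_oracle([0.01, 0.04]).tolist() == [0.02, 0.04]
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.04], method="simes-hochberg")[1]
        np.testing.assert_allclose(adj, [0.02, 0.04])

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        n = 120
        samples = [f"s{i}" for i in range(n)]
        ann = make_ann(samples, grp=rng.choice(["x", "y"], n))
        masks = [np.zeros(n, bool) for _ in range(15)]
        for m in masks:
            m[rng.choice(n, 40, replace=False)] = True
        net = enrich_network(build_network(masks, samples), ann)
        for col in net.pvalues.columns:
            p = net.pvalues[col].to_numpy()
            q = net.adj_pvalues[col].to_numpy()
            assert (q >= p - 1e-12).all()
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            np.testing.assert_allclose(q, hochberg_oracle(p), atol=1e-12)

    def test_max_cluster_excludes_big_edges_for_co_occurrence(self, rng):
        n = 400
        samples = [f"s{i}" for i in range(n)]
        attrs = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
        mut = pd.DataFrame(NO_MUTATION, index=attrs.index,
                           columns=["VHL", "PBRM1", "BAP1"])
        mut.iloc[:40] = MUTATION
        mut.iloc[:40, mut.columns.get_loc("BAP1")] = NO_MUTATION
        ann = code_co_occurrence(SampleAnnotations(attrs, mut))
        big = np.zeros(n, bool)
        big[:251] = True
        small = np.zeros(n, bool)
        small[:40] = True
        net = enrich_network(build_network([big, small], samples), ann,
                             max_cluster=250)
        assert np.isnan(net.pvalues.loc[0, "VHL_PBRM1"])  # n=251: not tested
        assert np.isfinite(net.pvalues.loc[1, "VHL_PBRM1"])
        # non-co-occurrence conditions still tested on the big edge
        assert np.isfinite(net.pvalues.loc[0, "VHL"])

    def test_planted_group_edges_flagged(self, rng):
        n = 300
        samples = [f"s{i}" for i in range(n)]
        group = np.zeros(n, bool)
        group[:60] = True
        ann = make_ann(samples, grp=np.where(group, "G", "other"))
        planted = []
        for _ in range(10):
            m = group.copy()
            flip = rng.choice(np.flatnonzero(group), 5, replace=False)
            m[flip] = False  # slightly noisy masks
            planted.append(m)
        background = []
        for _ in range(90):
            m = np.zeros(n, bool)
            m[rng.choice(n, 55, replace=False)] = True
            background.append(m)
        net = enrich_network(build_network(planted + background, samples), ann)
        flags = net.adj_pvalues["grp=G"].to_numpy() < 0.001
        assert flags[:10].all()
        assert flags[10:].sum() <= 1

    def test_null_network_false_flag_rate(self, rng):
        n = 250
        samples = [f"s{i}" for i in range(n)]
        ann = make_ann(samples, grp=rng.choice(["a", "b", "c"], n))
        masks = []
        for _ in range(1000):
            m = np.zeros(n, bool)
            m[rng.choice(n, 50, replace=False)] = True
            masks.append(m)
        net = enrich_network(build_network(masks, samples), ann)
        frac = float((net.adj_pvalues < 0.001).any(axis=1).mean())
        assert frac <= 0.002


class TestExtractSubnetwork:
    def setup_net(self, rng):
        n = 200
        samples = [f"s{i}" for i in range(n)]
        tumor = np.zeros(n, bool)
        tumor[:150] = True
        ann = make_ann(
            samples,
            tissue_type=np.where(tumor, "Primary Tumor", "Solid Tissue Normal"),
        )
        tumor_masks = []
        normal_masks = []
        for _ in range(8):
            m = np.zeros(n, bool)
            m[rng.choice(np.flatnonzero(tumor), 80, replace=False)] = True
            tumor_masks.append(m)
            m2 = np.zeros(n, bool)
            m2[rng.choice(np.flatnonzero(~tumor), 40, replace=False)] = True
            normal_masks.append(m2)
        net = build_network(tumor_masks + normal_masks, samples)
        return enrich_network(net, ann), len(tumor_masks)

    def test_alpha_one_returns_everything(self, rng):
        net, _ = self.setup_net(rng)
        sub = extract_subnetwork(net, "Primary Tumor", alpha=1.01)
        assert len(sub.edges) == len(net.edges)

    def test_condition_subnetworks_are_disjoint(self, rng):
        net, n_tumor = self.setup_net(rng)
        tumor_net = extract_subnetwork(net, "Primary Tumor")
        normal_net = extract_subnetwork(net, "Solid Tissue Normal")
        tumor_keys = {(e.gene_a, e.gene_b) for e in tumor_net.edges}
        normal_keys = {(e.gene_a, e.gene_b) for e in normal_net.edges}
        assert len(tumor_keys) == n_tumor
        assert not (tumor_keys & normal_keys)

    def test_untested_condition_is_error(self, rng):
        net, _ = self.setup_net(rng)
        with pytest.raises(KeyError, match="never tested"):
            extract_subnetwork(net, "Metastatic")
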