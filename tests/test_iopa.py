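"""Pathway loading, ORA, topology perturbation, p-value combination."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metabokit.iopa import (OmicsSummary, PathwayGraph, adjust_p, combine_p,
                            espia, iopa_run, load_pathways,
                            load_pathways_kgml, load_pathways_tsv, ora)
from metabokit.synthetic import SimulationSpec, simulate_pathways


def _summary(sig_ids, all_ids, kind="gene", betas=None):
    rows = []
    for fid in all_ids:
        rows.append((fid, kind,
                     (betas or {}).get(fid, 1.0 if fid in sig_ids else 0.0),
                     0.001 if fid in sig_ids else 0.9,
                     fid in sig_ids))
    return OmicsSummary(pd.DataFrame(
        rows, columns=["feature_id", "kind", "beta", "p", "significant"]))


class TestLoadPathways:
    def test_two_node_tsv(self, tmp_path):
        nodes = tmp_path / "nodes.tsv"
        edges = tmp_path / "edges.tsv"
        nodes.write_text("pathway_id\tpathway_name\tnode_id\tkind\n"
                         "p1\tdemo\tg1\tgene\np1\tdemo\tc1\tcompound\n")
        edges.write_text("pathway_id\tsrc\tdst\trelation\np1\tg1\tc1\tactivation\n")
        (graph,) = load_pathways_tsv(nodes, edges)
        assert graph.nodes == {("g1", "gene"), ("c1", "compound")}
        assert graph.edges == {("g1", "c1", 1, "activation")}

    def test_kgml_fixture_counts(self, tmp_path):
        kgml = tmp_path / "hsa00001.xml"
        kgml.write_text("""<?xml version="1.0"?>
<pathway name="path:hsa00001" title="demo pathway">
  <entry id="1" type="gene" name="hsa:10 hsa:11"/>
  <entry id="2" type="gene" name="hsa:12"/>
  <entry id="3" type="compound" name="cpd:C00031"/>
  <entry id="4" type="map" name="path:hsa00002"/>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PCrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>""")
        (g,) = load_pathways_kgml([kgml])
        assert len(g.members("gene")) == 3
        assert len(g.members("compound")) == 1
        signs = {(s, d): sg for s, d, sg, _ in g.edges}
        assert signs[("12", "C00031")] == -1
        assert signs[("10", "12")] == 1 and signs[("11", "12")] == 1

    def test_dangling_edge_rejected(self, tmp_path):
        nodes = tmp_path / "nodes.tsv"
        edges = tmp_path / "edges.tsv"
        nodes.write_text("pathway_id\tpathway_name\tnode_id\tkind\n"
                         "p1\tdemo\tg1\tgene\n")
        edges.write_text("pathway_id\tsrc\tdst\trelation\np1\tg1\tgX\tactivation\n")
        with pytest.raises(ValueError, match="dangling"):
            load_pathways_tsv(nodes, edges)

    def test_unsigned_relations_dropped_with_warning(self, tmp_path):
        nodes = tmp_path / "n.tsv"; edges = tmp_path / "e.tsv"
        nodes.write_text("pathway_id\tpathway_name\tnode_id\tkind\n"
                         "p1\td\tg1\tgene\np1\td\tg2\tgene\n")
        edges.write_text("pathway_id\tsrc\tdst\trelation\np1\tg1\tg2\tbinding\n")
        with pytest.warns(UserWarning, match="unsigned"):
            (g,) = load_pathways(nodes, edges)
        assert g.edges == set()


class TestOra:
    def test_exact_example(self):
        """N=10, K=4, n=3, k=2 -> P(X>=2) = 40/120."""
        ids = [f"g{i}" for i in range(10)]
        summary = _summary(set(ids[:4]), ids)
        pw = PathwayGraph("p", "p", {(ids[0], "gene"), (ids[1], "gene"),
                                     (ids[9], "gene")})
        p, counts = ora(pw, summary, "gene")
        assert counts == {"N": 10, "K": 4, "n": 3, "k": 2}
        assert p == pytest.approx(40.0 / 120.0, abs=1e-12)

    def test_k_zero_gives_one(self):
        ids = [f"g{i}" for i in range(8)]
        summary = _summary(set(ids[:3]), ids)
        pw = PathwayGraph("p", "p", {(ids[7], "gene"), (ids[6], "gene")})
        p, counts = ora(pw, summary, "gene")
        assert counts["k"] == 0 and p == 1.0

    def test_all_members_significant_closed_form(self):
        ids = [f"g{i}" for i in range(9)]
        K = 4
        summary = _summary(set(ids[:K]), ids)
        pw = PathwayGraph("p", "p", {(i, "gene") for i in ids[:3]})
        p, _ = ora(pw, summary, "gene")
        # k == n == 3: p = C(K,3)C(N-K,0)/C(N,3)
        expect = math.comb(K, 3) / math.comb(9, 3)
        assert p == pytest.approx(expect, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """Exact oracle: enumerate all C(N, n) draws for N <= 12."""
        rng = np.random.default_rng(0)
        for trial in range(5):
            N = int(rng.integers(5, 13))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            ids = [f"g{i}" for i in range(N)]
            sig = set(rng.choice(ids, size=K, replace=False))
            members = list(rng.choice(ids, size=n, replace=False))
            k_obs = len(set(members) & sig)
            hits = total = 0
            for draw in itertools.combinations(ids, n):
                total += 1
                hits += len(set(draw) & sig) >= k_obs
            pw = PathwayGraph("p", "p", {(m, "gene") for m in members})
            p, _ = ora(pw, _summary(sig, ids), "gene")
            assert p == pytest.approx(hits / total, abs=1e-10)

    def test_empty_overlap_flagged(self):
        summary = _summary({"g1"}, ["g1", "g2"])
        pw = PathwayGraph("p", "p", {("zz", "gene")})
        p, counts = ora(pw, summary, "gene")
        assert p == 1.0 and counts["n"] == 0


class TestEspia:
    def test_edgeless_pathway_no_propagation(self):
        pw = PathwayGraph("p", "p", {("a", "gene"), ("b", "gene")})
        t_a, p = espia(pw, {"a": 3.0}, n_boot=200, seed=0)
        assert t_a == 0.0 and p > 0.5

    def test_hand_solved_chain(self):
        """a -> b (+1), dE(a)=2, outdeg(a)=1: PF(b)=2, Acc=2, t_A=2."""
        pw = PathwayGraph("p", "p", {("a", "gene"), ("b", "compound")},
                          {("a", "b", 1, "activation")})
        t_a, _ = espia(pw, {"a": 2.0}, n_boot=100, seed=0)
        assert t_a == pytest.approx(2.0, abs=1e-12)

    def test_sign_flip_negates_statistic(self):
        # star graph (no two-step paths): accumulation is linear in the
        # edge signs, so flipping all signs exactly negates t_A
        nodes = {(x, "gene") for x in "abcd"}
        edges = {("a", "b", 1, "+"), ("a", "c", 1, "+"), ("a", "d", -1, "-")}
        pw_pos = PathwayGraph("p", "p", nodes, edges)
        pw_neg = PathwayGraph("p", "p", nodes,
                              {(s, d, -g, l) for s, d, g, l in edges})
        de = {"a": 1.5, "b": -0.5}
        t_pos, _ = espia(pw_pos, de, n_boot=100, seed=1)
        t_neg, _ = espia(pw_neg, de, n_boot=100, seed=1)
        assert t_neg == pytest.approx(-t_pos, abs=1e-10)

    def test_linear_solve_equals_iterative_propagation(self):
        """On an acyclic graph the fixed point can be reached by Jacobi
        iteration; both routes agree to 1e-10."""
        nodes = {(x, "gene") for x in "abcde"}
        edges = {("a", "b", 1, "+"), ("a", "c", -1, "-"),
                 ("b", "d", 1, "+"), ("c", "d", 1, "+"), ("d", "e", -1, "-")}
        pw = PathwayGraph("p", "p", nodes, edges)
        de = {"a": 2.0, "c": 1.0}
        order = sorted(pw.members())
        idx = {n: i for i, n in enumerate(order)}
        outdeg = {n: 0 for n in order}
        for s, _d, _g, _l in edges:
            outdeg[s] += 1
        B = np.zeros((5, 5))
        for s, d, g, _l in edges:
            B[idx[d], idx[s]] += g / outdeg[s]
        dev = np.array([de.get(n, 0.0) for n in order])
        pf = dev.copy()
        for _ in range(200):
            pf = dev + B @ pf
        t_iter = float((pf - dev).sum())
        t_a, _ = espia(pw, de, n_boot=100, seed=0)
        assert t_a == pytest.approx(t_iter, abs=1e-10)

    def test_small_bootstrap_rejected(self):
        pw = PathwayGraph("p", "p", {("a", "gene")})
        with pytest.raises(ValueError):
            espia(pw, {"a": 1.0}, n_boot=10)


class TestCombineP:
    def test_fisher_closed_form(self):
        """X = 9.2103 -> p = (1 + X/2) exp(-X/2) = 0.05605."""
        p = combine_p(0.1, 0.1, "fisher")
        x = -2 * (math.log(0.1) + math.log(0.1))
        assert x == pytest.approx(9.2103, abs=1e-4)
        assert p == pytest.approx((1 + x / 2) * math.exp(-x / 2), abs=1e-12)
        assert p == pytest.approx(0.05605, abs=1e-5)

    def test_fisher_of_ones(self):
        assert combine_p(1.0, 1.0, "fisher") == pytest.approx(1.0)

    def test_fisher_with_one_never_beats_component(self):
        for p in (0.001, 0.01, 0.1, 0.5, 0.9):
            assert combine_p(p, 1.0, "fisher") >= p

    def test_fisher_uniform_under_null(self):
        rng = np.random.default_rng(0)
        ps = [combine_p(a, b, "fisher")
              for a, b in rng.uniform(size=(10_000, 2))]
        assert sps.kstest(ps, "uniform").statistic < 0.02

    def test_nonpositive_p_clamped(self):
        with pytest.warns(UserWarning):
            p = combine_p(0.0, 0.5, "fisher")
        assert 0.0 < p < 1e-8

    def test_pbine_empirical_tail(self):
        rng = np.random.default_rng(1)
        null = rng.uniform(size=(2000, 2))
        p = combine_p(0.01, 0.01, "pbine", null_pairs=null)
        assert 0.0 < p < 0.05


class TestAdjustP:
    def test_bh_step_up_by_hand(self):
        np.testing.assert_allclose(adjust_p([0.01, 0.02, 0.03], "fdr_bh"),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        for method in ("fdr_bh", "bonferroni"):
            assert adjust_p([0.2], method)[0] == pytest.approx(0.2)

    def test_bonferroni_capped(self):
        np.testing.assert_allclose(adjust_p([0.4, 0.4, 0.4], "bonferroni"),
                                   [1.0, 1.0, 1.0])

    def test_bh_matches_reference_step_up(self):
        """Oracle: literal step-up definition re-implemented from scratch."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 50)))
            m = len(p)
            order = np.argsort(p)
            ref = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                val = min(prev, p[i] * m / rank)
                ref[i] = val
                prev = val
            np.testing.assert_allclose(adjust_p(p, "fdr_bh"), ref, atol=1e-12)


class TestIopaRun:
    def test_planted_pathway_ranks_first(self):
        spec = SimulationSpec(seed=11, n_pathways=6)
        pws, gs, cs, truth = simulate_pathways(spec)
        results, manhattan, volcano = iopa_run(pws, gs, cs, n_boot=200, seed=0)
        best = min(results, key=lambda r: r.p_combined)
        assert best.pathway_id == truth["enriched"]
        assert len(manhattan) == len(volcano) == 6

    def test_counts_invariants(self):
        spec = SimulationSpec(seed=12, n_pathways=4)
        pws, gs, cs, _ = simulate_pathways(spec)
        results, _, _ = iopa_run(pws, gs, cs, n_boot=200, seed=0)
        for r in results:
            assert r.deG_n <= r.G_n and r.deC_n <= r.C_n
            assert r.P_n == r.G_n + r.C_n
            assert r.deP_n == r.deG_n + r.deC_n
            for p in (r.p_ora_gene, r.p_ora_compound, r.p_ora_joint,
                      r.p_espia, r.p_combined, r.p_fdr, r.p_bonferroni):
                assert 0.0 <= p <= 1.0

    def test_no_significant_features_all_p_one(self):
        spec = SimulationSpec(seed=13, n_pathways=3)
        pws, gs, cs, _ = simulate_pathways(spec)
        for s in (gs, cs):
            s.table["significant"] = False  # beta threshold at infinity
        results, _, _ = iopa_run(pws, gs, cs, n_boot=200, seed=0)
        assert all(r.p_ora_joint == 1.0 for r in results)

    def test_seed_determinism(self):
        spec = SimulationSpec(seed=14, n_pathways=4)
        pws, gs, cs, _ = simulate_pathways(spec)
        a, _, _ = iopa_run(pws, gs, cs, n_boot=200, seed=5)
        b, _, _ = iopa_run(pws, gs, cs, n_boot=200, seed=5)
        assert [(r.t_A, r.p_espia, r.p_combined) for r in a] == \
               [(r.t_A, r.p_espia, r.p_combined) for r in b]

    def test_unmapped_pathway_reported_not_dropped(self):
        spec = SimulationSpec(seed=15, n_pathways=3)
        pws, gs, cs, _ = simulate_pathways(spec)
        orphan = PathwayGraph("orphan", "no mapped features",
                              {("UNKNOWN1", "gene"), ("UNKNOWN2", "compound")})
        results, _, _ = iopa_run(pws + [orphan], gs, cs, n_boot=200, seed=0)
        r = next(r for r in results if r.pathway_id == "orphan")
        assert r.p_ora_joint == 1.0 and r.p_espia == 1.0
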