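"""Node coverage, the PAO LP, per-strain statistics, the filter cascade."""

import numpy as np
import pytest

from strainpath.align_model import GafRecord
from strainpath.graph_model import VariationGraph
from strainpath.strain_pao import (NodeCoverage, PaoProblem, StrainConfig,
                                   StrainEstimate, compute_a_triplet,
                                   compute_b_strain, compute_d_strain,
                                   compute_f_strain, compute_node_coverage,
                                   filter_stage1, filter_stage2,
                                   finalize_profile, iterate_pao, solve_pao,
                                   species_consistency_filter)


def grid_search_objective(problem, step=0.01, upper=None):
    """Independent oracle: exhaustive grid over abundance vectors."""
    n_p = len(problem.strain_ids)
    if upper is None:
        upper = float(problem.depths.max(initial=0.0)) + 0.05
    axis = np.arange(0.0, upper + step / 2, step)
    best = np.inf
    if n_p == 1:
        for a in axis:
            best = min(best, problem.objective(np.array([a])))
    elif n_p == 2:
        A, B = np.meshgrid(axis, axis, indexing="ij")
        combos = np.stack([A.ravel(), B.ravel()], axis=1)
        resid = problem.depths[None, :] - combos @ problem.multiplicity.T
        best = float((np.abs(resid) @ problem.weights).min())
    else:
        for a in axis:  # chunk the first axis to bound memory
            A, B = np.meshgrid(axis, axis, indexing="ij")
            combos = np.stack([np.full(A.size, a), A.ravel(), B.ravel()],
                              axis=1)
            resid = problem.depths[None, :] - combos @ problem.multiplicity.T
            best = min(best, float((np.abs(resid) @ problem.weights).min()))
    return best


def chain_graph(lengths, strain="s", taxid=1):
    g = VariationGraph(species_taxid=taxid)
    for i, ln in enumerate(lengths, 1):
        g.add_node(i, "A" * ln)
    g.add_path(strain, [(i, "+") for i in range(1, len(lengths) + 1)],
               add_missing_edges=True)
    return g


def rec(read_id, steps, path_len, start, end, matches=None):
    span = end - start
    return GafRecord(read_id=read_id, read_length=span, read_start=0,
                     read_end=span, strand="+", path_steps=list(steps),
                     path_length=path_len, path_start=start, path_end=end,
                     residue_matches=matches or span, block_length=span,
                     mapq=60)


def random_pao_problem(rng, max_nodes=8, max_paths=3):
    n_v = int(rng.integers(1, max_nodes + 1))
    n_p = int(rng.integers(1, max_paths + 1))
    lengths = rng.integers(1, 50, size=n_v).astype(float)
    depths = np.round(rng.uniform(0, 1.2, size=n_v), 2)
    mult = rng.integers(0, 3, size=(n_v, n_p)).astype(float)
    for j in range(n_p):  # every path visits at least one node
        if mult[:, j].sum() == 0:
            mult[int(rng.integers(n_v)), j] = 1
    return PaoProblem(node_ids=list(range(1, n_v + 1)), lengths=lengths,
                      depths=depths, strain_ids=[f"p{j}" for j in range(n_p)],
                      multiplicity=mult)


class TestNodeCoverage:
    def test_read_inside_single_node(self):
        g = chain_graph([200])
        cov = compute_node_coverage(g, [rec("r", [(1, "+")], 200, 50, 150)])
        assert cov.aligned_bases[1] == 100
        assert cov.depth(1) == pytest.approx(0.5)

    def test_read_spanning_two_nodes(self):
        g = chain_graph([60, 100])
        cov = compute_node_coverage(
            g, [rec("r", [(1, "+"), (2, "+")], 160, 0, 100)])
        assert cov.aligned_bases == {1: 60, 2: 40}

    def test_per_base_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        lengths = [int(x) for x in rng.integers(5, 80, size=6)]
        g = chain_graph(lengths)
        total = sum(lengths)
        recs = []
        per_base = np.zeros(total, int)
        for i in range(40):
            s = int(rng.integers(0, total - 1))
            e = int(rng.integers(s + 1, total + 1))
            recs.append(rec(f"r{i}", [(j, "+") for j in range(1, 7)],
                            total, s, e))
            per_base[s:e] += 1
        cov = compute_node_coverage(g, recs)
        offset = 0
        for j, ln in enumerate(lengths, 1):
            assert cov.aligned_bases.get(j, 0) == per_base[offset:offset + ln].sum()
            offset += ln

    def test_repeated_node_accumulates_per_visit(self):
        g = VariationGraph(species_taxid=1)
        g.add_node(1, "A" * 50)
        g.add_path("s", [(1, "+"), (1, "+")], add_missing_edges=True)
        cov = compute_node_coverage(
            g, [rec("r", [(1, "+"), (1, "+")], 100, 0, 100)])
        assert cov.aligned_bases[1] == 100

    def test_no_alignments_all_zero(self):
        g = chain_graph([10, 10])
        cov = compute_node_coverage(g, [])
        assert cov.aligned_bases == {}
        assert not cov.is_covered(1)

    def test_interval_outside_path_raises(self):
        g = chain_graph([100])
        with pytest.raises(ValueError, match="interval"):
            compute_node_coverage(g, [rec("r", [(1, "+")], 200, 50, 150)])


class TestSolvePao:
    def test_single_path_uniform_coverage_exact(self):
        g = chain_graph([100, 50, 200])
        cov = NodeCoverage(g, {1: 300, 2: 150, 3: 600})  # depth 3 everywhere
        prob = PaoProblem.from_graph(g, cov, ["s"])
        assert solve_pao(prob)["s"] == pytest.approx(3.0, abs=1e-8)

    def test_disjoint_paths_separable(self):
        g = VariationGraph(species_taxid=1)
        for i, ln in enumerate([100, 100, 80, 80], 1):
            g.add_node(i, "A" * ln)
        g.add_path("a", [(1, "+"), (2, "+")], add_missing_edges=True)
        g.add_path("b", [(3, "+"), (4, "+")], add_missing_edges=True)
        cov = NodeCoverage(g, {1: 400, 2: 400, 3: 480, 4: 480})
        res = solve_pao(PaoProblem.from_graph(g, cov, ["a", "b"]))
        assert res["a"] == pytest.approx(4.0, abs=1e-8)
        assert res["b"] == pytest.approx(6.0, abs=1e-8)

    def test_bubble_instance_matches_grid_search(self):
        # shared/unique bubble: backbone visited by both, alleles exclusive
        g = VariationGraph(species_taxid=1)
        for i, ln in enumerate([40, 10, 10, 40], 1):
            g.add_node(i, "A" * ln)
        g.add_path("a", [(1, "+"), (2, "+"), (4, "+")],
                   add_missing_edges=True)
        g.add_path("b", [(1, "+"), (3, "+"), (4, "+")],
                   add_missing_edges=True)
        cov = NodeCoverage(g, {1: 40, 2: 7, 3: 3, 4: 40})
        prob = PaoProblem.from_graph(g, cov, ["a", "b"])
        res = solve_pao(prob)
        lp_obj = prob.objective(np.array([res["a"], res["b"]]))
        assert lp_obj <= grid_search_objective(prob) + 0.02

    def test_random_instances_match_grid_search(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            prob = random_pao_problem(rng)
            res = solve_pao(prob)
            lp_obj = prob.objective(
                np.array([res[s] for s in prob.strain_ids]))
            assert lp_obj <= grid_search_objective(prob) + 0.02

    def test_noise_free_recovery_below_1e6(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            g = VariationGraph(species_taxid=1)
            # two strains over a 3-bubble chain with exclusive alleles
            n = 1
            a_steps, b_steps = [], []
            for _ in range(4):
                g.add_node(n, "A" * int(rng.integers(20, 60)))
                a_steps.append((n, "+")); b_steps.append((n, "+")); n += 1
                g.add_node(n, "A" * 5)
                a_steps.append((n, "+")); n += 1
                g.add_node(n, "A" * 5)
                b_steps.append((n, "+")); n += 1
            g.add_path("a", a_steps, add_missing_edges=True)
            g.add_path("b", b_steps, add_missing_edges=True)
            true = {"a": float(np.round(rng.uniform(0.5, 10), 3)),
                    "b": float(np.round(rng.uniform(0.5, 10), 3))}
            bases = {}
            for sid, t in true.items():
                for v, _ in g.paths[sid].steps:
                    bases[v] = bases.get(v, 0) + t * g.nodes[v].length_bp
            cov = NodeCoverage(g, bases)
            res = solve_pao(PaoProblem.from_graph(g, cov, ["a", "b"]))
            for sid in true:
                assert abs(res[sid] - true[sid]) < 1e-6


class TestStrainStatistics:
    @pytest.fixture
    def two_strain_graph(self):
        g = VariationGraph(species_taxid=1)
        for i, ln in enumerate([100, 1, 1, 100, 1, 1, 100], 1):
            g.add_node(i, "A" * ln)
        g.add_path("a", [(1, "+"), (2, "+"), (4, "+"), (5, "+"), (7, "+")],
                   add_missing_edges=True)
        g.add_path("b", [(1, "+"), (3, "+"), (4, "+"), (6, "+"), (7, "+")],
                   add_missing_edges=True)
        return g

    def test_f_strain_zero_without_reads(self, two_strain_graph):
        cov = NodeCoverage(two_strain_graph)
        assert compute_f_strain(two_strain_graph, "a", cov,
                                alignments=[]) == 0.0

    def test_f_strain_one_with_full_tiling(self, two_strain_graph):
        g = two_strain_graph
        full = rec("r", g.paths["a"].steps, 302, 0, 302)
        cov = compute_node_coverage(g, [full])
        assert compute_f_strain(g, "a", cov, alignments=[full]) == 1.0

    def test_f_strain_half_traversed_matches_brute_force(self, two_strain_graph):
        g = two_strain_graph
        # one read traverses only the first bubble of strain a
        r1 = rec("r1", [(1, "+"), (2, "+"), (4, "+")], 201, 0, 201)
        cov = compute_node_coverage(g, [r1])
        # strain a's specific triples: (1,2,4),(2,4,5),(4,5,7) -> 1 of 3 seen
        got = compute_f_strain(g, "a", cov, alignments=[r1])
        assert got == pytest.approx(1 / 3)
        # 'nodes' mode: nodes 1,2,4 covered; 5,7 not
        got_nodes = compute_f_strain(g, "a", cov, mode="nodes")
        assert got_nodes == pytest.approx(1 / 3)

    def test_a_triplet_weighted_mean_over_exclusive_nodes(self):
        g = VariationGraph(species_taxid=1)
        for i, ln in enumerate([100, 100, 300, 100], 1):
            g.add_node(i, "A" * ln)
        g.add_path("a", [(1, "+"), (2, "+"), (3, "+"), (4, "+")],
                   add_missing_edges=True)
        g.add_path("b", [(1, "+")] + [(4, "+")], add_missing_edges=True)
        # exclusive triplet nodes of a: 2 (len 100, depth 2), 3 (len 300, depth 6)
        cov = NodeCoverage(g, {2: 200, 3: 1800})
        assert compute_a_triplet(g, "a", cov) == pytest.approx(5.0)

    def test_a_triplet_zero_without_specific_triplets(self):
        g = chain_graph([10, 10, 10])
        g.add_path("t", g.paths["s"].steps, add_missing_edges=True)
        cov = NodeCoverage(g, {1: 10})
        assert compute_a_triplet(g, "s", cov) == 0.0

    def test_b_strain_breadth(self, two_strain_graph):
        g = two_strain_graph
        assert compute_b_strain(g, "a", NodeCoverage(g)) == 0.0
        full = {v: 1 for v, _ in g.paths["a"].steps}
        assert compute_b_strain(g, "a", NodeCoverage(g, full)) == 1.0
        # covered nodes 1 and 4 carry 200 of 302 path bases
        part = NodeCoverage(g, {1: 5, 4: 5})
        assert compute_b_strain(g, "a", part) == pytest.approx(200 / 302)

    def test_d_strain_formula(self):
        assert compute_d_strain(3.0, 3.0) == 0.0
        assert compute_d_strain(1.0, 0.0) == 1.0
        assert compute_d_strain(0.0, 0.0) == 0.0
        assert compute_d_strain(5.0, 2.7) == pytest.approx(0.46)
        with pytest.raises(ValueError):
            compute_d_strain(-1.0, 0.0)


class TestFilterCascade:
    def est(self, **kw):
        e = StrainEstimate(strain_id=kw.pop("sid", "s"))
        for k, v in kw.items():
            setattr(e, k, v)
        return e

    def test_stage1_boundaries(self):
        at = self.est(f_strain=0.3)
        below = self.est(sid="t", f_strain=0.29)
        kept = filter_stage1([at, below], "short")
        assert kept == [at]
        long_at = self.est(f_strain=0.5)
        long_below = self.est(sid="t", f_strain=0.49)
        assert filter_stage1([long_at, long_below], "long") == [long_at]
        assert filter_stage1([self.est(f_strain=0.0)], "short") == []
        assert filter_stage1([self.est(f_strain=0.0)], "long") == []
        with pytest.raises(ValueError):
            filter_stage1([], "medium")

    def test_stage2_retention_rescue_and_removal(self):
        retained = self.est(d_strain=0.46)
        rescued = self.est(sid="u", d_strain=0.55, b_strain=0.95,
                           f_strain=0.95)
        removed_r = self.est(sid="v", d_strain=0.55, b_strain=0.5,
                             f_strain=0.5)
        removed_d = self.est(sid="w", d_strain=0.61, b_strain=1.0,
                             f_strain=1.0)
        kept = filter_stage2([retained, rescued, removed_r, removed_d])
        assert kept == [retained, rescued]
        assert retained.passed_stage2 and not retained.rescued
        assert rescued.rescued and not rescued.passed_stage2
        assert rescued.r_strain == pytest.approx(0.9025)

    def test_lowering_thresholds_never_removes_survivors(self):
        rng = np.random.default_rng(31)
        ests = [self.est(sid=f"s{i}", f_strain=rng.uniform(),
                         b_strain=rng.uniform(), d_strain=rng.uniform())
                for i in range(50)]
        base = StrainConfig()
        loose = StrainConfig(f_min_short=0.1, d_max=0.6, d_rescue_max=0.8,
                             r_min=0.5)
        def survivors(cfg):
            import copy
            pool = copy.deepcopy(ests)
            s1 = filter_stage1(pool, "short", cfg)
            return {e.strain_id for e in filter_stage2(s1, cfg)}
        assert survivors(base) <= survivors(loose)


class TestIteratePao:
    def test_single_true_strain_exact(self):
        g = chain_graph([300, 300, 300, 100])
        reads = [rec(f"r{i}", g.paths["s"].steps, 1000, 0, 1000)
                 for i in range(8)]
        cov = compute_node_coverage(g, reads)
        (est,) = iterate_pao(g, cov, reads, read_type="short")
        # a single path has no competitors: every triple is specific
        assert est.retained
        assert est.reported_abundance == pytest.approx(8.0, abs=1e-6)

    def test_absent_strain_eliminated_at_stage1(self):
        g = VariationGraph(species_taxid=1)
        for i, ln in enumerate([50, 1, 1, 50], 1):
            g.add_node(i, "A" * ln)
        g.add_path("present", [(1, "+"), (2, "+"), (4, "+")],
                   add_missing_edges=True)
        g.add_path("absent", [(1, "+"), (3, "+"), (4, "+")],
                   add_missing_edges=True)
        reads = [rec(f"r{i}", g.paths["present"].steps, 101, 0, 101)
                 for i in range(10)]
        cov = compute_node_coverage(g, reads)
        ests = {e.strain_id: e for e in
                iterate_pao(g, cov, reads, read_type="short")}
        assert ests["present"].retained
        assert not ests["absent"].passed_stage1
        assert ests["absent"].reported_abundance == 0.0


class TestSpeciesConsistency:
    def est(self, sid, ab):
        e = StrainEstimate(strain_id=sid, passed_stage2=True,
                           reported_abundance=ab)
        return e

    def test_equal_sums_no_action(self):
        recs, adj = species_consistency_filter(
            {1: 10.0}, {1: [self.est("a", 10.0)]})
        assert recs[0].d_species == 0.0
        assert not recs[0].removed and not recs[0].scaled
        assert adj == {(1, "a"): 10.0}

    def test_divergent_species_removed(self):
        # A=10, S=14 -> d = 4/14 = 0.2857 > 0.2
        recs, adj = species_consistency_filter(
            {1: 10.0}, {1: [self.est("a", 14.0)]})
        assert recs[0].d_species == pytest.approx(4 / 14)
        assert recs[0].removed
        assert adj == {}

    def test_overshoot_scaled_exactly(self):
        # A=10, S=11 -> d ~ 0.0909, retained, scaled by 10/11
        recs, adj = species_consistency_filter(
            {1: 10.0}, {1: [self.est("a", 6.0), self.est("b", 5.0)]})
        assert not recs[0].removed and recs[0].scaled
        assert sum(adj.values()) == pytest.approx(10.0)
        assert adj[(1, "a")] == pytest.approx(6.0 * 10 / 11)

    def test_undershoot_not_scaled(self):
        recs, adj = species_consistency_filter(
            {1: 10.0}, {1: [self.est("a", 9.5)]})
        assert not recs[0].scaled
        assert adj[(1, "a")] == 9.5


class TestFinalizeProfile:
    def test_single_strain(self):
        prof = finalize_profile({(1, "a"): 5.0})
        assert prof.rows == [(1, "a", 5.0, 1.0)]

    def test_ratio(self):
        prof = finalize_profile({(1, "a"): 2.0, (1, "b"): 6.0})
        rel = {sid: r for _, sid, _, r in prof.rows}
        assert rel == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_random_vectors_sum_to_one_and_preserve_ratios(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(1, 10))
            ab = {(1, f"s{i}"): float(rng.uniform(0.1, 50))
                  for i in range(n)}
            prof = finalize_profile(ab)
            rels = [r for *_, r in prof.rows]
            assert sum(rels) == pytest.approx(1.0, abs=1e-9)
            (k0, v0) = next(iter(ab.items()))
            rel_map = {(t, s): r for t, s, _, r in prof.rows}
            for k, v in ab.items():
                assert rel_map[k] / rel_map[k0] == pytest.approx(v / v0)
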