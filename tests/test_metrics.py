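"""Web descriptors: closed forms, brute-force oracles, invariances."""

import itertools
import math

import numpy as np
import pytest

from minewebs.metrics import (
    BipartiteMatrix,
    barber_modularity_q,
    bipartite_modularity,
    nodf,
    qualitative_from_counts,
    qualitative_metrics,
    quantitative_metrics,
)
from minewebs.web import TriPartiteWeb


def _web(pm=(), mp=(), dashed=(), mode="molecular"):
    return TriPartiteWeb(
        mode=mode,
        pm_edges={(a, b): w for a, b, w in pm},
        mp_edges={(a, b): w for a, b, w in mp},
        dashed_edges={(a, b): w for a, b, w in dashed},
    )


class TestQualitative:
    def test_one_plant_one_miner_closed_form(self):
        q = qualitative_metrics(_web(pm=[("p", "m", 3)]))
        assert q["ld_qual"] == 0.5
        assert q["vul_qual"] == 0.5
        assert q["conn_qual"] == 0.25

    def test_counts_formulae(self):
        q = qualitative_from_counts(29, 16, 16, 8)
        assert q["ld_qual"] == pytest.approx(29 / 40)
        assert q["conn_qual"] == pytest.approx(29 / 40 / 40)
        assert q["vul_qual"] == pytest.approx(29 / 32)
        assert q["gen_qual"] == pytest.approx(29 / 24)

    def test_dashed_links_counted_with_switch(self):
        web = _web(pm=[("p", "m", 1)], dashed=[("p", "h", 1)])
        with_d = qualitative_metrics(web, include_dashed=True)
        without = qualitative_metrics(web, include_dashed=False)
        assert with_d["n_links"] == 2 and without["n_links"] == 1
        assert with_d["n_species"] == 3 and without["n_species"] == 2

    def test_empty_web_rejected(self):
        with pytest.raises(ValueError):
            qualitative_metrics(_web())


class TestQuantitative:
    def test_uniform_star_effective_consumers(self):
        """One resource, four consumers, equal flows: the resource's
        effective consumer count is 2^log2(4) = 4."""
        web = _web(pm=[("r", f"c{i}", 5) for i in range(4)])
        q = quantitative_metrics(web)
        # vulnerability is the flow-weighted mean n_P over resources = 4
        assert q["vul_quant"] == pytest.approx(4.0)
        # each consumer has a single prey: generality 1
        assert q["gen_quant"] == pytest.approx(1.0)
        assert q["ld_quant"] == pytest.approx(2.5)

    def test_effective_number_bounded_by_richness(self, rng):
        """Effective partner counts never exceed realized partner counts
        (entropy maximised by the uniform distribution): over 200 random
        webs, quantitative generality <= the maximum prey richness."""
        for _ in range(200):
            n_p, n_m = rng.integers(2, 6), rng.integers(2, 6)
            pm = []
            for i in range(n_p):
                for j in range(n_m):
                    if rng.random() < 0.5:
                        pm.append((f"p{i}", f"m{j}", int(rng.integers(1, 9))))
            if not pm:
                continue
            q = quantitative_metrics(_web(pm=pm))
            prey_counts = {}
            for p, m, w in pm:
                prey_counts[m] = prey_counts.get(m, 0) + 1
            assert q["gen_quant"] <= max(prey_counts.values()) + 1e-12

    def test_skewed_flow_limits_to_one_partner(self):
        web = _web(pm=[("r", "c1", 9900), ("r", "c2", 100)])
        q = quantitative_metrics(web)
        assert 1.0 < q["vul_quant"] < 1.1

    def test_uniform_weights_match_qualitative_structure(self):
        """With all weights equal, each taxon's effective partner count
        equals its realized partner count."""
        pm = [("p1", "m1", 2), ("p1", "m2", 2), ("p2", "m2", 2)]
        web = _web(pm=pm)
        from minewebs.metrics import _flows, effective_numbers

        n_n, n_p = effective_numbers(_flows(web, True))
        assert n_p["P:p1"] == pytest.approx(2.0)   # p1 feeds two miners
        assert n_p["P:p2"] == pytest.approx(1.0)
        assert n_n["M:m2"] == pytest.approx(2.0)   # m2 eats two plants
        assert n_n["M:m1"] == pytest.approx(1.0)


def oracle_nodf(b: np.ndarray) -> float:
    """Brute-force pair enumeration straight from the definition."""
    terms = []
    for mat in (b, b.T):
        fills = mat.sum(axis=1)
        for i, j in itertools.combinations(range(mat.shape[0]), 2):
            hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
            if fills[hi] == fills[lo] or fills[lo] == 0:
                terms.append(0.0)
            else:
                terms.append(float((mat[hi] & mat[lo]).sum() / fills[lo]))
    return float(np.mean(terms))


class TestNODF:
    def test_packed_triangle_fully_nested(self):
        tri = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]])
        assert nodf(BipartiteMatrix(list("abc"), list("xyz"), tri)) == 1.0

    def test_checkerboard_identity_zero(self):
        assert nodf(BipartiteMatrix(list("ab"), list("xy"), np.eye(2))) == 0.0

    def test_matches_bruteforce_oracle_on_random_6x6(self, rng):
        for _ in range(50):
            b = (rng.random((6, 6)) < rng.uniform(0.2, 0.8)).astype(int)
            if b.sum() == 0:
                continue
            m = BipartiteMatrix([f"r{i}" for i in range(6)],
                                [f"c{i}" for i in range(6)], b)
            assert nodf(m) == pytest.approx(oracle_nodf(b), abs=1e-12)

    def test_percent_scale_flag(self):
        tri = np.array([[1, 1], [1, 0]])
        m = BipartiteMatrix(list("ab"), list("xy"), tri)
        assert nodf(m, scale="percent") == pytest.approx(100.0 * nodf(m))

    def test_monotone_under_nested_addition(self):
        """Restoring a presence inside an already-nested column profile never
        lowers NODF: enumerated over every single-presence deletion from the
        packed 4x4 triangle."""
        base = np.array([[1, 1, 1, 1],
                         [1, 1, 1, 0],
                         [1, 1, 0, 0],
                         [1, 0, 0, 0]])
        ids = list("abcd")
        full = nodf(BipartiteMatrix(ids, ids, base))
        for r in range(4):
            for c in range(4):
                if base[r, c] == 0:
                    continue
                degraded = base.copy()
                degraded[r, c] = 0
                assert full >= nodf(BipartiteMatrix(ids, ids, degraded)) - 1e-12

    def test_tiny_matrix_rejected(self):
        with pytest.raises(ValueError):
            nodf(BipartiteMatrix(["r"], ["c"], np.ones((1, 1))))


class TestModularity:
    def _blocks(self):
        w = np.zeros((4, 4))
        w[:2, :2] = 1.0
        w[2:, 2:] = 1.0
        return BipartiteMatrix([f"r{i}" for i in range(4)],
                               [f"c{i}" for i in range(4)], w)

    def test_two_equal_blocks_q_half(self):
        """Two disconnected complete blocks of equal weight: Q = 1/2."""
        q, labels = bipartite_modularity(self._blocks(), seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len({labels[f"r{i}"] for i in range(4)}) == 2

    def test_exhaustive_partition_search_confirms_optimum(self):
        """All 2^4 x 2^4 two-module assignments on the 4+4 block matrix:
        none beats the closed-form Q = 1/2."""
        m = self._blocks()
        best = -1.0
        for rows in itertools.product([0, 1], repeat=4):
            for cols in itertools.product([0, 1], repeat=4):
                q = barber_modularity_q(m, np.array(rows), np.array(cols))
                best = max(best, q)
        assert best == pytest.approx(0.5, abs=1e-12)

    def test_complete_bipartite_graph_q_zero(self):
        m = BipartiteMatrix(list("ab"), list("xy"), np.ones((2, 2)))
        q, _ = bipartite_modularity(m, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_greedy_dominates_random_partitions(self, rng):
        """The optimised Q is at least that of 1,000 random partitions."""
        w = (rng.random((5, 6)) < 0.5) * rng.integers(1, 5, size=(5, 6))
        if w.sum() == 0:
            w[0, 0] = 1
        m = BipartiteMatrix([f"r{i}" for i in range(5)],
                            [f"c{j}" for j in range(6)], w)
        q_best, _ = bipartite_modularity(m, seed=1)
        for _ in range(1000):
            rows = rng.integers(0, 6, size=5)
            cols = rng.integers(0, 6, size=6)
            assert barber_modularity_q(m, rows, cols) <= q_best + 1e-12

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            bipartite_modularity(
                BipartiteMatrix(list("ab"), list("xy"), np.zeros((2, 2))))


def test_metrics_invariant_under_node_relabeling(rng):
    pm = [("p1", "m1", 2), ("p1", "m2", 4), ("p2", "m2", 1), ("p3", "m3", 5)]
    mp = [("m1", "h1", 2), ("m2", "h2", 3)]
    web = _web(pm=pm, mp=mp)
    ren = {n: f"node-{n}" for n in
           ("p1", "p2", "p3", "m1", "m2", "m3", "h1", "h2")}
    web2 = _web(pm=[(ren[a], ren[b], w) for a, b, w in pm],
                mp=[(ren[a], ren[b], w) for a, b, w in mp])
    for fn in (qualitative_metrics, quantitative_metrics):
        q1, q2 = fn(web), fn(web2)
        for k in q1:
            assert q1[k] == pytest.approx(q2[k], abs=1e-12)
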