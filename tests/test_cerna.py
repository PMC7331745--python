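"""Shared-miRNA scoring against an enumeration oracle; network assembly."""

from itertools import combinations

import pytest

from cernet import (CoexprEdge, DERecord, TargetPair, build_cerna_network,
                    cerna_score, filter_targets_by_coexpression)


def oracle_hypergeom_tail(k: int, M: int, K: int, n: int) -> float:
    """P(|draw ∩ successes| >= k) by exhaustive enumeration of all C(M, n)
    draws from a universe of M items whose first K are successes."""
    successes = set(range(K))
    hits = total = 0
    for draw in combinations(range(M), n):
        total += 1
        hits += len(successes & set(draw)) >= k
    return hits / total


def _pair(mi, tg, cls="circRNA"):
    return TargetPair(mi, tg, cls, 1, 150.0, -30.0)


def _edge(mi, tg, cls="circRNA", r=-0.95, sign="negative"):
    return CoexprEdge(mi, "miRNA", tg, cls, r, 0.01, sign)


def _de(fid, cls, direction):
    lfc = 2.0 if direction == "up" else -2.0
    return DERecord(fid, cls, lfc, 0.01, 0.02, direction, 4.0, 1.0)


class TestCernaScore:
    def test_zero_overlap_gives_p_one(self):
        k, p = cerna_score({"a", "b"}, {"c", "d"}, M=10)
        assert k == 0 and p == 1.0

    def test_matches_enumeration_on_worked_instance(self):
        # M=10, K=4, n=5, k=3: compare against all C(10,5)=252 draws
        circ = {f"m{i}" for i in range(4)}
        mrna = {f"m{i}" for i in range(3)} | {"x", "y"}
        k, p = cerna_score(circ, mrna, M=10)
        assert k == 3
        assert p == pytest.approx(oracle_hypergeom_tail(3, 10, 4, 5), rel=1e-12)

    def test_saturation(self):
        full = {f"m{i}" for i in range(6)}
        k, p = cerna_score(full, full, M=6)
        assert k == 6 and p == pytest.approx(1.0)

    def test_universe_smaller_than_partner_set_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            cerna_score({"a", "b", "c"}, {"a"}, M=2)

    @pytest.mark.parametrize("M", [4, 6, 8])
    def test_enumeration_equivalence_small_universes(self, M):
        for K in range(M + 1):
            for n in range(M + 1):
                circ = {f"m{i}" for i in range(K)}
                mrna = {f"m{i}" for i in range(n)}  # maximal overlap
                k, p = cerna_score(circ, mrna, M)
                assert k == min(K, n)
                assert p == pytest.approx(
                    oracle_hypergeom_tail(k, M, K, n), rel=1e-9)


class TestValidatedPairs:
    def test_exact_intersection(self):
        pairs = [_pair("m1", "t1"), _pair("m1", "t2")]
        edges = [_edge("m1", "t1"), _edge("m2", "t1")]
        out = filter_targets_by_coexpression(pairs, edges)
        assert [(v.mirna_id, v.target_id) for v in out] == [("m1", "t1")]
        assert out[0].r == -0.95 and out[0].best_score == 150.0

    def test_disjoint_inputs_are_empty(self):
        assert filter_targets_by_coexpression(
            [_pair("m1", "t1")], [_edge("m2", "t2")]) == []

    def test_edge_orientation_does_not_matter(self):
        flipped = CoexprEdge("t1", "circRNA", "m1", "miRNA", -0.95, 0.01,
                             "negative")
        out = filter_targets_by_coexpression([_pair("m1", "t1")], [flipped])
        assert len(out) == 1

    def test_positive_edges_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            filter_targets_by_coexpression(
                [_pair("m1", "t1")], [_edge("m1", "t1", r=0.95, sign="positive")])

    def test_output_bounded_by_inputs(self):
        pairs = [_pair(f"m{i}", f"t{j}") for i in range(3) for j in range(3)]
        edges = [_edge("m0", "t0"), _edge("m1", "t1")]
        out = filter_targets_by_coexpression(pairs, edges)
        assert len(out) <= min(len(pairs), len(edges))


def _network_inputs(M=20):
    from cernet.cerna import ValidatedPair

    # c1 shares m1 and m2 with g1; M-2 further DE miRNAs fill the universe
    vc = [ValidatedPair("m1", "c1", "circRNA", -0.95, 0.01, 150, -30),
          ValidatedPair("m2", "c1", "circRNA", -0.93, 0.02, 150, -30)]
    vm = [ValidatedPair("m1", "g1", "mRNA", -0.94, 0.01, 150, -30),
          ValidatedPair("m2", "g1", "mRNA", -0.92, 0.02, 150, -30)]
    cm = [CoexprEdge("c1", "circRNA", "g1", "mRNA", 0.97, 0.001, "positive")]
    de = {
        "circRNA": [_de("c1", "circRNA", "up")],
        "mRNA": [_de("g1", "mRNA", "up")],
        "miRNA": [_de("m1", "miRNA", "down"), _de("m2", "miRNA", "down")] +
                 [_de(f"mx{i}", "miRNA", "up") for i in range(M - 2)],
    }
    return vc, vm, cm, de


class TestBuildNetwork:
    def test_planted_hand_network_is_recovered(self):
        vc, vm, cm, de = _network_inputs()
        candidates, triplets = build_cerna_network(vc, vm, cm, de)
        assert len(candidates) == 1
        c = candidates[0]
        assert (c.k, c.K, c.n, c.M) == (2, 2, 2, 20)
        assert c.p_hyper < 0.05
        assert [(t.circ_id, t.mirna_id, t.mrna_id) for t in triplets] == \
               [("c1", "m1", "g1"), ("c1", "m2", "g1")]

    def test_empty_circ_mrna_edges_dominate(self):
        vc, vm, _, de = _network_inputs()
        _, triplets = build_cerna_network(vc, vm, [], de)
        assert triplets == []

    def test_direction_violation_dropped(self):
        vc, vm, cm, de = _network_inputs()
        # make m2 move with the circRNA: its triplet must be excluded
        de["miRNA"][1] = _de("m2", "miRNA", "up")
        _, triplets = build_cerna_network(vc, vm, cm, de)
        assert [(t.mirna_id) for t in triplets] == ["m1"]

    def test_missing_de_record_is_named(self):
        vc, vm, cm, de = _network_inputs()
        de["mRNA"] = []
        with pytest.raises(KeyError, match="g1"):
            build_cerna_network(vc, vm, cm, de)

    def test_small_universe_kills_significance(self):
        # with M=4 the best achievable tail probability for k=K=n=2 is
        # C(2,2)/C(4,2) = 1/6 > 0.05: no candidate may pass
        vc, vm, cm, de = _network_inputs(M=4)
        candidates, triplets = build_cerna_network(vc, vm, cm, de)
        assert candidates == [] and triplets == []

    def test_relaxing_alpha_is_monotone(self):
        vc, vm, cm, de = _network_inputs(M=8)
        strict, t_strict = build_cerna_network(vc, vm, cm, de, alpha=0.02)
        loose, t_loose = build_cerna_network(vc, vm, cm, de, alpha=0.5)
        key = lambda c: (c.circ_id, c.mrna_id)
        assert {key(c) for c in strict} <= {key(c) for c in loose}
        assert len(t_strict) <= len(t_loose)

    def test_k_min_filters_low_overlap(self):
        vc, vm, cm, de = _network_inputs()
        c1, _ = build_cerna_network(vc, vm, cm, de, k_min=2)
        c2, _ = build_cerna_network(vc, vm, cm, de, k_min=3)
        assert len(c1) == 1 and c2 == []

    def test_referential_integrity_on_simulated_run(self, default_dataset):
        from cernet import analyze

        ds = default_dataset
        res = analyze(ds.circ, ds.mrna, ds.mirna, ds.mirna_fa, ds.target_fa)
        vc = {(v.mirna_id, v.target_id) for v in res.validated_circ}
        vm = {(v.mirna_id, v.target_id) for v in res.validated_mrna}
        cm = {(e.a_id, e.b_id) for e in res.edges_circ_mrna}
        for t in res.triplets:
            assert (t.mirna_id, t.circ_id) in vc
            assert (t.mirna_id, t.mrna_id) in vm
            assert (t.circ_id, t.mrna_id) in cm
            assert t.circ_direction == t.mrna_direction != t.mirna_direction
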