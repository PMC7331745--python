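"""Seed matching, the duplex aligner against a brute-force oracle, energies,
site prediction on planted sequences, and pair collapse."""

import dataclasses
from functools import lru_cache

import numpy as np
import pytest

from cernet import (AlignParams, SeqRecord, SimulationConfig, collapse_to_pairs,
                    duplex_align, duplex_energy, predict_mres, seed_match,
                    simulate_dataset)
from cernet.mre_prediction import MRE, revcomp

PARAMS = AlignParams()


# ---------------------------------------------------------------------------
# independent alignment oracle: exhaustive search over monotone chains of
# aligned base pairs, with affine costs charged per gap run between pairs
# ---------------------------------------------------------------------------

def oracle_best_score(mirna_seq: str, window: str, params: AlignParams = PARAMS
                      ) -> float:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    m_rev = mirna_seq[::-1]
    n_m, n_t = len(m_rev), len(window)

    def pair_score(i, j):
        a, b = m_rev[i], window[j]
        if comp[a] == b:
            s = params.match
        elif (a, b) in (("G", "U"), ("U", "G")):
            s = params.wobble
        else:
            s = params.mismatch
        pos1 = n_m - i  # 1-based miRNA position
        lo, hi = params.seed_span
        return s * params.seed_multiplier if lo <= pos1 <= hi else s

    def gap_cost(run):
        return params.gap_open + params.gap_extend * (run - 1)

    @lru_cache(maxsize=None)
    def best_from(i, j):
        # best alignment score starting with the pair (i, j); it may stop
        # after any pair (local alignment)
        s = pair_score(i, j)
        ext = 0.0
        for i2 in range(i + 1, n_m):
            for j2 in range(j + 1, n_t):
                g = 0.0
                if i2 - i - 1:
                    g += gap_cost(i2 - i - 1)
                if j2 - j - 1:
                    g += gap_cost(j2 - j - 1)
                ext = max(ext, g + best_from(i2, j2))
        return s + ext

    best = 0.0
    for i in range(n_m):
        for j in range(n_t):
            best = max(best, best_from(i, j))
    return best


def _rand_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestSeedMatch:
    def test_perfect_full_complement_yields_8mer(self):
        m = SeqRecord("mi", "UGGAAUGUAAGG", "miRNA")
        t = SeqRecord("t", revcomp(m.seq), "mRNA_target")
        sites = seed_match(m, t)
        # seed core sits 7 nt from the 3' end of the site; A faces position 1
        L = len(m.seq)
        assert (L - 8, L, "8mer") in sites

    def test_no_complementarity_yields_nothing(self):
        m = SeqRecord("mi", "A" * 12, "miRNA")
        t = SeqRecord("t", "A" * 40, "mRNA_target")
        assert seed_match(m, t) == []

    def test_hand_built_7mer_m8(self):
        # miRNA positions 2-8 = GGAAUGU; revcomp = ACAUUCC on the target
        m = SeqRecord("mi", "UGGAAUGUAAGG", "miRNA")
        t = SeqRecord("t", "GGGUUACAUUCCGGG", "mRNA_target")
        assert seed_match(m, t) == [(5, 12, "7mer-m8")]

    def test_brute_force_window_scan_agrees(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            m = SeqRecord("mi", _rand_rna(rng, 22), "miRNA")
            t = SeqRecord("t", _rand_rna(rng, 120), "mRNA_target")
            core = revcomp(m.seq[1:7])
            expected_starts = sorted(
                i for i in range(len(t.seq) - 5) if t.seq[i:i + 6] == core)
            got = seed_match(m, t)
            got_cores = sorted(s if typ in ("6mer", "7mer-A1") else s + 1
                               for s, _, typ in got)
            assert got_cores == expected_starts

    def test_too_short_target_is_empty(self):
        m = SeqRecord("mi", "UGGAAUGUAAGG", "miRNA")
        assert seed_match(m, SeqRecord("t", "ACGU", "mRNA_target")) == []


class TestDuplexAlign:
    def test_eight_nt_perfect_duplex_in_seed_scores_80(self):
        m = SeqRecord("mi", "UGGAAUGU", "miRNA")  # 8 nt, all in doubled span
        score, pairs = duplex_align(m, revcomp(m.seq))
        assert score == 80.0  # 8 pairs x (+5) x2 seed weighting
        assert len(pairs) == 8 and all(k in ("GC", "AU") for _, _, k in pairs)

    def test_no_positive_pair_floors_at_zero(self):
        m = SeqRecord("mi", "AAAAAAAA", "miRNA")
        score, pairs = duplex_align(m, "AAAAAAAA")
        assert score == 0.0 and pairs == []

    def test_window_cap_enforced(self):
        m = SeqRecord("mi", "UGGAAUGU", "miRNA")
        with pytest.raises(ValueError, match="tile"):
            duplex_align(m, "A" * 81)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n_m = int(rng.integers(6, 13))
            n_t = int(rng.integers(6, 13))
            m = SeqRecord("mi", _rand_rna(rng, n_m), "miRNA")
            t = _rand_rna(rng, n_t)
            dp, _ = duplex_align(m, t)
            assert dp == oracle_best_score(m.seq, t)

    def test_traceback_score_consistent_with_pairs(self):
        rng = np.random.default_rng(29)
        lo, hi = PARAMS.seed_span
        for _ in range(50):
            m = SeqRecord("mi", _rand_rna(rng, 12), "miRNA")
            t = _rand_rna(rng, 20)
            score, pairs = duplex_align(m, t)
            total = 0.0
            for pos, _, kind in pairs:
                if kind == "gap":
                    continue
                s = {"GC": 5.0, "AU": 5.0, "GU": 2.0, "mismatch": -3.0}[kind]
                total += s * 2 if lo <= pos <= hi else s
            # gaps: charge runs
            runs, prev_gap = [], False
            for pos, tpos, kind in pairs:
                if kind == "gap":
                    if prev_gap:
                        runs[-1] += 1
                    else:
                        runs.append(1)
                    prev_gap = True
                else:
                    prev_gap = False
            total += sum(-8.0 - 2.0 * (r - 1) for r in runs)
            assert total == pytest.approx(score)


class TestDuplexEnergy:
    def test_ten_gc_pairs(self):
        assert duplex_energy([(i, i, "GC") for i in range(10)]) == -30.0

    def test_empty_alignment(self):
        assert duplex_energy([]) == 0.0

    def test_gu_additivity(self):
        base = [(1, 1, "AU"), (2, 2, "GC")]
        assert duplex_energy(base + [(3, 3, "GU")]) == duplex_energy(base) - 1.0

    def test_mismatch_and_gap_penalize(self):
        assert duplex_energy([(1, 1, "mismatch"), (-1, 2, "gap")]) == 1.0


class TestPredictMres:
    def test_planted_sites_recovered_exactly_at_default_thresholds(
            self, default_dataset):
        ds = default_dataset
        mir = {r.id: r for r in ds.mirna_fa}
        tgt = {r.id: r for r in ds.target_fa}
        for site in ds.truth.planted_sites:
            mres = predict_mres([mir[site.mirna_id]], [tgt[site.target_id]])
            hits = [m for m in mres if (m.start, m.end) == (site.start, site.end)]
            assert len(hits) == 1, site
            assert hits[0].align_score >= 140.0
            assert hits[0].energy <= -20.0

    def test_infinite_score_min_empties_output(self, default_dataset):
        ds = default_dataset
        mres = predict_mres(ds.mirna_fa[:3], ds.target_fa[:3],
                            score_min=float("inf"))
        assert mres == []

    def test_tighter_thresholds_are_monotone(self, default_dataset):
        ds = default_dataset
        mirnas, targets = ds.mirna_fa[:6], ds.target_fa[:10]
        loose = predict_mres(mirnas, targets, score_min=60, energy_max=-5)
        mid = predict_mres(mirnas, targets, score_min=100, energy_max=-5)
        tight = predict_mres(mirnas, targets, score_min=100, energy_max=-25)
        assert len(loose) >= len(mid) >= len(tight)
        key = lambda m: (m.mirna_id, m.target_id, m.start)
        assert {key(m) for m in tight} <= {key(m) for m in mid} <= {key(m) for m in loose}

    def test_order_invariance_to_input_shuffling(self, default_dataset):
        rng = np.random.default_rng(3)
        ds = default_dataset
        mirnas, targets = list(ds.mirna_fa[:6]), list(ds.target_fa[:8])
        ref = predict_mres(mirnas, targets, score_min=60, energy_max=-5)
        rng.shuffle(mirnas)
        rng.shuffle(targets)
        assert predict_mres(mirnas, targets, score_min=60, energy_max=-5) == ref

    def test_shuffled_targets_rarely_hit_at_default_thresholds(
            self, default_dataset):
        rng = np.random.default_rng(31)
        ds = default_dataset
        mirnas = ds.mirna_fa[:12]
        shuffled = []
        for r in ds.target_fa[:40]:
            seq = "".join(rng.permutation(list(r.seq)))
            shuffled.append(SeqRecord(r.id, seq, r.moltype))
        mres = predict_mres(mirnas, shuffled)
        hit_pairs = {(m.mirna_id, m.target_id) for m in mres}
        assert len(hit_pairs) / (len(mirnas) * len(shuffled)) < 0.05

    def test_junction_spanning_site_on_circular_target(self):
        rng = np.random.default_rng(37)
        m = SeqRecord("mi", _rand_rna(rng, 22), "miRNA")
        block = revcomp(m.seq)
        # place the site across the backsplice junction: last 10 nt at the
        # end of the sequence, remaining 12 nt wrapping to the start
        body = _rand_rna(rng, 80)
        seq = block[10:] + body + block[:10]
        circ = SeqRecord("c", seq, "circRNA_target")
        mres = predict_mres([m], [circ])
        # the seed portion of the wrapped site lies just past the junction:
        # miRNA positions 2-7 pair target positions 5..10 of the circle
        exp_end = 12 if m.seq[0] == "U" else 11
        assert [(s.start, s.end) for s in mres] == [(4, exp_end)]
        assert mres[0].align_score >= 140.0
        # a linear read of the same sequence misses the junction site
        linear = SeqRecord("c", seq, "mRNA_target")
        assert predict_mres([m], [linear]) == []


class TestCollapse:
    def _mre(self, mi, tg, start, score, energy):
        return MRE(mi, tg, "mRNA", start, start + 7, "7mer-m8", score, energy)

    def test_grouping_and_best_fields(self):
        mres = [self._mre("m1", "t1", 0, 150, -25),
                self._mre("m1", "t1", 40, 160, -22),
                self._mre("m1", "t1", 90, 145, -30),
                self._mre("m1", "t2", 5, 141, -21)]
        pairs = collapse_to_pairs(mres)
        assert [(p.mirna_id, p.target_id, p.n_sites) for p in pairs] == \
               [("m1", "t1", 3), ("m1", "t2", 1)]
        assert pairs[0].best_score == 160 and pairs[0].best_energy == -30

    def test_empty_input(self):
        assert collapse_to_pairs([]) == []

    def test_pair_count_bounded_by_site_count(self, default_dataset):
        ds = default_dataset
        mres = predict_mres(ds.mirna_fa[:8], ds.target_fa[:12],
                            score_min=60, energy_max=-5)
        pairs = collapse_to_pairs(mres)
        assert len(pairs) <= len(mres)
        assert sum(p.n_sites for p in pairs) == len(mres)
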