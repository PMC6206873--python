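"""Duplex alignment, the six target rules, energies, UTR scanning."""

import numpy as np
import pytest

from koisrna.targets import (align_duplex, duplex_energy, evaluate_rules,
                             evaluate_site, load_energy_params, merge_overlapping,
                             perfect_complement, scan_utr)

GUIDE = "TGAGGTAGTAGGTTGTATAGTT"          # 22 nt


def site_with(guide, changes):
    """Perfect site with planted per-position states (test-local helper)."""
    compl = {"A": "T", "T": "A", "G": "C", "C": "G"}
    wob = {"G": "T", "T": "G"}
    site = [compl[b] for b in reversed(guide)]
    for pos, kind in changes.items():
        j = len(guide) - pos
        if kind == "GU":
            site[j] = wob[guide[pos - 1]]
        else:
            site[j] = kind
    return "".join(site)


class TestAlignDuplex:
    def test_perfect_complement_all_wc(self):
        d = align_duplex(GUIDE, perfect_complement(GUIDE))
        assert set(d.states) == {"WC"}
        assert d.weighted_mismatch_score == 0.0

    def test_single_opposition_scores_one(self):
        site = site_with(GUIDE, {6: "C"})      # guide pos 6 = T; T:C mismatch
        d = align_duplex(GUIDE, site)
        assert d.states[5] == "MM"
        assert d.weighted_mismatch_score == 1.0

    @pytest.mark.parametrize("pos", [2, 15])
    def test_gu_wobble_scores_half(self, pos):
        # guide positions 2 and 15 are G/T-capable in GUIDE
        assert GUIDE[pos - 1] in "GT"
        d = align_duplex(GUIDE, site_with(GUIDE, {pos: "GU"}))
        assert d.states[pos - 1] == "GU"
        assert d.weighted_mismatch_score == 0.5

    def test_register_shift_minimizes_score(self):
        d = align_duplex(GUIDE, perfect_complement(GUIDE) + "ACG")
        assert d.weighted_mismatch_score == 0.0 and d.offset == 3
        d0 = align_duplex(GUIDE, "ACG" + perfect_complement(GUIDE))
        assert d0.weighted_mismatch_score == 0.0 and d0.offset == 0

    def test_length_gap_limit(self):
        with pytest.raises(ValueError):
            align_duplex(GUIDE, perfect_complement(GUIDE) + "ACGT")

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            align_duplex("ACGTN" + GUIDE[5:], perfect_complement(GUIDE))

    def test_score_additivity(self, rng):
        for _ in range(20):
            site = site_with(GUIDE, {int(rng.integers(1, 23)): "A"})
            d = align_duplex(GUIDE, site)
            assert d.weighted_mismatch_score == d.recount_score()


class TestRules:
    def test_perfect_duplex_passes_all(self):
        v = evaluate_rules(align_duplex(GUIDE, perfect_complement(GUIDE)))
        assert (v.r1, v.r2, v.r3, v.r4, v.r5) == (True,) * 5

    def test_five_mismatches_fail_r1(self):
        site = site_with(GUIDE, {p: "C" if GUIDE[p - 1] != "G" else "A"
                                 for p in (13, 15, 17, 19, 21)})
        v = evaluate_rules(align_duplex(GUIDE, site))
        assert not v.r1

    def test_single_mismatch_at_ten_fails_r4_only_positionals(self):
        site = site_with(GUIDE, {10: "C" if GUIDE[9] != "G" else "A"})
        v = evaluate_rules(align_duplex(GUIDE, site))
        assert not v.r4
        assert v.r1 and v.r5 and v.r3

    def test_eight_wobbles_at_r1_boundary(self):
        # hand-built guide: G at every even position so eight isolated
        # wobbles reach exactly score 4.0 (r1 boundary, still passing)
        guide = "AGAGAGAGAGAGAGAGAGAGAG"
        positions = [2, 4, 6, 8, 14, 16, 18, 20]
        site = site_with(guide, {p: "GU" for p in positions})
        d = align_duplex(guide, site)
        assert d.weighted_mismatch_score == 4.0
        v = evaluate_rules(d)
        assert v.r1 and v.r3 and v.r4

    def test_run_of_three_fails_r2(self):
        site = site_with(GUIDE, {p: "A" if GUIDE[p - 1] != "T" else "C"
                                 for p in (15, 16, 17)})
        v = evaluate_rules(align_duplex(GUIDE, site))
        assert not v.r2

    def test_adjacent_seed_mismatches_fail_r3(self):
        site = site_with(GUIDE, {5: "A", 6: "C"})   # G:A and T:C oppositions
        v = evaluate_rules(align_duplex(GUIDE, site))
        assert not v.r3

    def test_lenient_gu_mode_ignores_wobble_adjacency(self):
        site = site_with(GUIDE, {4: "GU", 5: "GU"})  # adjacent G positions
        strict = evaluate_rules(align_duplex(GUIDE, site), strict_gu=True)
        lenient = evaluate_rules(align_duplex(GUIDE, site), strict_gu=False)
        assert not strict.r3 and lenient.r3


class TestEnergy:
    def test_perfect_duplex_ratio_one(self):
        e = duplex_energy(GUIDE, perfect_complement(GUIDE))
        assert e.ratio == 1.0 and e.duplex_mfe < 0

    def test_two_stack_toy_duplex_is_hand_sum(self):
        p = load_energy_params()
        guide = "GCA"
        e = duplex_energy(guide, perfect_complement(guide))
        assert e.duplex_mfe == pytest.approx(
            min(0.0, p.stacks["GC"] + p.stacks["CA"] + p.init))

    def test_half_broken_duplex_fails_ratio(self):
        site = site_with(GUIDE, {p: ("C" if GUIDE[p - 1] in "AT" else "A")
                                 for p in range(2, 22, 2)})
        e = duplex_energy(GUIDE, site)
        assert e.ratio < 0.75

    def test_no_pairs_is_undefined(self):
        with pytest.raises(ValueError):
            duplex_energy("AAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAA")

    def test_gu_to_wc_monotone(self, rng):
        """Fixing any wobble to Watson-Crick never hurts rules or ratio."""
        for _ in range(30):
            guide = "".join(rng.choice(list("ACGT"), size=22))
            wob_pos = [p for p in range(1, 23) if guide[p - 1] in "GT"]
            picked = list(rng.choice(wob_pos, size=min(4, len(wob_pos)),
                                     replace=False))
            site_gu = site_with(guide, {p: "GU" for p in picked})
            site_wc = site_with(guide, {p: "GU" for p in picked[1:]})
            _, v_gu, e_gu = evaluate_site(guide, site_gu)
            _, v_wc, e_wc = evaluate_site(guide, site_wc)
            for r in ("r1", "r2", "r3", "r4", "r5", "r6"):
                assert getattr(v_wc, r) >= getattr(v_gu, r)
            assert e_wc.ratio >= e_gu.ratio - 1e-12


def oracle_scan(guide, tx, strict_gu=True, min_ratio=0.75):
    """Exhaustive all-window oracle with its own quadratic merge."""
    passing = []
    L = len(guide)
    for wlen in range(L - 2, L + 3):
        for start in range(0, len(tx) - wlen + 1):
            site = tx[start:start + wlen]
            d, v, e = evaluate_site(guide, site, strict_gu, min_ratio)
            if v.overall:
                passing.append((start, start + wlen, d, e))
    chosen = []
    used = [False] * len(passing)
    # transitively cluster overlapping windows, pick the best per cluster
    for i in range(len(passing)):
        if used[i]:
            continue
        cluster = [i]
        used[i] = True
        changed = True
        while changed:
            changed = False
            for j in range(len(passing)):
                if not used[j] and any(passing[j][0] < passing[k][1]
                                       and passing[k][0] < passing[j][1]
                                       for k in cluster):
                    cluster.append(j)
                    used[j] = True
                    changed = True
        best = min(cluster, key=lambda k: (
            passing[k][2].weighted_mismatch_score, passing[k][3].duplex_mfe,
            abs(len(passing[k][2].site) - L), passing[k][0]))
        chosen.append((passing[best][0], passing[best][1]))
    return sorted(chosen)


class TestScan:
    def test_planted_perfect_site_found_at_coordinates(self, rng):
        tx = "".join(rng.choice(list("ACGT"), size=500))
        tx = tx[:200] + perfect_complement(GUIDE) + tx[200 + 22:]
        preds = scan_utr(GUIDE, tx)
        assert len(preds) == 1
        assert (preds[0].start, preds[0].end) == (200, 222)
        assert preds[0].energy.ratio == 1.0

    def test_scan_matches_exhaustive_oracle(self, rng):
        for _ in range(3):
            tx = "".join(rng.choice(list("ACGT"), size=600))
            pos = int(rng.integers(50, 500))
            tx = tx[:pos] + perfect_complement(GUIDE) + tx[pos + 22:]
            got = sorted((p.start, p.end) for p in scan_utr(GUIDE, tx))
            assert got == oracle_scan(GUIDE, tx)

    def test_rule4_violating_site_not_predicted(self):
        site = site_with(GUIDE, {10: "C" if GUIDE[9] != "G" else "A"})
        tx = ("ACGT" * 50) + site + ("TGCA" * 50)
        assert scan_utr(GUIDE, tx) == []

    def test_reverse_complement_identity(self, rng):
        tx = "".join(rng.choice(list("ACGT"), size=300)) + perfect_complement(GUIDE)
        preds = scan_utr(GUIDE, tx)
        assert any(p.energy.ratio == 1.0 for p in preds)
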