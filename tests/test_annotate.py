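"""Hierarchical annotation, conserved-miRNA calling and family clustering."""

import numpy as np
import pytest

from koisrna.annotate import (Hit, ReferenceSet, assign_hierarchy,
                              annotation_summary_from_counts,
                              call_conserved_mirnas, cluster_families,
                              family_name, format_percentage, map_sequences,
                              revcomp, screen_novel_candidates,
                              summarize_annotation, PRIORITY)
from koisrna.preprocess import SmallRNALibrary


def oracle_search(query, refs, max_mm):
    """Exhaustive position-by-position Hamming search over both strands."""
    hits = []
    for rid, ref in refs.items():
        for oriented, strand in ((query, "+"), (revcomp(query), "-")):
            for pos in range(len(ref) - len(oriented) + 1):
                d = sum(a != b for a, b in zip(oriented, ref[pos:pos + len(oriented)]))
                if d <= max_mm:
                    hits.append((rid, pos, strand, d))
    if not hits:
        return set()
    dmin = min(h[3] for h in hits)
    return {h for h in hits if h[3] == dmin}


class TestMapSequences:
    def test_exact_hit(self):
        ref = ReferenceSet("known_miRNA",
                           sequences={"m1": "TGAGGTAGTAGGTTGTATAGTT"})
        hits = map_sequences(["TGAGGTAGTAGGTTGTATAGTT"], ref, 1, both_strands=False)
        assert len(hits) == 1 and hits[0].mismatches == 0

    def test_distance_two_rejected_at_tolerance_one(self):
        ref = ReferenceSet("known_miRNA",
                           sequences={"m1": "TGAGGTAGTAGGTTGTATAGTT"})
        hits = map_sequences(["AGAGGTAGTAGGTTGTATAGTA"], ref, 1, both_strands=False)
        assert hits == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_exhaustive_oracle_on_toy_genome(self, rng, max_mm):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=5000))}
        ref = ReferenceSet("genome", sequences=genome)
        queries = []
        for _ in range(40):
            queries.append("".join(rng.choice(list("ACGT"), size=22)))
        for _ in range(10):     # planted (possibly mutated) genome substrings
            pos = rng.integers(0, 5000 - 22)
            q = list(genome["chr1"][pos:pos + 22])
            for _ in range(rng.integers(0, 3)):
                i = rng.integers(22)
                q[i] = rng.choice([b for b in "ACGT" if b != q[i]])
            queries.append("".join(q))
        hits = map_sequences(queries, ref, max_mm)
        got = {}
        for h in hits:
            got.setdefault(h.query, set()).add((h.ref_id, h.position, h.strand,
                                                h.mismatches))
        for q in queries:
            assert got.get(q, set()) == oracle_search(q, genome, max_mm), q


class TestAssignHierarchy:
    def test_genbank_outranks_known_mirna(self):
        seq = "A" * 22
        hits = {"genbank_ncRNA": [Hit(seq, "rRNA_1", 0, "+", 1)],
                "known_miRNA": [Hit(seq, "mir-1", 0, "+", 0)]}
        a = assign_hierarchy(hits, [seq])[seq]
        assert a.category == "genbank_ncRNA"

    def test_intron_only(self):
        seq = "C" * 22
        a = assign_hierarchy({"intron": [Hit(seq, "chr1", 5, "+", 0)]}, [seq])[seq]
        assert a.category == "intron"

    def test_no_hits_is_other(self):
        a = assign_hierarchy({}, ["G" * 22])["G" * 22]
        assert a.category == "other" and a.best_hit is None

    def test_randomized_tables_match_priority_argmax(self, rng):
        cats = list(PRIORITY)
        for trial in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            present = [c for c in cats if rng.random() < 0.4]
            hits = {c: [Hit(seq, f"{c}_ref", 0, "+", int(rng.integers(0, 2)))]
                    for c in present}
            a = assign_hierarchy(hits, [seq])[seq]
            expected = next((c for c in PRIORITY if c in present), "other")
            assert a.category == expected

    def test_lower_priority_hit_never_changes_assignment(self, rng):
        seq = "T" * 22
        hits = {"rfam_ncRNA": [Hit(seq, "snRNA_1", 0, "+", 0)]}
        before = assign_hierarchy(hits, [seq])[seq].category
        hits["intron"] = [Hit(seq, "chr1", 9, "+", 0)]
        after = assign_hierarchy(hits, [seq])[seq].category
        assert before == after == "rfam_ncRNA"

    def test_single_assignment_per_sequence(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(30)]
        hits = {"exon": [Hit(s, "chr1", 0, "+", 0) for s in seqs[:20]]}
        out = assign_hierarchy(hits, seqs)
        assert len(out) == len(seqs)


class TestSummaries:
    def test_percentages_at_table_precision(self):
        df = annotation_summary_from_counts(
            {"tRNA": 173_761, "rRNA": 175_928}, 19_649_441)
        by = df.set_index("category")
        assert by.loc["tRNA", "percent_str"] == "0.88"
        assert by.loc["rRNA", "percent_str"] == "0.90"

    def test_zero_category_renders_three_decimals(self):
        df = annotation_summary_from_counts({"snRNA": 0}, 1000)
        assert df.iloc[0]["percent_str"] == "0.000"

    def test_format_switchover(self):
        assert format_percentage(0.0999) == "0.100"
        assert format_percentage(0.1) == "0.10"

    def test_summarize_uses_library_counts(self):
        lib = SmallRNALibrary({"A" * 22: 30, "C" * 22: 70}, 100, "x")
        assigns = assign_hierarchy(
            {"exon": [Hit("A" * 22, "chr1", 0, "+", 0)]}, list(lib.entries))
        df = summarize_annotation(assigns, lib).set_index("category")
        assert df.loc["exon", "reads"] == 30
        assert df.loc["other", "reads"] == 70


LET7A = "TGAGGTAGTAGGTTGTATAGTT"


class TestConservedCalling:
    def test_identical_read_called_conserved(self):
        recs = call_conserved_mirnas({LET7A: 12}, {"ccr-let-7a": LET7A})
        assert len(recs) == 1
        assert recs[0].name == "ccr-let-7a"
        assert recs[0].status == "known_carp"
        assert recs[0].counts == {"lib": 12}

    def test_three_substitutions_not_called(self):
        q = "AGAGGTAGTAGGTTGTATACTA"     # 3 mismatches vs LET7A
        assert call_conserved_mirnas({q: 5}, {"ccr-let-7a": LET7A}) == []

    def test_planted_variant_pool_matches_truth(self, rng):
        ref = {"dre-miR-200b": "".join(rng.choice(list("ACGT"), size=22))}
        seq = ref["dre-miR-200b"]
        variants = {}
        truth_called = {}
        for n_mm in (0, 1, 2, 3):
            q = list(seq)
            for i in range(n_mm):
                pos = 2 * i
                q[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[q[pos]]
            qs = "".join(q)
            variants[qs] = 10 + n_mm
            truth_called[qs] = n_mm <= 2
        recs = call_conserved_mirnas(variants, ref)
        called = set(recs[0].variant_sequences) if recs else set()
        assert called == {q for q, ok in truth_called.items() if ok}
        assert recs[0].counts["lib"] == sum(v for q, v in variants.items()
                                            if truth_called[q])
        assert recs[0].status == "conserved"

    def test_three_prime_length_slack(self):
        recs = call_conserved_mirnas({LET7A[:-2]: 1}, {"ccr-let-7a": LET7A})
        assert recs and recs[0].name == "ccr-let-7a"
        assert call_conserved_mirnas({LET7A[:-3]: 1}, {"ccr-let-7a": LET7A}) == []


class TestFamilies:
    @pytest.mark.parametrize("name,family", [
        ("ccr-miR-199-5p", "miR-199"),
        ("ccr-miR-199-3p", "miR-199"),
        ("ccr-miR-125b", "miR-125"),
        ("ccr-let-7a", "let-7"),
        ("dre-let-7c-5p", "let-7"),
        ("ccr-miR-126-3p", "miR-126"),
        ("ccr-miR-92a-5p", "miR-92"),
    ])
    def test_family_normalization(self, name, family):
        assert family_name(name) == family

    def test_arm_variants_cluster_together(self):
        recs = call_conserved_mirnas(
            {"ACAGTAGTCTGCACATTGGTT": 2, "CCCAGTGTTCAGACTACCTGTTC": 3},
            {"ccr-miR-199-3p": "ACAGTAGTCTGCACATTGGTT",
             "ccr-miR-199-5p": "CCCAGTGTTCAGACTACCTGTTC"})
        fams = cluster_families(recs)
        assert fams == {"miR-199": ["ccr-miR-199-3p", "ccr-miR-199-5p"]}

    def test_fixture_list_matches_hand_oracle(self):
        recs = call_conserved_mirnas(
            {LET7A: 1}, {"ccr-let-7a": LET7A})
        fams = cluster_families(recs)
        assert fams == {"let-7": ["ccr-let-7a"]}


class TestNovelScreen:
    def _rand(self, rng, n):
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_planted_inverted_repeat_accepted(self, rng):
        mature = self._rand(rng, 22)
        g = self._rand(rng, 300) + mature + self._rand(rng, 8) + revcomp(mature) \
            + self._rand(rng, 300)
        cands = screen_novel_candidates([Hit(mature, "chr1", 300, "+", 0)],
                                        {"chr1": g})
        assert len(cands) == 1
        assert cands[0].fold_energy <= -18.0
        assert cands[0].mature_arm == "5p"

    def test_unstructured_flank_rejected(self, rng):
        read = self._rand(rng, 22)
        g = self._rand(rng, 200) + read + self._rand(rng, 200)
        assert screen_novel_candidates([Hit(read, "chr1", 200, "+", 0)],
                                       {"chr1": g}) == []

    def test_loop_only_read_rejected(self, rng):
        mature = self._rand(rng, 22)
        g = self._rand(rng, 300) + mature + self._rand(rng, 30) \
            + revcomp(mature) + self._rand(rng, 300)
        loop_read = g[326:348]      # entirely inside the 30-nt loop
        assert screen_novel_candidates([Hit(loop_read, "chr1", 326, "+", 0)],
                                       {"chr1": g}) == []

    def test_hairpin_energy_oracle(self, bundle):
        """Planted genome hairpins fold below the screen threshold."""
        from koisrna.targets import duplex_energy
        for (chrom, s, e, _), (name, mature) in zip(
                bundle.hairpins, sorted(bundle.novel_matures.items())):
            hp = bundle.genome[chrom][s:e]
            arm3 = hp[-len(mature):]
            assert duplex_energy(mature, arm3).duplex_mfe <= -18.0
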