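from itertools import product

import numpy as np
import pytest

from motifweave.io import AnnotationTable, PromoterDb, PromoterRecord
from motifweave.pwm import Pwm, build_pwm
from motifweave.scan import (
    PvalueTable,
    genes_with_all_motifs,
    genome_retrieval,
    go_enrichment,
    pwm_pvalue_table,
    scan_promoter,
)

from conftest import random_dna


def brute_force_tail(pwm: Pwm, int_score: int, scale=1000) -> float:
    """Tail probability by enumeration of all 4^w windows (uniform bg)."""
    lo = pwm.log_odds(None)
    w = pwm.width
    total = 0.0
    for word in product(range(4), repeat=w):
        s = int(sum(np.rint(lo[b, j] * scale) for j, b in enumerate(word)))
        if s >= int_score:
            total += 0.25 ** w
    return total


class TestPvalueTable:
    def test_top_score_probability(self):
        # two columns, each 0.7 on one base: only the consensus dinucleotide
        # reaches the maximum score, so its tail is (1/4)^2
        counts = np.array([[70, 10], [10, 70], [10, 10], [10, 10]], dtype=float)
        pwm = Pwm(counts)
        t = pwm_pvalue_table(pwm)
        top = int(t.int_scores.max(axis=0).sum())
        assert t.pvalue(top) == pytest.approx(1 / 16)

    def test_minimum_score_tail_is_one(self):
        rng = np.random.default_rng(2)
        pwm = Pwm(rng.random((4, 6)) * 10, 0.25)
        t = pwm_pvalue_table(pwm)
        assert t.total_mass() == pytest.approx(1.0, abs=1e-9)
        low = int(t.int_scores.min(axis=0).sum())
        assert t.pvalue(low) == pytest.approx(1.0)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_dp_equals_brute_force(self, width):
        rng = np.random.default_rng(width)
        pwm = Pwm(rng.random((4, width)) * 10, 0.25)
        t = pwm_pvalue_table(pwm)
        queries = np.quantile(t._support, [0.0, 0.3, 0.7, 1.0]).astype(int)
        for q in queries:
            assert t.pvalue(int(q)) == pytest.approx(
                brute_force_tail(pwm, int(q)), abs=1e-12)

    def test_tail_non_increasing(self):
        rng = np.random.default_rng(3)
        pwm = Pwm(rng.random((4, 6)) * 10, 0.25)
        t = pwm_pvalue_table(pwm)
        tails = t.pvalues(t._support)
        assert (np.diff(tails) <= 0).all()


class TestScanPromoter:
    def test_consensus_sequence_is_hit(self):
        pwm = build_pwm(["ACGTACGT"] * 5, 0.1)
        hits = scan_promoter(pwm, ("g", "ACGTACGT"))
        assert any(h.start == 0 and h.end == 8 for h in hits)

    def test_all_n_promoter_empty(self):
        pwm = build_pwm(["ACGTACGT"] * 5, 0.1)
        assert scan_promoter(pwm, ("g", "N" * 50)) == []

    def test_short_promoter_empty_not_error(self):
        pwm = build_pwm(["ACGTACGT"] * 5, 0.1)
        assert scan_promoter(pwm, ("g", "ACG")) == []

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(11)
        pwm = Pwm(rng.random((4, 5)) * 8, 0.25)
        seq = random_dna(50, rng)
        table = pwm_pvalue_table(pwm)
        rc_table = pwm_pvalue_table(pwm.reverse_complement())
        expected = set()
        from motifweave.pwm import encode
        enc = encode(seq)
        for i in range(len(seq) - 4):
            for strand, tab in (("+", table), ("-", rc_table)):
                s = int(tab.int_scores[enc[i:i + 5], np.arange(5)].sum())
                if tab.pvalue(s) <= 0.05:
                    expected.add((i, strand))
        got = {(h.start, h.strand) for h in scan_promoter(pwm, ("g", seq), 0.05)}
        assert got == expected

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        pwm = Pwm(rng.random((4, 6)) * 8, 0.25)
        seq = random_dna(300, rng)
        a = scan_promoter(pwm, ("g", seq), 0.01)
        b = scan_promoter(pwm, ("g", seq), 0.01)
        assert a == b


def _db_with_word(word, carriers, n_total, rng, length=80):
    recs = []
    for i in range(n_total):
        seq = random_dna(length, rng)
        if i in carriers:
            seq = seq[: 10] + word + seq[10 + len(word):]
        recs.append(PromoterRecord(f"g{i}", seq))
    return PromoterDb(recs)


class TestGenomeRetrieval:
    def test_planted_genes_returned(self):
        rng = np.random.default_rng(21)
        pwm = build_pwm(["GTACGGATCC"] * 5, 0.1)
        db = _db_with_word("GTACGGATCC", {1, 3}, 5, rng)
        genes = genome_retrieval(pwm, db)
        assert set(genes) == {"g1", "g3"}

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(22)
        pwm = Pwm(rng.random((4, 8)) * 6, 0.25)
        db = PromoterDb([PromoterRecord(f"g{i}", random_dna(400, rng))
                         for i in range(10)])
        tight = set(genome_retrieval(pwm, db, 1e-4))
        loose = set(genome_retrieval(pwm, db, 1e-2))
        assert tight <= loose

    def test_copy_number(self):
        rng = np.random.default_rng(23)
        word = "GTACGGATCC"
        seq = random_dna(100, rng)
        for pos in (5, 40, 80):
            seq = seq[:pos] + word + seq[pos + 10:]
        db = PromoterDb([PromoterRecord("g0", seq),
                         PromoterRecord("g1", random_dna(100, rng))])
        counts = genome_retrieval(build_pwm([word] * 5, 0.1), db)
        assert counts["g0"] >= 3


class TestAllMotifIntersection:
    def test_intersection_and_subset_law(self):
        rng = np.random.default_rng(31)
        w1, w2 = "GTACGGATCC", "TTGACCGGTA"
        recs = []
        for i in range(5):
            seq = random_dna(300, rng)
            if i in (0, 2):  # both words within the last 200 bp
                seq = seq[:150] + w1 + seq[160:250] + w2 + seq[260:]
            elif i == 4:  # only one word
                seq = seq[:150] + w1 + seq[160:]
            recs.append(PromoterRecord(f"g{i}", seq))
        db = PromoterDb(recs)
        pwms = [build_pwm([w1] * 5, 0.1), build_pwm([w2] * 5, 0.1)]
        both = genes_with_all_motifs(pwms, db, within_bp=200)
        assert both == ["g0", "g2"]
        for pwm in pwms:
            assert set(both) <= set(genome_retrieval(pwm, db))

    def test_unmatched_pwm_empties_intersection(self):
        rng = np.random.default_rng(32)
        db = PromoterDb([PromoterRecord(f"g{i}", random_dna(100, rng))
                         for i in range(4)])
        pwms = [build_pwm(["GTACGGATCC"] * 5, 0.1),
                build_pwm(["AACCGGTTAA"] * 5, 0.1)]
        assert genes_with_all_motifs(pwms, db, within_bp=None) == []


class TestGoEnrichment:
    def _table(self):
        genes = {f"g{i}": set() for i in range(10)}
        for i in range(4):
            genes[f"g{i}"].add("GO:0000010")
        for g in genes:
            genes[g].add("GO:0000099")  # universal term
        return AnnotationTable(genes, {"GO:0000010": "planted"})

    def test_exact_hypergeometric_value(self):
        ann = self._table()
        res = go_enrichment(["g0", "g1", "g2"], ann)
        by_term = {r.term_id: r for r in res}
        # all 3 listed genes carry the 4/10 term: C(4,3)/C(10,3) = 1/30
        assert by_term["GO:0000010"].p_raw == pytest.approx(4 / 120)

    def test_universal_term_p_one(self):
        ann = self._table()
        res = go_enrichment(["g0", "g1", "g2"], ann)
        by_term = {r.term_id: r for r in res}
        assert by_term["GO:0000099"].p_raw == pytest.approx(1.0)

    def test_single_term_bh_identity(self):
        genes = {f"g{i}": {"GO:0000010"} for i in range(6)}
        ann = AnnotationTable(genes)
        res = go_enrichment(["g0", "g1"], ann)
        assert len(res) == 1 and res[0].p_adj == pytest.approx(res[0].p_raw)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment([], self._table())
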