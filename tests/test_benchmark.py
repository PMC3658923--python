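import math

import numpy as np
import pytest

from motifweave.benchmark import (
    ConfusionCounts,
    aggregate,
    confusion_nucleotides,
    metrics,
    partition_true_positives,
    percent_change,
)


def brute_force_confusion(truth, pred, lengths):
    """Independent per-position oracle using explicit label sets."""
    tp = fp = fn = tn = 0
    for sid, L in lengths.items():
        t = {p for s in truth if s[0] == sid for p in range(s[1], s[2])}
        p_ = {p for s in pred if s[0] == sid for p in range(s[1], s[2])}
        for pos in range(L):
            if pos in t and pos in p_:
                tp += 1
            elif pos in p_:
                fp += 1
            elif pos in t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = [("s", 10, 20)]
        cc = confusion_nucleotides(truth, truth, {"s": 100})
        assert (cc.nTP, cc.nFP, cc.nFN, cc.nTN) == (10, 0, 0, 90)

    def test_disjoint_prediction(self):
        cc = confusion_nucleotides([("s", 10, 20)], [("s", 50, 60)], {"s": 100})
        assert (cc.nTP, cc.nFP, cc.nFN, cc.nTN) == (0, 10, 10, 80)

    def test_half_overlap(self):
        cc = confusion_nucleotides([("s", 10, 20)], [("s", 15, 25)], {"s": 100})
        assert (cc.nTP, cc.nFP, cc.nFN, cc.nTN) == (5, 5, 5, 85)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            confusion_nucleotides([("s", 95, 105)], [], {"s": 100})

    def test_counts_partition_total(self):
        rng = np.random.default_rng(0)
        lengths = {f"s{i}": 80 for i in range(3)}
        truth = [(f"s{int(rng.integers(3))}", int(p), int(p) + 6)
                 for p in rng.integers(0, 74, size=8)]
        pred = [(f"s{int(rng.integers(3))}", int(p), int(p) + 6)
                for p in rng.integers(0, 74, size=8)]
        cc = confusion_nucleotides(truth, pred, lengths)
        assert cc.total == sum(lengths.values())


class TestMetrics:
    def test_perfect(self):
        nSn, nCC, nFDR = metrics(ConfusionCounts(10, 0, 0, 90))
        assert (nSn, nCC, nFDR) == (1.0, 1.0, 0.0)

    def test_half_overlap_values(self):
        nSn, nCC, nFDR = metrics(ConfusionCounts(5, 5, 5, 85))
        assert nSn == pytest.approx(0.5)
        assert nFDR == pytest.approx(0.5)
        assert nCC == pytest.approx(400 / 900)

    def test_undefined_reported_as_none(self):
        nSn, nCC, nFDR = metrics(ConfusionCounts(0, 0, 10, 90))
        assert nSn == 0.0 and nFDR is None and nCC is None

    def test_ncc_equals_pearson_of_indicators(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(0, 2, size=60).astype(bool)
            p = rng.integers(0, 2, size=60).astype(bool)
            cc = ConfusionCounts(int((t & p).sum()), int((~t & p).sum()),
                                 int((t & ~p).sum()), int((~t & ~p).sum()))
            nCC = metrics(cc)[1]
            if nCC is None:
                continue
            assert nCC == pytest.approx(np.corrcoef(t, p)[0, 1], abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAggregate:
    def test_mean_of_identical_reports(self):
        cc = ConfusionCounts(10, 20, 5, 65)
        out = aggregate([cc, cc, cc])
        assert out["mean_nTP"] == 10 and out["mean_nFP"] == 20
        assert out["mean_nSn"] == pytest.approx(10 / 15)

    def test_display_rounding(self):
        out = aggregate([ConfusionCounts(1, 0, 0, 0),
                         ConfusionCounts(2, 0, 0, 0)])
        assert out["mean_nTP"] == pytest.approx(1.5)
        assert out["mean_nTP_display"] == 2

    def test_percent_change_one_decimal(self):
        assert percent_change(107815, 80159) == 25.7
        assert percent_change(200, 150) == 25.0


class TestPartition:
    def test_single_engine_only(self):
        lengths = {"s": 100}
        truth = [("s", 10, 30)]
        parts = partition_true_positives(
            {"A": [("s", 10, 20)], "B": []}, truth, lengths)
        assert parts == {"A": 1.0, "B": 0.0, "shared": 0.0}

    def test_identical_predictions_all_shared(self):
        lengths = {"s": 100}
        truth = [("s", 10, 30)]
        pred = [("s", 12, 25)]
        parts = partition_true_positives(
            {"A": pred, "B": pred, "C": pred}, truth, lengths)
        assert parts == {"A": 0.0, "B": 0.0, "C": 0.0, "shared": 1.0}

    def test_disjoint_engine_sets_hand_counts(self):
        lengths = {"s": 100}
        truth = [("s", 0, 30)]
        parts = partition_true_positives(
            {"A": [("s", 0, 10)], "B": [("s", 10, 15)], "C": [("s", 40, 50)]},
            truth, lengths)
        # 15 true-positive nucleotides: 10 from A alone, 5 from B alone
        assert parts["A"] == pytest.approx(10 / 15)
        assert parts["B"] == pytest.approx(5 / 15)
        assert parts["C"] == 0.0 and parts["shared"] == 0.0
        assert math.isclose(sum(parts.values()), 1.0)

    def test_no_true_positives_all_zero(self):
        parts = partition_true_positives(
            {"A": [("s", 50, 60)], "B": []}, [("s", 0, 10)], {"s": 100})
        assert set(parts.values()) == {0.0}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        lengths = {f"s{i}": 60 for i in range(2)}
        def rand_sites(k):
            return [(f"s{int(rng.integers(2))}", int(p), int(p) + 5)
                    for p in rng.integers(0, 55, size=k)]
        truth = rand_sites(6)
        per_engine = {"A": rand_sites(4), "B": rand_sites(4), "C": rand_sites(4)}
        parts = partition_true_positives(per_engine, truth, lengths)
        # oracle: label every position explicitly
        tallies = {"A": 0, "B": 0, "C": 0, "shared": 0}
        total = 0
        for sid, L in lengths.items():
            t = {p for s in truth if s[0] == sid for p in range(s[1], s[2])}
            cover = {e: {p for s in per_engine[e] if s[0] == sid
                         for p in range(s[1], s[2])} for e in per_engine}
            for pos in t:
                engines = [e for e in cover if pos in cover[e]]
                if not engines:
                    continue
                total += 1
                if len(engines) == 1:
                    tallies[engines[0]] += 1
                else:
                    tallies["shared"] += 1
        for k in tallies:
            assert parts[k] == pytest.approx(tallies[k] / total if total else 0.0)


class TestConfusionOracle:
    def test_random_toys_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            lengths = {f"s{i}": int(rng.integers(20, 80)) for i in range(3)}
            def sites(k):
                out = []
                for _ in range(k):
                    sid = f"s{int(rng.integers(3))}"
                    L = lengths[sid]
                    w = int(rng.integers(3, 9))
                    start = int(rng.integers(0, max(1, L - w)))
                    out.append((sid, start, start + w))
                return out
            truth, pred = sites(int(rng.integers(0, 6))), sites(int(rng.integers(0, 6)))
            cc = confusion_nucleotides(truth, pred, lengths)
            assert (cc.nTP, cc.nFP, cc.nFN, cc.nTN) == \
                brute_force_confusion(truth, pred, lengths)
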