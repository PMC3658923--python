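"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from motifweave.io import PromoterDb, PromoterRecord
from motifweave.synth import high_ic_pwm, make_dataset, word_pwm


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def strong_planted_dataset():
    """20 x 500 nt order-0 background with a width-10 high-IC implant in
    every sequence — the strong-signal recovery fixture."""
    pwm = high_ic_pwm(10, seed=42)
    return make_dataset("markov", 20, 500, pwm, occurrence_rate=1.0, seed=42)


@pytest.fixture(scope="session")
def word_planted_dataset():
    """Exact 8-mer planted once in each of 10 shuffled-background sequences."""
    return make_dataset("markov", 10, 500, word_pwm("TGACGTCA"),
                        occurrence_rate=1.0, seed=7)


@pytest.fixture()
def toy_db():
    rng = np.random.default_rng(0)
    recs = [PromoterRecord(f"g{i}", random_dna(60, rng)) for i in range(8)]
    return PromoterDb(recs, source="toy")


@pytest.fixture(scope="session")
def three_implant_fixture():
    """20 x 400 nt sequences carrying three implants with complementary
    difficulty: a diffuse width-10 PWM in every sequence (PWM engines'
    territory), an exact 6-mer in every sequence, and an exact 10-mer in
    only 4 sequences (a beacon for exact-count word enumeration, too rare
    for one-site-per-sequence samplers).  Returns (sequences, truth) with
    truth[name] = [(seq_id, start, width), ...]."""
    rng = np.random.default_rng(2024)
    n, L = 20, 400
    diffuse = high_ic_pwm(10, dominant=0.8, seed=77, name="diffuse")
    truth = {"diffuse_pwm": [], "word6": [], "rare_word10": []}
    seqs = []
    for i in range(n):
        s = list(random_dna(L, rng))
        placed: list[tuple[int, int]] = []

        def place(word):
            for _ in range(100):
                p = int(rng.integers(0, L - len(word)))
                if all(p + len(word) <= a or p >= b for a, b in placed):
                    placed.append((p, p + len(word)))
                    s[p: p + len(word)] = list(word)
                    return p
            raise RuntimeError("could not place implant")

        inst = "".join("ACGT"[rng.choice(4, p=diffuse.probs[:, j])]
                       for j in range(10))
        truth["diffuse_pwm"].append((f"s{i}", place(inst), 10))
        truth["word6"].append((f"s{i}", place("TTAGCA"), 6))
        if i < 4:
            truth["rare_word10"].append((f"s{i}", place("ATCGGATGCA"), 10))
        seqs.append((f"s{i}", "".join(s)))
    return seqs, truth


def overlap_recovery(truth_sites, sites) -> float:
    """Fraction of (seq_id, start, width) truth sites overlapped over at
    least half their width by some predicted site."""
    if not truth_sites:
        return 1.0
    hit = 0
    for sid, start, w in truth_sites:
        if any(s.seq_id == sid
               and min(s.end, start + w) - max(s.start, start) >= (w + 1) // 2
               for s in sites):
            hit += 1
    return hit / len(truth_sites)


def recovery_fraction(truth, sites, tol_nt: int = 1) -> float:
    """Fraction of truth sites whose start is matched within +-tol_nt by a
    predicted site on the same sequence."""
    if not truth:
        return 1.0
    hit = 0
    for t in truth:
        if any(s.seq_id == t[0] and abs(s.start - t[1]) <= tol_nt for s in sites):
            hit += 1
    return hit / len(truth)
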