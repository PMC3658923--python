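"""Seeded generators of planted-motif benchmark datasets and toy genome fixtures.

Three dataset flavors emulate the standard planted-motif benchmark families:

* ``markov`` — fully synthetic sequences from an order-0 (uniform by default)
  background;
* ``semi_synthetic`` — background sampled from an order-3 Markov chain trained
  on user-supplied seed sequences, so local composition mimics real promoters;
* ``real_like`` — background assembled by recombining fragments of supplied
  promoter sequences, preserving longer-range structure.

Implants are sampled column-wise from a PWM, placed uniformly (position and
strand) without overlap, at most one per sequence (ZOOPS), and their exact
coordinates are recorded as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import AnnotationTable, PromoterDb, PromoterRecord, reverse_complement
from .pwm import BASES, BASE_INDEX, MarkovBackground, Pwm, _all_kmers

__all__ = [
    "BenchmarkDataset",
    "FLAVORS",
    "train_markov",
    "make_dataset",
    "make_fixture_genome",
    "high_ic_pwm",
    "word_pwm",
]

FLAVORS = ("markov", "semi_synthetic", "real_like")


@dataclass(frozen=True)
class BenchmarkDataset:
    flavor: str
    sequences: tuple[tuple[str, str], ...]
    truth: tuple[tuple[str, int, int, str], ...]  # (seq_id, start, end, strand)
    planted_pwm: Pwm
    seed: int

    def seq_lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.sequences}

    def write(self, prefix: str | Path) -> None:
        """FASTA + truth BED6 + JSON parameter sidecar."""
        prefix = Path(prefix)
        with open(prefix.with_suffix(".fasta"), "w") as fh:
            for sid, seq in self.sequences:
                fh.write(f">{sid}\n{seq}\n")
        with open(prefix.with_suffix(".truth.bed"), "w") as fh:
            for i, (sid, start, end, strand) in enumerate(self.truth):
                fh.write(f"{sid}\t{start}\t{end}\timplant_{i + 1}\t0\t{strand}\n")
        sidecar = {
            "flavor": self.flavor,
            "n_sequences": len(self.sequences),
            "motif_width": self.planted_pwm.width,
            "seed": self.seed,
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)


def train_markov(seqs: list[str], order: int) -> MarkovBackground:
    """Maximum-likelihood order-k Markov chain with add-one smoothing."""
    if order < 0:
        raise ValueError("order must be >= 0")
    total = sum(len(s) for s in seqs)
    if total <= 4 ** (order + 1):
        raise ValueError(
            f"need more than 4^{order + 1} total bases to train an order-{order} model"
        )
    counts: dict[str, np.ndarray] = {c: np.zeros(4) for c in _all_kmers(order)}
    for s in seqs:
        s = s.upper()
        for i in range(order, len(s)):
            ctx, ch = s[i - order: i], s[i]
            if ch not in BASE_INDEX or any(c not in BASE_INDEX for c in ctx):
                continue
            counts[ctx][BASE_INDEX[ch]] += 1
    probs = {c: (v + 1.0) / (v.sum() + 4.0) for c, v in counts.items()}
    return MarkovBackground(order, probs)


def train_markov_raw(seqs: list[str], order: int) -> dict[str, np.ndarray]:
    """Unsmoothed conditional frequencies (contexts with no data omitted)."""
    counts: dict[str, np.ndarray] = {}
    for s in seqs:
        s = s.upper()
        for i in range(order, len(s)):
            ctx, ch = s[i - order: i], s[i]
            if ch not in BASE_INDEX or any(c not in BASE_INDEX for c in ctx):
                continue
            counts.setdefault(ctx, np.zeros(4))[BASE_INDEX[ch]] += 1
    return {c: v / v.sum() for c, v in counts.items() if v.sum() > 0}


def _sample_site(pwm: Pwm, rng: np.random.Generator) -> str:
    cols = pwm.probs
    return "".join(BASES[rng.choice(4, p=cols[:, j])] for j in range(pwm.width))


def _fragment_background(fragments: list[str], length: int,
                         rng: np.random.Generator, fragment_len: int = 50) -> str:
    pool = [f.upper() for f in fragments if len(f) >= fragment_len]
    if not pool:
        raise ValueError(f"need supplied sequences of at least {fragment_len} nt")
    out = []
    size = 0
    while size < length:
        src = pool[rng.integers(len(pool))]
        start = int(rng.integers(0, len(src) - fragment_len + 1))
        frag = src[start: start + fragment_len]
        if rng.integers(2):
            frag = reverse_complement(frag)
        out.append(frag)
        size += len(frag)
    return "".join(out)[:length]


def make_dataset(
    flavor: str,
    n_seqs: int,
    seq_len: int,
    pwm: Pwm,
    occurrence_rate: float = 1.0,
    seed: int = 0,
    seed_sequences: list[str] | None = None,
    sites_per_seq: int = 1,
) -> BenchmarkDataset:
    """Generate a planted-motif dataset with exact ground truth.

    Each sequence independently carries an implant with probability
    ``occurrence_rate`` (ZOOPS); ``sites_per_seq`` > 1 plants that many
    non-overlapping implants instead, for occurrence-count tests.  Identical
    seeds give identical datasets.
    """
    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; choose from {FLAVORS}")
    if seq_len < pwm.width:
        raise ValueError("sequences shorter than the motif cannot hold an implant")
    if not 0.0 <= occurrence_rate <= 1.0:
        raise ValueError("occurrence_rate must lie in [0, 1]")
    if sites_per_seq * (2 * pwm.width) > seq_len:
        raise ValueError("implants cannot fit without overlap")
    rng = np.random.default_rng(seed)
    if flavor == "markov":
        bg = MarkovBackground.uniform(0)
        draw = lambda: bg.sample(seq_len, rng)
    elif flavor == "semi_synthetic":
        if not seed_sequences:
            raise ValueError("semi_synthetic flavor needs seed_sequences")
        model = train_markov(seed_sequences, order=3)
        draw = lambda: model.sample(seq_len, rng)
    else:  # real_like
        if not seed_sequences:
            raise ValueError("real_like flavor needs seed_sequences")
        draw = lambda: _fragment_background(seed_sequences, seq_len, rng)
    sequences: list[tuple[str, str]] = []
    truth: list[tuple[str, int, int, str]] = []
    w = pwm.width
    for i in range(n_seqs):
        sid = f"seq_{i + 1}"
        seq = list(draw())
        n_implants = sites_per_seq if rng.random() < occurrence_rate else 0
        placed: list[tuple[int, int]] = []
        for _ in range(n_implants):
            for _attempt in range(200):
                start = int(rng.integers(0, seq_len - w + 1))
                if all(start + w <= a or start >= b for a, b in placed):
                    break
            else:
                raise RuntimeError("could not place non-overlapping implant")
            site = _sample_site(pwm, rng)
            strand = "+" if rng.integers(2) == 0 else "-"
            seq[start: start + w] = list(site if strand == "+"
                                         else reverse_complement(site))
            placed.append((start, start + w))
            truth.append((sid, start, start + w, strand))
        sequences.append((sid, "".join(seq)))
    return BenchmarkDataset(flavor, tuple(sequences), tuple(truth), pwm, seed)


def high_ic_pwm(width: int = 10, dominant: float = 0.87, seed: int = 0,
                name: str = "planted") -> Pwm:
    """A random strong motif: one dominant base per column at the given
    probability, remainder spread evenly (IC ~ 12 bits at width 10, 0.87)."""
    rng = np.random.default_rng(seed)
    counts = np.full((4, width), (1 - dominant) / 3 * 100)
    for j in range(width):
        counts[rng.integers(4), j] = dominant * 100
    return Pwm(counts, 0.0, name=name)


def word_pwm(word: str, name: str | None = None) -> Pwm:
    """The degenerate PWM of an exact word (probability 1 per column)."""
    counts = np.zeros((4, len(word)))
    for j, ch in enumerate(word.upper()):
        counts[BASE_INDEX[ch], j] = 1.0
    return Pwm(counts, 0.0, name=name or f"word_{word}")


def make_fixture_genome(
    n_genes: int = 50,
    enriched_term_fraction: float = 0.1,
    seed: int = 0,
    min_len: int = 200,
    max_len: int = 1000,
    n_background_terms: int = 5,
) -> tuple[PromoterDb, AnnotationTable]:
    """A toy promoter database plus GO annotations with a known positive control.

    A designated term (``GO:0000001``) annotates exactly the first
    ``enriched_term_fraction`` of genes, so enrichment of that gene subset is a
    planted positive; background terms are scattered uniformly.
    """
    if n_genes < 10:
        raise ValueError("fixture genome needs at least 10 genes")
    rng = np.random.default_rng(seed)
    records = []
    offset = 0
    for i in range(n_genes):
        L = int(rng.integers(min_len, max_len + 1))
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=L))
        records.append(PromoterRecord(f"gene_{i + 1:04d}", seq, "chrSim",
                                      offset, offset + L, "+"))
        offset += L + 100
    db = PromoterDb(records, source=f"synthetic fixture genome (seed {seed})",
                    masked=False)
    n_enriched = max(2, int(round(enriched_term_fraction * n_genes)))
    gene_terms: dict[str, set[str]] = {r.gene_id: set() for r in records}
    term_names = {"GO:0000001": "planted positive-control process"}
    for r in records[:n_enriched]:
        gene_terms[r.gene_id].add("GO:0000001")
    for t in range(n_background_terms):
        term = f"GO:{t + 2:07d}"
        term_names[term] = f"background process {t + 1}"
        # background terms are kept reasonably common: ultra-sparse terms
        # are genuinely enrichable by chance in small gene lists
        for r in records:
            if rng.random() < 0.3:
                gene_terms[r.gene_id].add(term)
    # every gene gets at least one term so the annotated universe is the db
    for r in records:
        if not gene_terms[r.gene_id]:
            gene_terms[r.gene_id].add("GO:0000002")
    return db, AnnotationTable(gene_terms, term_names)
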