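"""Genome-wide PWM retrieval with exact p-values, gene lists, GO enrichment.

The scanner assigns each window a log-odds score in bits and converts it to a
p-value P(score' >= score) under an order-0 background, computed exactly by
dynamic-programming convolution of the integerized per-column score
distributions (the standard construction used by PWM retrieval tools).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import PromoterDb, AnnotationTable
from .pwm import Pwm, MarkovBackground, encode, _order0_freqs

__all__ = [
    "ScanHit",
    "EnrichmentResult",
    "PvalueTable",
    "pwm_pvalue_table",
    "scan_promoter",
    "scan_db",
    "count_promoters_with_hit",
    "genome_retrieval",
    "genes_with_all_motifs",
    "go_enrichment",
]

DEFAULT_SCAN_P = 1e-4


@dataclass(frozen=True)
class ScanHit:
    """A PWM match within a promoter; coordinates are 0-based half-open
    within the promoter sequence."""

    gene_id: str
    start: int
    end: int
    strand: str
    score: float  # bits
    p_value: float


class PvalueTable:
    """Exact null distribution of a PWM's integerized log-odds score.

    Scores are multiplied by ``scale`` and rounded; the table maps every
    achievable integer score to the exact tail probability that a random
    background window scores at least that high.
    """

    def __init__(self, pwm: Pwm, background: MarkovBackground | None = None,
                 scale: int = 1000):
        bg = _order0_freqs(background)
        lo = pwm.log_odds(bg)
        # -inf columns (pseudocount 0) get a large negative finite stand-in so
        # the DP stays finite; such windows can never reach a positive tail cut
        int_lo = np.where(np.isfinite(lo), np.rint(lo * scale), np.iinfo(np.int64).min // (4 * pwm.width))
        self.int_scores = int_lo.astype(np.int64)
        self.scale = scale
        self.bg = bg
        # DP over columns: distribution of the sum of per-column scores
        dist: dict[int, float] = {0: 1.0}
        for j in range(pwm.width):
            nxt: dict[int, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    s2 = s + int(self.int_scores[b, j])
                    nxt[s2] = nxt.get(s2, 0.0) + p * bg[b]
            dist = nxt
        self._support = np.array(sorted(dist), dtype=np.int64)
        pmf = np.array([dist[s] for s in self._support])
        # tail[i] = P(score >= support[i])
        self._tail = pmf[::-1].cumsum()[::-1]

    def pvalue(self, int_score: int) -> float:
        """Exact P(random window score >= int_score)."""
        i = np.searchsorted(self._support, int_score, side="left")
        if i >= len(self._support):
            return 0.0
        return float(self._tail[i])

    def pvalues(self, int_scores: np.ndarray) -> np.ndarray:
        i = np.searchsorted(self._support, int_scores, side="left")
        out = np.where(i < len(self._support),
                       self._tail[np.minimum(i, len(self._support) - 1)], 0.0)
        return out

    def total_mass(self) -> float:
        return float(self._tail[0])

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose tail p-value is <= p_threshold
        (one past the maximum support if no score qualifies)."""
        ok = self._tail <= p_threshold
        if not ok.any():
            return int(self._support[-1]) + 1
        return int(self._support[np.argmax(ok)])


def pwm_pvalue_table(pwm: Pwm, background: MarkovBackground | None = None,
                     scale: int = 1000) -> PvalueTable:
    return PvalueTable(pwm, background, scale)


def _window_int_scores(enc: np.ndarray, int_scores: np.ndarray) -> np.ndarray:
    """Integer score of every window of width w; windows containing N get
    the minimum int64 sentinel."""
    w = int_scores.shape[1]
    n_win = len(enc) - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        col = enc[j : j + n_win]
        bad = col > 3
        valid &= ~bad
        out += int_scores[np.minimum(col, 3), j]
    out[~valid] = np.iinfo(np.int64).min
    return out


def scan_promoter(pwm: Pwm, promoter, p_threshold: float = DEFAULT_SCAN_P,
                  background: MarkovBackground | None = None,
                  table: PvalueTable | None = None,
                  rc_table: PvalueTable | None = None) -> list[ScanHit]:
    """All windows on both strands with exact p <= p_threshold, sorted by start.

    ``promoter`` is a PromoterRecord or a bare (gene_id, seq) pair.  Windows
    containing N are skipped; overlapping hits are allowed.  A promoter shorter
    than the PWM yields an empty list.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0,1)")
    gene_id, seq = _as_pair(promoter)
    if table is None:
        table = PvalueTable(pwm, background)
    if rc_table is None:
        rc_table = PvalueTable(pwm.reverse_complement(), background)
    enc = encode(seq)
    w = pwm.width
    hits: list[ScanHit] = []
    fwd = _window_int_scores(enc, table.int_scores)
    rev = _window_int_scores(enc, rc_table.int_scores)
    # only windows reaching the threshold score need exact p-values
    for strand, scores, tab in (("+", fwd, table), ("-", rev, rc_table)):
        thr = tab.score_threshold(p_threshold)
        for i in np.flatnonzero(scores >= thr):
            s = int(scores[i])
            hits.append(ScanHit(gene_id, int(i), int(i) + w, strand,
                                s / tab.scale, tab.pvalue(s)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _as_pair(promoter) -> tuple[str, str]:
    if isinstance(promoter, tuple):
        return promoter
    return promoter.gene_id, promoter.seq


def scan_db(pwm: Pwm, db, p_threshold: float = DEFAULT_SCAN_P,
            background: MarkovBackground | None = None) -> dict[str, list[ScanHit]]:
    """Scan every promoter in a db; returns gene_id -> hits (possibly empty)."""
    table = PvalueTable(pwm, background)
    rc_table = PvalueTable(pwm.reverse_complement(), background)
    out: dict[str, list[ScanHit]] = {}
    for rec in db:
        out[_as_pair(rec)[0]] = scan_promoter(
            pwm, rec, p_threshold, table=table, rc_table=rc_table
        )
    return out


def count_promoters_with_hit(pwm: Pwm, promoters,
                             p_threshold: float = DEFAULT_SCAN_P,
                             background: MarkovBackground | None = None) -> int:
    """Number of promoters with >=1 site on either strand at p <= threshold."""
    table = PvalueTable(pwm, background)
    rc_table = PvalueTable(pwm.reverse_complement(), background)
    thr_f = table.score_threshold(p_threshold)
    thr_r = rc_table.score_threshold(p_threshold)
    n = 0
    for rec in promoters:
        enc = encode(_as_pair(rec)[1])
        if (_window_int_scores(enc, table.int_scores) >= thr_f).any() or \
           (_window_int_scores(enc, rc_table.int_scores) >= thr_r).any():
            n += 1
    return n


def genome_retrieval(pwm: Pwm, genome_db: PromoterDb,
                     p_threshold: float = DEFAULT_SCAN_P,
                     background: MarkovBackground | None = None) -> dict[str, int]:
    """Genes with >=1 hit and their per-gene hit counts (motif copy numbers)."""
    if len(genome_db) == 0:
        raise ValueError("genome promoter db is empty")
    hits = scan_db(pwm, genome_db, p_threshold, background)
    return {g: len(h) for g, h in hits.items() if h}


def genes_with_all_motifs(pwms: list[Pwm], genome_db: PromoterDb,
                          p_threshold: float = DEFAULT_SCAN_P,
                          within_bp: int | None = 200,
                          background: MarkovBackground | None = None) -> list[str]:
    """Genes whose promoters contain every PWM, optionally restricted to hits
    in the last ``within_bp`` bases before the TSS (promoter 3' end)."""
    if len(pwms) < 2:
        raise ValueError("need at least two PWMs to intersect")
    gene_sets: list[set[str]] = []
    for pwm in pwms:
        hits = scan_db(pwm, genome_db, p_threshold, background)
        ok = set()
        for rec in genome_db:
            hs = hits[rec.gene_id]
            if within_bp is not None:
                cut = max(0, rec.length - within_bp)
                hs = [h for h in hs if h.start >= cut]
            if hs:
                ok.add(rec.gene_id)
        gene_sets.append(ok)
    inter = set.intersection(*gene_sets)
    return sorted(inter)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # genes in list with term
    n: int  # annotated genes in list
    K: int  # annotated genome genes with term
    N: int  # annotated genome genes
    p_raw: float
    p_adj: float


def go_enrichment(gene_list: list[str], annotations: AnnotationTable) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail overrepresentation of GO terms in a gene list.

    The universe is the set of annotated genes (genes with no GO annotation are
    excluded from N and from the effective list size n).  p values are BH
    adjusted across the tested terms; results sorted by p_raw ascending.
    """
    from statsmodels.stats.multitest import multipletests

    if not gene_list:
        raise ValueError("empty gene list")
    universe = annotations.annotated_genes()
    listed = [g for g in dict.fromkeys(gene_list) if g in universe]
    if not listed:
        raise ValueError("no gene in the list has a GO annotation")
    N, n = len(universe), len(listed)
    terms = sorted({t for g in listed for t in annotations.terms_for(g)})
    rows = []
    for t in terms:
        genome_genes = annotations.genes_with_term(t)
        K = len(genome_genes)
        k = sum(1 for g in listed if t in annotations.terms_for(g))
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((t, k, K, min(p_raw, 1.0)))
    p_adj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(t, annotations.term_names.get(t, ""), k, n, K, N, p, float(pa))
        for (t, k, K, p), pa in zip(rows, p_adj)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results
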