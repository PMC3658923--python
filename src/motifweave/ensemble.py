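"""Combining filtered motifs across engines, MNCP ranking, position histograms.

The Mean Normalized Conditional Probability (MNCP) asks whether a motif occurs
more often among the input promoters than in a random set of promoters drawn
from the genome.  All promoters (input positives plus the random sample) are
ranked by per-promoter match count; for the i-th positive at overall rank r_i,
NCP_i = (i / r_i) / (n / N), and MNCP is the mean of the NCP_i.  MNCP > 1
means the input promoters outrank the random set; MNCP <= 1 means the motif is
at least as common in random promoters as in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterResult
from .finders import MotifPrediction, Site
from .io import PromoterDb, PromoterRecord, sample_background
from .pwm import Pwm
from .scan import DEFAULT_SCAN_P, scan_db

__all__ = [
    "RankedMotif",
    "PositionHistogram",
    "combine",
    "mncp_from_ranks",
    "mncp_score",
    "rank_motifs",
    "position_histogram",
]

RANDOM_NOTE = ("motif occurs at least as frequently in a random promoter set "
               "as in the input set (MNCP <= 1)")


@dataclass(frozen=True)
class RankedMotif:
    motif: MotifPrediction
    mncp: float
    rank: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.mncp < 0:
            raise ValueError("MNCP must be >= 0")
        if self.rank < 1:
            raise ValueError("ranks start at 1")


@dataclass
class PositionHistogram:
    """Counts of motif sites per upstream position bin.

    Bins are half-open toward the TSS: a bin (lo, hi] in upstream coordinates
    is stored by its boundaries (negative ints, lo < hi <= 0) and covers sites
    whose 5'-most base lies at distance d upstream with lo <= -d < hi,
    i.e. upstream windows like [-60,-40), counted half-open toward the TSS.
    """

    bin_width: int = 20
    bins: dict[tuple[int, int], int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.bins.values())

    def sorted_items(self):
        return sorted(self.bins.items())


def combine(filtered_lists: list[list[FilterResult]]) -> list[MotifPrediction]:
    """Concatenate all motifs that passed their engine's filter.

    Provenance (engine, motif name) is preserved; no similarity-based
    deduplication is attempted — likely duplicates are reported side by side.
    """
    out: list[MotifPrediction] = []
    for results in filtered_lists:
        out.extend(r.motif for r in results if r.passed)
    return out


def _match_stats(pwm: Pwm, records, p_threshold: float) -> dict[str, tuple[int, float]]:
    """Per-promoter (hit count, best site score); score -inf if no hit."""
    hits = scan_db(pwm, records, p_threshold)
    return {
        g: (len(h), max((x.score for x in h), default=-np.inf))
        for g, h in hits.items()
    }


def mncp_from_ranks(positive_ranks: list[int], N: int) -> float:
    """MNCP given the overall ranks (1-based) of the n positives among N.

    NCP_i = (i / r_i) / (n / N) for the i-th positive in rank order.
    """
    ranks = sorted(positive_ranks)
    n = len(ranks)
    if n == 0 or ranks[0] < 1 or ranks[-1] > N:
        raise ValueError("positive ranks must be 1-based and lie within N")
    return float(np.mean([(i / r) / (n / N) for i, r in enumerate(ranks, 1)]))


def mncp_score(pwm: Pwm, input_db, random_sample: list[PromoterRecord],
               scan_p_threshold: float = DEFAULT_SCAN_P) -> float:
    """MNCP of a motif: input promoters vs a disjoint random promoter sample.

    Promoters are ranked by match count (desc), ties broken by best site score
    (desc) then gene_id (asc) so the score is reproducible.
    """
    input_records = list(input_db)
    if not input_records:
        raise ValueError("empty input promoter set")
    input_ids = {r.gene_id for r in input_records}
    rand_ids = {r.gene_id for r in random_sample}
    if input_ids & rand_ids:
        raise ValueError("random sample must be disjoint from the input set")
    if len(random_sample) < len(input_records):
        raise ValueError("random sample must be at least as large as the input set")
    stats = _match_stats(pwm, list(input_records) + list(random_sample),
                         scan_p_threshold)
    n, N = len(input_records), len(stats)
    order = sorted(stats, key=lambda g: (-stats[g][0], -stats[g][1], g))
    # promoters with identical (count, best score) are genuinely tied: use
    # mid-ranks within tie groups so arbitrary id ordering cannot bias MNCP;
    # where keys are distinct this reduces to the plain rank
    ranks = np.zeros(N)
    start = 0
    while start < N:
        end = start
        key = stats[order[start]]
        while end < N and stats[order[end]] == key:
            end += 1
        ranks[start:end] = (start + 1 + end) / 2  # mean of ranks start+1..end
        start = end
    ncps = []
    i = 0
    for r, g in zip(ranks, order):
        if g in input_ids:
            i += 1
            ncps.append((i / r) / (n / N))
    return float(np.mean(ncps))


def rank_motifs(motifs: list[MotifPrediction], input_db, genome_db: PromoterDb,
                n_random: int | None = None, seed: int = 0,
                scan_p_threshold: float = DEFAULT_SCAN_P) -> list[RankedMotif]:
    """Rank motifs by MNCP against one shared seeded random promoter sample.

    The sample excludes input gene ids; by default its size is
    max(min(1000, available), 10 * n_input) capped at availability.  Motifs
    with MNCP <= 1 carry an explanatory note.
    """
    if not motifs:
        raise ValueError("no motifs to rank")
    input_records = list(input_db)
    input_ids = {r.gene_id for r in input_records}
    pool = [r for r in genome_db if r.gene_id not in input_ids]
    if len(pool) < len(input_records):
        raise ValueError("genome promoter db too small relative to the input set")
    if n_random is None:
        n_random = max(min(1000, len(pool)), 10 * len(input_records))
    n_random = min(n_random, len(pool))
    sample = sample_background(PromoterDb(pool, source=genome_db.source),
                               n_random, seed)
    scored = [
        (mncp_score(m.pwm, input_records, sample, scan_p_threshold), m)
        for m in motifs
    ]
    scored.sort(key=lambda t: (-t[0], t[1].engine, t[1].name))
    return [
        RankedMotif(m, s, rank, note="" if s > 1 else RANDOM_NOTE)
        for rank, (s, m) in enumerate(scored, start=1)
    ]


def position_histogram(sites: list[Site], promoter_lengths: dict[str, int],
                       bin_width: int = 20) -> PositionHistogram:
    """Histogram of site positions upstream of the TSS.

    The promoter 3' end is position -1 (immediately before the TSS); a site is
    binned by its 5'-most base.  Bins are half-open toward the TSS: a site at
    upstream position -60 falls in [-60,-40), not [-80,-60).
    """
    hist = PositionHistogram(bin_width=bin_width, bins={})
    for s in sites:
        L = promoter_lengths[s.seq_id]
        if s.start < 0 or s.end > L:
            raise ValueError(f"site {s} lies outside its promoter (length {L})")
        upstream = s.start - L  # in [-L, -width]
        b = (-upstream - 1) // bin_width  # bin index counted from TSS
        key = (-(b + 1) * bin_width, -b * bin_width)
        hist.bins[key] = hist.bins.get(key, 0) + 1
    return hist
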