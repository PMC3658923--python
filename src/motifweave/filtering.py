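"""Per-engine statistical filters on discovered motifs.

A motif is kept only if its occurrence among the input promoters is unlikely
under the background.  The Gibbs and consensus engines are filtered with a
binomial upper tail pB (per-promoter occurrence probability estimated from a
seeded random sample of genome promoters); the EM engine with a hypergeometric
upper tail pH over the whole genome promoter set.  Cutoffs follow the
benchmark-optimized values: pB <= 0.7 (gibbs), pB <= 0.3 (consensus),
pH <= 0.05 (em).  "Occurrence" means at least one scanner hit per promoter at
the scan p-value threshold (default 1e-4) on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .finders import MotifPrediction
from .io import PromoterDb, sample_background
from .pwm import Pwm
from .scan import DEFAULT_SCAN_P, count_promoters_with_hit

__all__ = [
    "FilterResult",
    "DEFAULT_CUTOFFS",
    "binomial_upper_tail",
    "hypergeometric_upper_tail",
    "count_promoters_with_motif",
    "filter_motifs",
]

DEFAULT_CUTOFFS = {"gibbs": 0.7, "consensus": 0.3, "em": 0.05}
DEFAULT_BACKGROUND_SAMPLE = 1000


@dataclass(frozen=True)
class FilterResult:
    """Filter verdict for one motif.

    For binomial filters ``bg_rate_p`` is the estimated per-promoter
    occurrence probability; for the hypergeometric filter ``K_bg``/``N_bg``
    are the background occurrence counts.
    """

    motif: MotifPrediction
    k_input: int
    n_input: int
    p_value: float
    cutoff: float
    passed: bool
    test: str  # "binomial" | "hypergeometric"
    bg_rate_p: float | None = None
    K_bg: int | None = None
    N_bg: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k_input <= self.n_input:
            raise ValueError("k_input must lie in [0, n_input]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")
        if self.passed != (self.p_value <= self.cutoff):
            raise ValueError("passed flag inconsistent with p_value and cutoff")


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need n, K <= N, got n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def count_promoters_with_motif(pwm: Pwm, promoters,
                               scan_p_threshold: float = DEFAULT_SCAN_P) -> int:
    """Promoters with >=1 scanner hit on either strand at p <= threshold."""
    return count_promoters_with_hit(pwm, promoters, scan_p_threshold)


def filter_motifs(
    predictions: list[MotifPrediction],
    engine: str,
    input_db,
    genome_db: PromoterDb,
    seed: int = 0,
    cutoffs: dict[str, float] | None = None,
    scan_p_threshold: float = DEFAULT_SCAN_P,
    background_sample_size: int = DEFAULT_BACKGROUND_SAMPLE,
) -> list[FilterResult]:
    """Apply the engine's background-occurrence filter to its predictions.

    All motifs are returned; failing ones are flagged ``passed=False``.
    The binomial background rate is estimated once per motif from a seeded
    random sample of ``background_sample_size`` genome promoters (the whole
    genome db if smaller).
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    if engine not in cutoffs:
        raise ValueError(f"unknown engine {engine!r}")
    if len(genome_db) == 0:
        raise ValueError("genome promoter db is empty")
    input_records = list(input_db)
    n_input = len(input_records)
    cutoff = cutoffs[engine]
    results: list[FilterResult] = []
    B = min(background_sample_size, len(genome_db))
    bg_sample = sample_background(genome_db, B, seed) if engine != "em" else None
    for pred in predictions:
        k_input = count_promoters_with_motif(pred.pwm, input_records, scan_p_threshold)
        if engine == "em":
            K = count_promoters_with_motif(pred.pwm, genome_db, scan_p_threshold)
            N = len(genome_db)
            p_value = hypergeometric_upper_tail(min(k_input, min(n_input, K)),
                                                n_input, K, N)
            # k can exceed min(n, K) only when input genes are outside the db;
            # clip keeps the tail well defined and conservative
            results.append(FilterResult(pred, k_input, n_input, p_value, cutoff,
                                        p_value <= cutoff, "hypergeometric",
                                        K_bg=K, N_bg=N))
        else:
            k_bg = count_promoters_with_motif(pred.pwm, bg_sample, scan_p_threshold)
            p_hat = k_bg / len(bg_sample)
            p_value = binomial_upper_tail(k_input, n_input, p_hat)
            results.append(FilterResult(pred, k_input, n_input, p_value, cutoff,
                                        p_value <= cutoff, "binomial",
                                        bg_rate_p=p_hat))
    return results
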