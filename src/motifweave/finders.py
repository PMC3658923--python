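"""Three de-novo motif discovery engines over promoter sets.

* ``em`` — a ZOOPS (zero-or-one occurrence per sequence) expectation-
  maximization finder: word seeds are refined by EM on the mixture of a
  motif PWM and an order-0 background, the best motif is accepted, its sites
  erased, and the search repeats.
* ``gibbs`` — a site-sampler: one candidate site per sequence, resampled
  sweep by sweep from the posterior given the PWM built from all other
  sites; the maximum-posterior configuration after burn-in is reported.
* ``consensus`` — exhaustive word enumeration at (length, mismatch) pairs
  (6,1), (8,2), (10,3): words occurring (within the mismatch budget) in at
  least a quorum of sequences are scored by the binomial upper-tail
  probability of their total occurrence count under the background.

All engines search both strands by default, report up to ``n_motifs``
motifs sorted by decreasing engine score, and share deterministic
tie-breaking (score desc, then leftmost start, then input order).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .pwm import (
    Pwm,
    background_from_sequences,
    build_pwm,
    decode,
    encode,
)

__all__ = [
    "Site",
    "MotifPrediction",
    "FinderConfig",
    "run_em_finder",
    "run_gibbs_finder",
    "run_consensus_finder",
    "run_finder",
    "ENGINES",
]


@dataclass(frozen=True)
class Site:
    """A predicted motif occurrence; coordinates are 0-based half-open on the
    forward strand of the promoter, ``strand`` says which strand matched."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float

    def as_tuple(self):
        return (self.seq_id, self.start, self.end, self.strand, self.score)


@dataclass(frozen=True)
class MotifPrediction:
    pwm: Pwm
    engine: str  # em | gibbs | consensus
    sites: tuple[Site, ...]
    engine_score: float
    word: str | None = None  # the enumerated word, consensus engine only

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a motif prediction must carry at least one site")
        for s in self.sites:
            if s.end - s.start != self.pwm.width:
                raise ValueError(f"site {s} does not match pwm width {self.pwm.width}")

    @property
    def name(self) -> str:
        return self.pwm.name

    def consensus(self) -> str:
        return self.pwm.consensus()


@dataclass(frozen=True)
class FinderConfig:
    """Shared engine configuration.

    Widths are constrained to [6, 10] for pipeline use; the EM and Gibbs
    engines use a single ``width`` (default 10), the consensus engine its
    (length, mismatch) ``schedule``.
    """

    n_motifs: int = 10
    width: int = 10
    both_strands: bool = True
    seed: int = 0
    # EM
    n_seeds: int = 10
    tol: float = 1e-4
    max_iter: int = 100
    pseudocount: float = 0.25
    # Gibbs
    burn_in: int = 100
    n_samples: int = 200
    gibbs_pseudocount: float = 0.5
    # consensus
    quorum: float = 0.5
    schedule: tuple[tuple[int, int], ...] = ((6, 1), (8, 2), (10, 3))

    def __post_init__(self) -> None:
        if not 6 <= self.width <= 10:
            raise ValueError("width must lie in [6, 10]")
        for L, d in self.schedule:
            if not 6 <= L <= 10:
                raise ValueError("schedule lengths must lie in [6, 10]")


# ---------------------------------------------------------------------------
# window bookkeeping


def _as_pairs(promoters) -> list[tuple[str, str]]:
    out = []
    for p in promoters:
        if isinstance(p, tuple):
            out.append((p[0], p[1]))
        else:
            out.append((p.gene_id, p.seq))
    return out


@dataclass
class _Windows:
    """Flattened catalogue of scannable width-w windows across sequences."""

    seq_idx: np.ndarray  # (n,) int
    pos: np.ndarray  # (n,) forward-strand start
    strand: np.ndarray  # (n,) 0 = '+', 1 = '-'
    mat: np.ndarray  # (n, w) int8 encoded window (motif-strand orientation)
    clean: np.ndarray  # (n,) bool: all-uppercase source (eligible as seed)
    n_seqs: int

    def __len__(self) -> int:
        return len(self.pos)


def _build_windows(work: list[np.ndarray], lower: list[np.ndarray], w: int,
                   both_strands: bool) -> _Windows:
    seq_idx, pos, strand, mats, clean = [], [], [], [], []
    for i, enc in enumerate(work):
        n_win = len(enc) - w + 1
        if n_win <= 0:
            continue
        idx = np.arange(n_win)
        win = np.lib.stride_tricks.sliding_window_view(enc, w)
        valid = (win <= 3).all(axis=1)
        low = np.lib.stride_tricks.sliding_window_view(lower[i], w).any(axis=1)
        if valid.any():
            seq_idx.append(np.full(valid.sum(), i))
            pos.append(idx[valid])
            strand.append(np.zeros(valid.sum(), dtype=np.int8))
            mats.append(win[valid])
            clean.append(~low[valid])
            if both_strands:
                seq_idx.append(np.full(valid.sum(), i))
                pos.append(idx[valid])
                strand.append(np.ones(valid.sum(), dtype=np.int8))
                mats.append((3 - win[valid])[:, ::-1])  # reverse complement
                clean.append(~low[valid])
    if not mats:
        return _Windows(np.zeros(0, int), np.zeros(0, int), np.zeros(0, np.int8),
                        np.zeros((0, w), np.int8), np.zeros(0, bool), len(work))
    return _Windows(
        np.concatenate(seq_idx), np.concatenate(pos), np.concatenate(strand),
        np.ascontiguousarray(np.concatenate(mats)), np.concatenate(clean),
        len(work),
    )


def _pack_words(mat: np.ndarray) -> np.ndarray:
    """Pack (n, w<=31) base-index rows into uint64, 2 bits per base."""
    w = mat.shape[1]
    out = np.zeros(len(mat), dtype=np.uint64)
    for j in range(w):
        out = (out << np.uint64(2)) | mat[:, j].astype(np.uint64)
    return out


def _unpack_word(word: int, w: int) -> np.ndarray:
    out = np.zeros(w, dtype=np.int8)
    for j in range(w - 1, -1, -1):
        out[j] = word & 3
        word >>= 2
    return out


def _mismatch_counts(packed_windows: np.ndarray, packed_words: np.ndarray,
                     ) -> np.ndarray:
    """(n_words, n_windows) Hamming distances via 2-bit XOR + popcount."""
    x = packed_windows[None, :] ^ packed_words[:, None]
    y = (x | (x >> np.uint64(1))) & np.uint64(0x5555555555555555)
    return np.bitwise_count(y)


def _prepare(promoters, width: int):
    pairs = _as_pairs(promoters)
    if len(pairs) < 2:
        raise ValueError("motif discovery needs at least 2 sequences")
    enc = [encode(s) for _, s in pairs]
    lower = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) >= ord("a")
             for _, s in pairs]
    usable = [((np.lib.stride_tricks.sliding_window_view(e, width) <= 3)
               .all(axis=1).any() if len(e) >= width else False) for e in enc]
    if not any(usable):
        raise ValueError(f"no sequence has a scannable window of width {width}")
    return pairs, enc, lower


def _erase_sites(work: list[np.ndarray], pairs, sites: tuple[Site, ...]) -> None:
    ids = {sid: i for i, (sid, _) in enumerate(pairs)}
    for s in sites:
        work[ids[s.seq_id]][s.start: s.end] = 4


def _site_sort_key(pairs):
    order = {sid: i for i, (sid, _) in enumerate(pairs)}
    return lambda s: (-s.score, s.start, order[s.seq_id], s.strand)


# ---------------------------------------------------------------------------
# EM (ZOOPS)


def _one_mismatch_occurrence(packed: np.ndarray, w: int) -> np.ndarray:
    """For every window, the number of windows (incl. itself) within Hamming
    distance 1, via single-position-masked keys: a pair of words is within
    one mismatch iff some masked key coincides.  An exact duplicate shares
    all w masked keys, a 1-mismatch neighbour exactly one, so
    N_<=1 = sum_j |group_j| - (w-1) * N_exact."""
    total = np.zeros(len(packed), dtype=np.int64)
    for j in range(w):
        mask = ~np.uint64(3 << (2 * (w - 1 - j)))
        keys = packed & mask
        _, inv, cnt = np.unique(keys, return_inverse=True, return_counts=True)
        total += cnt[inv]
    _, inv, cnt = np.unique(packed, return_inverse=True, return_counts=True)
    return total - (w - 1) * cnt[inv]


def _seed_words(win: _Windows, n_seeds: int) -> list[np.ndarray]:
    """Top distinct clean words by occurrence count within one mismatch;
    deterministic ordering (count desc, word asc)."""
    if not win.clean.any():
        return []
    w = win.mat.shape[1]
    packed_all = _pack_words(win.mat)
    occ = _one_mismatch_occurrence(packed_all, w)
    cand, first = np.unique(packed_all[win.clean], return_index=True)
    cand_occ = occ[np.flatnonzero(win.clean)[first]]
    order = np.lexsort((cand, -cand_occ))[:n_seeds]
    return [_unpack_word(int(cand[i]), w) for i in order]


def _one_hot(mat: np.ndarray) -> np.ndarray:
    """(n, 4w) float32 one-hot of an (n, w) base-index matrix."""
    n, w = mat.shape
    X = np.zeros((n, 4 * w), dtype=np.float32)
    rows = np.arange(n)
    for j in range(w):
        X[rows, mat[:, j].astype(np.int64) * w + j] = 1.0
    return X


def _em_zoops(win: _Windows, X: np.ndarray, theta0: np.ndarray, bg: np.ndarray,
              tol: float, max_iter: int, pseudocount: float
              ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Run ZOOPS EM from an initial PWM; returns (theta, Z, gamma, loglik).

    ``X`` is the one-hot window matrix; the likelihood-ratio and M-step
    updates are single matrix products against it.
    """
    w = theta0.shape[1]
    m_per_seq = np.bincount(win.seq_idx, minlength=win.n_seqs).astype(float)
    m_per_seq[m_per_seq == 0] = 1.0
    theta, gamma = theta0, 0.5
    prev_ll = -np.inf
    Z = np.zeros(len(win))
    for _ in range(max_iter):
        log_ratio = (np.log(theta) - np.log(bg)[:, None]).astype(np.float32)
        lr = np.exp(X @ log_ratio.ravel(), dtype=np.float32).astype(float)
        # E-step
        seq_sum = np.bincount(win.seq_idx, weights=lr, minlength=win.n_seqs)
        denom = (1.0 - gamma) + gamma / m_per_seq * seq_sum
        Z = (gamma / m_per_seq[win.seq_idx]) * lr / denom[win.seq_idx]
        ll = float(np.log(denom).sum())
        # M-step
        counts = (X.T @ Z.astype(np.float32)).reshape(4, w).astype(float)
        counts += pseudocount
        theta = counts / counts.sum(axis=0)
        q = np.bincount(win.seq_idx, weights=Z, minlength=win.n_seqs)
        gamma = float(np.clip(q.mean(), 1e-4, 1 - 1e-4))
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return theta, Z, gamma, prev_ll


def run_em_finder(promoters, config: FinderConfig = FinderConfig()) -> list[MotifPrediction]:
    """ZOOPS EM finder; deterministic given input order and config.seed."""
    pairs, enc, lower = _prepare(promoters, config.width)
    bg = background_from_sequences([s for _, s in pairs]).stationary()
    work = [e.copy() for e in enc]
    motifs: list[MotifPrediction] = []
    w, cols = config.width, np.arange(config.width)
    for mi in range(config.n_motifs):
        win = _build_windows(work, lower, w, config.both_strands)
        if len(win) == 0:
            break
        seeds = _seed_words(win, config.n_seeds)
        if not seeds:
            break
        X = _one_hot(win.mat)
        best = None
        for seed in seeds:
            theta0 = np.full((4, w), 0.1)
            theta0[seed, cols] = 0.7
            fit = _em_zoops(win, X, theta0, bg, config.tol, config.max_iter,
                            config.pseudocount)
            if best is None or fit[3] > best[3]:
                best = fit
        theta, Z, gamma, ll = best
        # hard site assignment: best window of each sequence whose posterior
        # occupancy exceeds 1/2
        q = np.bincount(win.seq_idx, weights=Z, minlength=win.n_seqs)
        log_ratio = np.log(theta) - np.log(bg)[:, None]
        lo_bits = (np.log2(theta) - np.log2(bg)[:, None])
        sites: list[Site] = []
        site_rows = []
        for i in range(win.n_seqs):
            if q[i] <= 0.5:
                continue
            mask = win.seq_idx == i
            if not mask.any():
                continue
            zi = np.where(mask, Z, -np.inf)
            # tie-break: highest Z, then leftmost, then '+' strand
            order = np.lexsort((win.strand, win.pos, -zi))
            j = order[0]
            row = win.mat[j]
            score = float(lo_bits[row, cols].sum())
            sites.append(Site(pairs[i][0], int(win.pos[j]), int(win.pos[j]) + w,
                              "+-"[win.strand[j]], score))
            site_rows.append(row)
        if len(sites) < 2:
            break
        sites.sort(key=_site_sort_key(pairs))
        pwm = build_pwm([decode(r) for r in site_rows], config.pseudocount,
                        name=f"em_{mi + 1}")
        motifs.append(MotifPrediction(pwm, "em", tuple(sites), ll))
        _erase_sites(work, pairs, tuple(sites))
    motifs.sort(key=lambda m: -m.engine_score)
    return [replace(m, pwm=m.pwm.with_name(f"em_{i + 1}"))
            for i, m in enumerate(motifs)]


# ---------------------------------------------------------------------------
# Gibbs site sampler


def run_gibbs_finder(promoters, config: FinderConfig = FinderConfig()) -> list[MotifPrediction]:
    """Gibbs site-sampler; stochastic — identical output only for equal seed."""
    pairs, enc, lower = _prepare(promoters, config.width)
    bg = background_from_sequences([s for _, s in pairs]).stationary()
    rng = np.random.default_rng(config.seed)
    work = [e.copy() for e in enc]
    w, cols = config.width, np.arange(config.width)
    pc = config.gibbs_pseudocount
    motifs: list[MotifPrediction] = []
    for mi in range(config.n_motifs):
        win = _build_windows(work, lower, w, config.both_strands)
        if len(win) == 0:
            break
        per_seq = [np.flatnonzero(win.seq_idx == i) for i in range(win.n_seqs)]
        active = [i for i in range(win.n_seqs) if len(per_seq[i])]
        if len(active) < 2:
            break
        # data-driven start: each sequence's window closest to the best seed
        # word (random start only if no clean seed exists); the sampler then
        # explores around the mode instead of relying on a lucky random init
        seeds = _seed_words(win, 1)
        if seeds:
            cur = {}
            for i in active:
                mism = (win.mat[per_seq[i]] != seeds[0]).sum(axis=1)
                j = np.lexsort((win.strand[per_seq[i]], win.pos[per_seq[i]],
                                mism))[0]
                cur[i] = per_seq[i][j]
        else:
            cur = {i: per_seq[i][rng.integers(len(per_seq[i]))] for i in active}
        row_at = {(int(win.seq_idx[r]), int(win.pos[r]), int(win.strand[r])): r
                  for r in range(len(win))}

        def counts_from(rows) -> np.ndarray:
            c = np.zeros((4, w)) + pc
            for r in rows:
                c[win.mat[r], cols] += 1
            return c

        def joint_score(state) -> float:
            c = counts_from(state.values())
            theta = c / c.sum(axis=0)
            log_ratio = np.log(theta) - np.log(bg)[:, None]
            return float(sum(log_ratio[win.mat[r], cols].sum()
                             for r in state.values()))

        def shifted(state, delta):
            """All sites moved by delta in motif orientation, or None if any
            shifted window is unavailable (edge or masked)."""
            out = {}
            for i, r in state.items():
                step = delta if win.strand[r] == 0 else -delta
                key = (i, int(win.pos[r]) + step, int(win.strand[r]))
                if key not in row_at:
                    return None
                out[i] = row_at[key]
            return out

        best_score, best_cur = -np.inf, dict(cur)
        for sweep in range(config.burn_in + config.n_samples):
            for i in active:
                others = [cur[k] for k in active if k != i]
                c = counts_from(others)
                theta = c / c.sum(axis=0)
                log_ratio = np.log(theta) - np.log(bg)[:, None]
                rows = win.mat[per_seq[i]]
                logw = log_ratio[rows, cols].sum(axis=1)
                p = np.exp(logw - logw.max())
                p /= p.sum()
                cur[i] = per_seq[i][rng.choice(len(per_seq[i]), p=p)]
            # phase-shift move: realign all sites together if that improves
            # the joint score (the site sampler cannot fix phase one
            # sequence at a time)
            if sweep % 10 == 9 or sweep == config.burn_in + config.n_samples - 1:
                cur_score = joint_score(cur)
                for delta in [d for k in range(1, w // 2 + 1) for d in (-k, k)]:
                    cand = shifted(cur, delta)
                    if cand is not None:
                        s = joint_score(cand)
                        if s > cur_score:
                            cur, cur_score = cand, s
            if sweep >= config.burn_in:
                score = joint_score(cur)
                if score > best_score:
                    best_score, best_cur = score, dict(cur)
        c = counts_from(best_cur.values())
        theta = c / c.sum(axis=0)
        lo_bits = np.log2(theta) - np.log2(bg)[:, None]
        sites, site_rows = [], []
        for i in active:
            r = best_cur[i]
            row = win.mat[r]
            sites.append(Site(pairs[i][0], int(win.pos[r]), int(win.pos[r]) + w,
                              "+-"[win.strand[r]], float(lo_bits[row, cols].sum())))
            site_rows.append(row)
        sites.sort(key=_site_sort_key(pairs))
        pwm = build_pwm([decode(r) for r in site_rows], pc, name=f"gibbs_{mi + 1}")
        motifs.append(MotifPrediction(pwm, "gibbs", tuple(sites), best_score))
        _erase_sites(work, pairs, tuple(sites))
    motifs.sort(key=lambda m: -m.engine_score)
    return [replace(m, pwm=m.pwm.with_name(f"gibbs_{i + 1}"))
            for i, m in enumerate(motifs)]


# ---------------------------------------------------------------------------
# consensus enumeration


def _neighborhood_match_prob(words: np.ndarray, d: int, bg: np.ndarray) -> np.ndarray:
    """P(a random background window is within d' mismatches of each word) for
    every stringency d' = 0..d: Poisson-binomial tail over per-position match
    probabilities, by DP.  ``words`` is an (n, L) base-index matrix; returns
    an (n, d+1) matrix of cumulative probabilities."""
    n, L = words.shape
    # dp[:, k] = P(exactly k mismatches so far); k = d+1 absorbs overflow
    dp = np.zeros((n, d + 2))
    dp[:, 0] = 1.0
    for j in range(L):
        p_match = bg[words[:, j]]
        nxt = np.zeros_like(dp)
        nxt[:, : d + 1] += dp[:, : d + 1] * p_match[:, None]
        nxt[:, 1:] += dp[:, :-1] * (1 - p_match[:, None])
        nxt[:, d + 1] += dp[:, d + 1]  # absorbing overflow state
        dp = nxt
    return dp[:, : d + 1].cumsum(axis=1)


def _unpack_words(packed: np.ndarray, w: int) -> np.ndarray:
    """(n, w) base-index matrix from packed uint64 words."""
    out = np.zeros((len(packed), w), dtype=np.int8)
    for j in range(w - 1, -1, -1):
        out[:, j] = (packed & np.uint64(3)).astype(np.int8)
        packed = packed >> np.uint64(2)
    return out


def run_consensus_finder(promoters, config: FinderConfig = FinderConfig()) -> list[MotifPrediction]:
    """Exhaustive word enumeration with mismatches; fully deterministic.

    At length 6 every 4^6 word is enumerated; at lengths 8 and 10 the
    candidates are the words actually occurring in the input (either strand),
    which always include any planted exact word.  A word is a candidate motif
    if it occurs (within its mismatch budget) in at least ``quorum`` of the
    sequences; candidates are scored by -log10 of the binomial upper-tail
    probability of the observed total occurrence count under the background.
    """
    pairs, enc, lower = _prepare(promoters, min(L for L, _ in config.schedule))
    bg = background_from_sequences([s for _, s in pairs]).stationary()
    # first pass: score every candidate word per schedule entry, keep arrays
    scored: list[tuple[float, int, int, int]] = []  # (score, L, d, packed word)
    windows_by_len: dict[int, _Windows] = {}
    for L, d in config.schedule:
        win = _build_windows(enc, lower, L, config.both_strands)
        if len(win) == 0:
            continue
        windows_by_len[L] = win
        packed = _pack_words(win.mat)
        if L == 6:
            cand = np.arange(4 ** L, dtype=np.uint64)
        else:
            pool = packed[win.clean] if win.clean.any() else packed
            cand = np.unique(pool)
            # both strands are scanned, so a word and its reverse complement
            # have identical occurrence counts: keep one representative
            rc = _pack_words(3 - _unpack_words(cand, L)[:, ::-1])
            cand = np.unique(np.minimum(cand, rc))
        need = int(np.ceil(config.quorum * win.n_seqs))
        n_windows = len(packed)
        # seq_idx is non-decreasing; segment boundaries for per-seq counting
        seg = np.flatnonzero(np.r_[True, np.diff(win.seq_idx) != 0])
        # occurrence counts at every stringency d' = 0..d
        k_obs = np.zeros((len(cand), d + 1), dtype=np.int64)
        n_seq_hit = np.zeros(len(cand), dtype=np.int64)
        chunk = max(1, int(4e7) // max(1, n_windows))
        for a in range(0, len(cand), chunk):
            sub = cand[a : a + chunk]
            mm = _mismatch_counts(packed, sub)
            for dp in range(d + 1):
                k_obs[a : a + chunk, dp] = (mm <= dp).sum(axis=1)
            per_seq = np.add.reduceat(mm <= d, seg, axis=1)
            n_seq_hit[a : a + chunk] = (per_seq > 0).sum(axis=1)
        ok = n_seq_hit >= need
        if not ok.any():
            continue
        words = _unpack_words(cand[ok], L)
        p_word = _neighborhood_match_prob(words, d, bg)  # (n_ok, d+1)
        pvals = stats.binom.sf(k_obs[ok] - 1, n_windows, p_word)
        # best evidence over stringencies: a word that matches exactly in many
        # sequences should not be diluted by its full mismatch neighbourhood
        scores = (-np.log10(np.maximum(pvals, 1e-300))).max(axis=1)
        scored.extend(
            (float(s), L, d, int(wd)) for s, wd in zip(scores, cand[ok])
        )
    # score desc, then shorter word, then lexicographically smaller word
    scored.sort(key=lambda t: (-t[0], t[1], t[3]))
    motifs: list[MotifPrediction] = []
    key = _site_sort_key(pairs)
    taken: dict[str, set[int]] = {}  # positions already claimed per sequence
    for score, L, d, word in scored:
        if len(motifs) >= config.n_motifs:
            break
        win = windows_by_len[L]
        wordvec = _unpack_word(word, L)
        mism = (win.mat != wordvec).sum(axis=1)
        hit_idx = np.flatnonzero(mism <= d)
        sites = [
            Site(pairs[win.seq_idx[r]][0], int(win.pos[r]), int(win.pos[r]) + L,
                 "+-"[win.strand[r]], float(L - mism[r]))
            for r in hit_idx
        ]
        sites.sort(key=key)
        # suppress shifted/substring variants of already-reported words: skip
        # a word whose occurrences mostly lie on positions already claimed
        covered = sum(
            1 for s in sites
            if len(taken.get(s.seq_id, set()).intersection(range(s.start, s.end)))
            >= (s.end - s.start) / 2
        )
        if motifs and covered >= len(sites) / 2:
            continue
        for s in sites:
            taken.setdefault(s.seq_id, set()).update(range(s.start, s.end))
        pwm = build_pwm([decode(win.mat[r]) for r in hit_idx],
                        config.pseudocount, name=f"consensus_{len(motifs) + 1}")
        motifs.append(MotifPrediction(pwm, "consensus", tuple(sites),
                                      float(score), word=decode(wordvec)))
    return motifs


ENGINES = {
    "em": run_em_finder,
    "gibbs": run_gibbs_finder,
    "consensus": run_consensus_finder,
}


def run_finder(engine: str, promoters, config: FinderConfig = FinderConfig()):
    try:
        fn = ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown engine {engine!r}; choose from {sorted(ENGINES)}")
    return fn(promoters, config)
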