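"""Position weight matrices, consensus calling, log-odds scoring, Markov backgrounds.

Bases are indexed A=0, C=1, G=2, T=3 everywhere.  A Pwm stores raw site counts
plus a pseudocount; probabilities are derived as
(count + pseudocount) / (n_sites + 4*pseudocount) per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "BASES",
    "BASE_INDEX",
    "IUPAC_TWO",
    "Pwm",
    "MarkovBackground",
    "build_pwm",
    "encode",
    "decode",
    "write_pwms",
    "read_pwms",
    "read_meme_motifs",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# two-base ambiguity codes, unordered pairs
IUPAC_TWO = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 (A=0,C=1,G=2,T=3; N and other -> 4).

    Lowercase (soft-masked) bases encode like their uppercase forms.
    """
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in arr)


@dataclass(frozen=True)
class Pwm:
    """A nucleotide position weight matrix.

    ``counts`` is 4 x width (rows A,C,G,T); ``probs`` is derived with the
    pseudocount and every column sums to 1.
    """

    counts: np.ndarray
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def n_sites(self) -> float:
        return float(self.counts[:, 0].sum())

    @property
    def probs(self) -> np.ndarray:
        denom = self.counts.sum(axis=0) + 4 * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    def log_odds(self, background: "MarkovBackground | np.ndarray | None" = None) -> np.ndarray:
        """4 x width log2 odds matrix vs an order-0 background (default uniform).

        Zero-probability cells map to -inf.
        """
        bg = _order0_freqs(background)
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(bg)[:, None]

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits vs uniform background."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + h.sum(axis=0)

    def consensus(self) -> str:
        """IUPAC consensus: top base if P >= 0.5; two-base code if the top two
        jointly reach 0.75; otherwise N."""
        out = []
        for col in self.probs.T:
            order = np.argsort(-col, kind="stable")
            if col[order[0]] >= 0.5:
                out.append(BASES[order[0]])
            elif col[order[0]] + col[order[1]] >= 0.75:
                out.append(IUPAC_TWO[frozenset(BASES[order[0]] + BASES[order[1]])])
            else:
                out.append("N")
        return "".join(out)

    def reverse_complement(self) -> "Pwm":
        """Columns reversed, A<->T and C<->G swapped; an involution."""
        rc = self.counts[::-1, ::-1].copy()
        return Pwm(rc, self.pseudocount, name=self.name + "_rc")

    def with_name(self, name: str) -> "Pwm":
        return Pwm(self.counts, self.pseudocount, name=name)


def build_pwm(sites: list[str], pseudocount: float = 0.0, name: str = "motif") -> Pwm:
    """Build a Pwm from equal-length ACGT site strings."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must all have the same length")
    counts = np.zeros((4, w))
    for si, s in enumerate(sites):
        for j, ch in enumerate(s.upper()):
            if ch not in BASE_INDEX:
                raise ValueError(
                    f"non-ACGT character {ch!r} in site {si} position {j}"
                )
            counts[BASE_INDEX[ch], j] += 1
    return Pwm(counts, pseudocount, name=name)


def _order0_freqs(background) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    if isinstance(background, MarkovBackground):
        if background.order != 0:
            raise ValueError("log-odds scoring takes an order-0 background")
        return background.stationary()
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    return bg


def log_odds_score(pwm: Pwm, window: str, background=None) -> float:
    """Sum over columns of log2(P_motif(base) / P_bg(base)), in bits.

    The window must be exactly pwm.width long and contain no N; callers skip
    N-containing windows.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != pwm width {pwm.width}")
    idx = encode(window)
    if (idx > 3).any():
        raise ValueError("window contains non-ACGT characters; caller must skip")
    lo = pwm.log_odds(background)
    return float(lo[idx, np.arange(pwm.width)].sum())


@dataclass(frozen=True)
class MarkovBackground:
    """Order-k Markov chain over ACGT.

    ``probs`` maps each length-k context string to a 4-vector of conditional
    probabilities (k=0: single entry with context "").
    """

    order: int
    probs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        for ctx, p in self.probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (4,) or not np.isclose(p.sum(), 1.0, atol=1e-9):
                raise ValueError(f"conditional distribution for {ctx!r} must sum to 1")
            self.probs[ctx] = p

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovBackground":
        ctxs = [""] if order == 0 else _all_kmers(order)
        return cls(order, {c: np.full(4, 0.25) for c in ctxs})

    @classmethod
    def from_frequencies(cls, freqs) -> "MarkovBackground":
        f = np.asarray(freqs, dtype=float)
        return cls(0, {"": f / f.sum()})

    def stationary(self) -> np.ndarray:
        """Marginal base frequencies (order 0: the distribution itself;
        higher orders: empirical mean over contexts)."""
        if self.order == 0:
            return self.probs[""]
        return np.mean([p for p in self.probs.values()], axis=0)

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """Draw one sequence of the given length from the chain."""
        out: list[str] = []
        for i in range(length):
            ctx = "".join(out[-self.order:]) if self.order else ""
            if len(ctx) < self.order or ctx not in self.probs:
                p = self.stationary()
            else:
                p = self.probs[ctx]
            out.append(BASES[rng.choice(4, p=p)])
        return "".join(out)

    def log_likelihood(self, seq: str) -> float:
        """Natural-log likelihood of an ACGT string under the chain."""
        total = 0.0
        for i, ch in enumerate(seq):
            ctx = seq[max(0, i - self.order): i]
            if len(ctx) < self.order or ctx not in self.probs:
                p = self.stationary()
            else:
                p = self.probs[ctx]
            total += float(np.log(p[BASE_INDEX[ch]]))
        return total


def _all_kmers(k: int) -> list[str]:
    kmers = [""]
    for _ in range(k):
        kmers = [s + b for s in kmers for b in BASES]
    return kmers


def background_from_sequences(seqs: list[str]) -> MarkovBackground:
    """Order-0 background from observed base frequencies (N excluded)."""
    counts = np.zeros(4)
    for s in seqs:
        idx = encode(s)
        counts += np.bincount(idx[idx < 4], minlength=4)
    if counts.sum() == 0:
        return MarkovBackground.uniform(0)
    return MarkovBackground.from_frequencies(counts)


# ---------------------------------------------------------------------------
# PWM text format:  ">name width=w" then four rows "A p1 p2 ... pw" etc.

def write_pwms(path: str | Path, pwms: list[Pwm]) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} width={pwm.width}\n")
            for b, row in zip(BASES, pwm.probs):
                fh.write(b + " " + " ".join(f"{p:.6f}" for p in row) + "\n")


def read_pwms(path: str | Path) -> list[Pwm]:
    pwms: list[Pwm] = []
    name, rows = None, {}
    def flush():
        if name is None:
            return
        if set(rows) != set(BASES):
            raise ValueError(f"motif {name!r}: need exactly rows A,C,G,T")
        mat = np.array([rows[b] for b in BASES])
        pwms.append(Pwm(mat, 0.0, name=name))
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            flush()
            name, rows = s[1:].split()[0], {}
        else:
            b, *vals = s.split()
            rows[b.upper()] = [float(v) for v in vals]
    flush()
    return pwms


def read_meme_motifs(path: str | Path) -> list[Pwm]:
    """Read letter-probability matrices from a minimal MEME text file."""
    pwms: list[Pwm] = []
    lines = Path(path).read_text().splitlines()
    i, name = 0, None
    while i < len(lines):
        s = lines[i].strip()
        if s.startswith("MOTIF"):
            parts = s.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(pwms) + 1}"
        elif s.startswith("letter-probability matrix"):
            rows = []
            i += 1
            while i < len(lines):
                t = lines[i].strip()
                if not t or not t[0].isdigit() and not t.startswith(("0", "1", ".")):
                    break
                rows.append([float(v) for v in t.split()])
                i += 1
            mat = np.array(rows).T  # MEME rows are positions, columns ACGT
            pwms.append(Pwm(mat, 0.0, name=name or f"motif{len(pwms) + 1}"))
            continue
        i += 1
    return pwms
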