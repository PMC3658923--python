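"""Nucleotide-level evaluation of motif predictions against planted truth.

Every nucleotide position in every evaluated sequence is labelled positive or
negative by the union of site intervals, strand-agnostically, for both the
truth and the prediction; the confusion counts then give
nSn = nTP/(nTP+nFN), nFDR = nFP/(nFP+nTP) and the Matthews-style nucleotide
correlation coefficient nCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_nucleotides",
    "metrics",
    "aggregate",
    "percent_change",
    "partition_true_positives",
]

Interval = tuple[str, int, int]  # (seq_id, start, end); extra fields ignored


@dataclass(frozen=True)
class ConfusionCounts:
    nTP: int
    nFP: int
    nFN: int
    nTN: int

    def __post_init__(self) -> None:
        if min(self.nTP, self.nFP, self.nFN, self.nTN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.nTP + self.nFP + self.nFN + self.nTN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.nTP + other.nTP, self.nFP + other.nFP,
                               self.nFN + other.nFN, self.nTN + other.nTN)


@dataclass
class MetricReport:
    """Per-dataset confusion counts and derived metrics, plus averages.

    Metrics with undefined denominators are ``None`` (reported as
    not-available), never silently zero.
    """

    counts: list[ConfusionCounts]
    labels: list[str] = field(default_factory=list)

    def per_dataset(self) -> list[dict]:
        rows = []
        for i, cc in enumerate(self.counts):
            nSn, nCC, nFDR = metrics(cc)
            rows.append({
                "dataset": self.labels[i] if i < len(self.labels) else str(i),
                "nTP": cc.nTP, "nFP": cc.nFP, "nFN": cc.nFN, "nTN": cc.nTN,
                "nSn": nSn, "nCC": nCC, "nFDR": nFDR,
            })
        return rows

    def averages(self) -> dict:
        return aggregate(self.counts)


def _mask(intervals, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    masks = {sid: np.zeros(L, dtype=bool) for sid, L in lengths.items()}
    for iv in intervals:
        sid, start, end = iv[0], int(iv[1]), int(iv[2])
        if sid not in masks:
            raise ValueError(f"site on unknown sequence {sid!r}")
        if start < 0 or end > lengths[sid] or start > end:
            raise ValueError(
                f"site [{start},{end}) outside sequence {sid!r} of length {lengths[sid]}"
            )
        masks[sid][start:end] = True
    return masks


def confusion_nucleotides(truth_sites, predicted_sites,
                          seq_lengths: dict[str, int]) -> ConfusionCounts:
    """Per-nucleotide confusion counts summed over sequences.

    Sites are (seq_id, start, end, ...) tuples or objects with those
    attributes; positions covered by any site on either strand count as
    positive.
    """
    truth = _mask(_as_intervals(truth_sites), seq_lengths)
    pred = _mask(_as_intervals(predicted_sites), seq_lengths)
    tp = fp = fn = tn = 0
    for sid in seq_lengths:
        t, p = truth[sid], pred[sid]
        tp += int((t & p).sum())
        fp += int((~t & p).sum())
        fn += int((t & ~p).sum())
        tn += int((~t & ~p).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _as_intervals(sites) -> list[Interval]:
    out = []
    for s in sites:
        if isinstance(s, tuple):
            out.append((s[0], int(s[1]), int(s[2])))
        else:
            out.append((s.seq_id, s.start, s.end))
    return out


def metrics(cc: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(nSn, nCC, nFDR); an undefined metric is None, never 0."""
    nSn = cc.nTP / (cc.nTP + cc.nFN) if cc.nTP + cc.nFN > 0 else None
    nFDR = cc.nFP / (cc.nFP + cc.nTP) if cc.nFP + cc.nTP > 0 else None
    denom = ((cc.nTP + cc.nFN) * (cc.nTN + cc.nFP)
             * (cc.nTP + cc.nFP) * (cc.nTN + cc.nFN))
    if denom > 0:
        nCC = (cc.nTP * cc.nTN - cc.nFN * cc.nFP) / math.sqrt(denom)
    else:
        nCC = None
    return nSn, nCC, nFDR


def percent_change(a: float, b: float) -> float:
    """Percent change from a to b, (a - b) / a * 100, to one decimal."""
    if a == 0:
        raise ValueError("percent change from zero is undefined")
    return round((a - b) / a * 100, 1)


def aggregate(counts: list[ConfusionCounts]) -> dict:
    """Unweighted arithmetic means over datasets.

    Count means are also given rounded to the nearest integer for display
    (matching printed benchmark tables); metric means skip datasets where a
    metric is undefined.
    """
    if not counts:
        raise ValueError("need at least one report")
    out: dict = {}
    for name in ("nTP", "nFP", "nFN", "nTN"):
        vals = [getattr(c, name) for c in counts]
        out[f"mean_{name}"] = float(np.mean(vals))
        out[f"mean_{name}_display"] = int(round(float(np.mean(vals))))
    for mi, name in enumerate(("nSn", "nCC", "nFDR")):
        vals = [metrics(c)[mi] for c in counts]
        vals = [v for v in vals if v is not None]
        out[f"mean_{name}"] = float(np.mean(vals)) if vals else None
    return out


def partition_true_positives(per_engine_predictions: dict[str, list],
                             truth_sites, seq_lengths: dict[str, int]) -> dict[str, float]:
    """Fractions of true-positive nucleotides attributable to each engine alone
    or shared (predicted by at least two engines).

    Returns {engine: fraction, ..., "shared": fraction}; fractions sum to 1
    whenever any true-positive nucleotide exists, else all are 0.
    """
    if len(per_engine_predictions) < 2:
        raise ValueError("need predictions from at least two engines")
    truth = _mask(_as_intervals(truth_sites), seq_lengths)
    engine_masks = {
        e: _mask(_as_intervals(sites), seq_lengths)
        for e, sites in per_engine_predictions.items()
    }
    engines = sorted(per_engine_predictions)
    tallies = {e: 0 for e in engines}
    tallies["shared"] = 0
    total = 0
    for sid, L in seq_lengths.items():
        hit = np.stack([engine_masks[e][sid] for e in engines])
        n_pred = hit.sum(axis=0)
        tp = truth[sid] & (n_pred > 0)
        total += int(tp.sum())
        tallies["shared"] += int((tp & (n_pred >= 2)).sum())
        for ei, e in enumerate(engines):
            only = tp & (n_pred == 1) & hit[ei]
            tallies[e] += int(only.sum())
    if total == 0:
        return {k: 0.0 for k in tallies}
    return {k: v / total for k, v in tallies.items()}
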