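"""End-to-end orchestration: the discovery model, its results, and the
benchmark harness.

:class:`MotifDiscovery` is a statsmodels-style model object: it is built from
data (an input promoter set plus a genome promoter database) and a
configuration; :meth:`MotifDiscovery.fit` runs the full pipeline — three
discovery engines, per-engine background filters, combination, MNCP ranking,
positional histograms and (when a genome and annotations are supplied)
genome-wide retrieval with GO enrichment — and returns a
:class:`MotifDiscoveryResults` carrying every intermediate, a summary table
and TSV writers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import (
    ConfusionCounts,
    confusion_nucleotides,
    metrics,
    aggregate,
    partition_true_positives,
)
from .ensemble import (
    PositionHistogram,
    RankedMotif,
    combine,
    position_histogram,
    rank_motifs,
)
from .filtering import DEFAULT_CUTOFFS, FilterResult, filter_motifs
from .finders import ENGINES, FinderConfig, MotifPrediction, run_finder
from .io import PromoterDb, promoters_from_bed, read_fasta, PromoterRecord
from .scan import genome_retrieval, go_enrichment
from .synth import BenchmarkDataset, make_dataset

__all__ = [
    "PipelineConfig",
    "MotifDiscovery",
    "MotifDiscoveryResults",
    "BenchmarkResults",
    "run_pipeline",
    "run_benchmark",
]

log = logging.getLogger("motifweave")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of a pipeline run; the seed is recorded in all outputs."""

    finder: FinderConfig = field(default_factory=FinderConfig)
    cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    scan_p_threshold: float = 1e-4
    n_random: int | None = None  # MNCP random-sample size; None = default rule
    background_sample_size: int = 1000
    bin_width: int = 20
    seed: int = 0
    run_retrieval: bool = True
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        for eng, c in self.cutoffs.items():
            if not 0 < c < 1:
                raise ValueError(f"cutoff for {eng!r} must lie in (0,1)")

    def config_hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "finder": asdict(self.finder)}, sort_keys=True,
            default=str,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


class MotifDiscovery:
    """Ensemble motif discovery model over a set of co-expressed promoters.

    Parameters
    ----------
    input_db
        Promoters of the co-expressed gene set (PromoterDb or iterable of
        PromoterRecord / (id, seq) pairs).  At least 2 promoters.
    genome_db
        The genome-wide promoter database used for filtering, MNCP ranking
        and retrieval; optional only when filters and ranking are not wanted.
    annotations
        Optional gene -> GO AnnotationTable for enrichment of retrieved genes.
    config
        PipelineConfig; defaults follow the pipeline's standard settings
        (10 motifs per engine, widths 6-10, cutoffs 0.7/0.3/0.05, scan
        p <= 1e-4).
    """

    def __init__(self, input_db, genome_db: PromoterDb | None = None,
                 annotations=None, config: PipelineConfig | None = None):
        records = [r if isinstance(r, PromoterRecord)
                   else PromoterRecord(r[0], r[1]) for r in input_db]
        if len(records) < 2:
            raise ValueError(
                "need at least 2 promoters: motif discovery is diluted or "
                "impossible on singleton gene sets; supply a larger cluster"
            )
        self.input_db = PromoterDb(records, source="user input")
        self.genome_db = genome_db
        self.annotations = annotations
        self.config = config or PipelineConfig()

    # -- alternative constructors -------------------------------------------

    @classmethod
    def from_gene_ids(cls, gene_ids: list[str], genome_db: PromoterDb,
                      annotations=None, config: PipelineConfig | None = None):
        """Resolve gene ids against the genome promoter db.

        Unknown ids are reported and skipped; the run continues if at least
        2 remain.
        """
        known = [g for g in gene_ids if g in genome_db]
        unknown = [g for g in gene_ids if g not in genome_db]
        if unknown:
            warnings.warn(f"{len(unknown)} unknown gene ids skipped: "
                          f"{unknown[:10]}", stacklevel=2)
        if len(known) < 2:
            raise ValueError(
                f"fewer than 2 input gene ids resolve against the promoter db "
                f"(unknown: {unknown[:10]})"
            )
        return cls(genome_db.subset(known), genome_db, annotations, config)

    @classmethod
    def from_fasta(cls, fasta_path, genome_db=None, annotations=None,
                   config=None):
        recs = [PromoterRecord(rid, seq) for rid, seq in read_fasta(fasta_path)]
        return cls(recs, genome_db, annotations, config)

    @classmethod
    def from_bed(cls, bed_path, genome_fasta, genome_db=None, annotations=None,
                 config=None):
        return cls(promoters_from_bed(bed_path, genome_fasta), genome_db,
                   annotations, config)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "MotifDiscoveryResults":
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed,
                          finder=replace(cfg.finder, seed=seed))
        log.info("fit: %d input promoters, seed=%d, config=%s",
                 len(self.input_db), cfg.seed, cfg.config_hash())
        predictions: dict[str, list[MotifPrediction]] = {}
        for engine in sorted(ENGINES):
            fc = replace(cfg.finder, seed=cfg.seed)
            predictions[engine] = run_finder(engine, self.input_db, fc)
            log.info("engine %s: %d motifs", engine, len(predictions[engine]))
        filtered: dict[str, list[FilterResult]] = {}
        if self.genome_db is not None:
            for engine, preds in predictions.items():
                filtered[engine] = filter_motifs(
                    preds, engine, self.input_db, self.genome_db,
                    seed=cfg.seed, cutoffs=cfg.cutoffs,
                    scan_p_threshold=cfg.scan_p_threshold,
                    background_sample_size=cfg.background_sample_size,
                ) if preds else []
            combined = combine(list(filtered.values()))
        else:
            combined = [m for preds in predictions.values() for m in preds]
        if not combined:
            warnings.warn("all motifs failed their filters; nothing to rank",
                          stacklevel=2)
            ranked: list[RankedMotif] = []
        elif self.genome_db is not None:
            ranked = rank_motifs(combined, self.input_db, self.genome_db,
                                 n_random=cfg.n_random, seed=cfg.seed,
                                 scan_p_threshold=cfg.scan_p_threshold)
        else:
            ranked = [RankedMotif(m, 0.0, i + 1, note="not ranked (no genome db)")
                      for i, m in enumerate(combined)]
        lengths = {r.gene_id: r.length for r in self.input_db}
        histograms = {
            rm.motif.name: position_histogram(list(rm.motif.sites), lengths,
                                              cfg.bin_width)
            for rm in ranked
        }
        retrieval: dict[str, dict[str, int]] = {}
        enrichment: dict[str, list] = {}
        if self.genome_db is not None and cfg.run_retrieval:
            for rm in ranked:
                retrieval[rm.motif.name] = genome_retrieval(
                    rm.motif.pwm, self.genome_db, cfg.scan_p_threshold)
                if self.annotations is not None and cfg.run_enrichment:
                    genes = sorted(retrieval[rm.motif.name])
                    genes = [g for g in genes
                             if g in self.annotations.annotated_genes()]
                    if genes:
                        enrichment[rm.motif.name] = go_enrichment(
                            genes, self.annotations)
        return MotifDiscoveryResults(
            model=self, config=cfg, predictions=predictions, filtered=filtered,
            ranked=ranked, histograms=histograms, retrieval=retrieval,
            enrichment=enrichment,
        )


@dataclass
class MotifDiscoveryResults:
    """Everything a pipeline fit produced; summary() gives the ranked table."""

    model: MotifDiscovery
    config: PipelineConfig
    predictions: dict[str, list[MotifPrediction]]
    filtered: dict[str, list[FilterResult]]
    ranked: list[RankedMotif]
    histograms: dict[str, PositionHistogram]
    retrieval: dict[str, dict[str, int]]
    enrichment: dict[str, list]

    def summary(self) -> pd.DataFrame:
        rows = []
        for rm in self.ranked:
            rows.append({
                "rank": rm.rank,
                "motif": rm.motif.name,
                "engine": rm.motif.engine,
                "consensus": rm.motif.consensus(),
                "width": rm.motif.pwm.width,
                "n_sites": len(rm.motif.sites),
                "mncp": round(rm.mncp, 4),
                "note": rm.note,
            })
        return pd.DataFrame(rows, columns=["rank", "motif", "engine",
                                           "consensus", "width", "n_sites",
                                           "mncp", "note"])

    def filter_table(self) -> pd.DataFrame:
        rows = []
        for engine, results in sorted(self.filtered.items()):
            for fr in results:
                rows.append({
                    "motif": fr.motif.name, "engine": engine,
                    "test": fr.test, "k_input": fr.k_input,
                    "n_input": fr.n_input,
                    "bg": fr.bg_rate_p if fr.test == "binomial"
                    else f"{fr.K_bg}/{fr.N_bg}",
                    "p_value": fr.p_value, "cutoff": fr.cutoff,
                    "passed": fr.passed,
                })
        return pd.DataFrame(rows, columns=["motif", "engine", "test",
                                           "k_input", "n_input", "bg",
                                           "p_value", "cutoff", "passed"])

    def _header(self) -> str:
        return (f"# motifweave {__version__} seed={self.config.seed} "
                f"config={self.config.config_hash()}\n")

    def write(self, outdir: str | Path) -> None:
        """Write ranked motifs, filter report, PWMs, site BED, histograms and
        (when computed) retrieval gene lists and enrichment, as TSVs, each
        with a version/seed/config-hash header."""
        from .pwm import write_pwms

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def tsv(name: str, df: pd.DataFrame) -> None:
            with open(outdir / name, "w") as fh:
                fh.write(self._header())
                df.to_csv(fh, sep="\t", index=False)

        tsv("ranked_motifs.tsv", self.summary())
        tsv("filter_report.tsv", self.filter_table())
        write_pwms(outdir / "motifs.pwm", [rm.motif.pwm for rm in self.ranked])
        with open(outdir / "sites.bed", "w") as fh:
            fh.write(self._header())
            for rm in self.ranked:
                for s in rm.motif.sites:
                    fh.write(f"{s.seq_id}\t{s.start}\t{s.end}\t{rm.motif.name}"
                             f"\t{int(round(s.score * 100))}\t{s.strand}\n")
        hist_rows = []
        for name, hist in self.histograms.items():
            for (lo, hi), count in hist.sorted_items():
                hist_rows.append({"motif": name, "bin_start": lo,
                                  "bin_end": hi, "count": count})
        tsv("position_histograms.tsv",
            pd.DataFrame(hist_rows, columns=["motif", "bin_start", "bin_end",
                                             "count"]))
        if self.retrieval:
            rows = [{"motif": m, "gene_id": g, "copies": c}
                    for m, genes in sorted(self.retrieval.items())
                    for g, c in sorted(genes.items())]
            tsv("genome_retrieval.tsv",
                pd.DataFrame(rows, columns=["motif", "gene_id", "copies"]))
        if self.enrichment:
            rows = []
            for m, res in sorted(self.enrichment.items()):
                for er in res:
                    rows.append({"motif": m, "term": er.term_id,
                                 "name": er.term_name, "k": er.k, "n": er.n,
                                 "K": er.K, "N": er.N, "p_raw": er.p_raw,
                                 "p_adj": er.p_adj})
            tsv("go_enrichment.tsv",
                pd.DataFrame(rows, columns=["motif", "term", "name", "k", "n",
                                            "K", "N", "p_raw", "p_adj"]))


def run_pipeline(input_db, genome_db=None, annotations=None,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> MotifDiscoveryResults:
    """Convenience wrapper: build the model, fit, optionally write outputs."""
    res = MotifDiscovery(input_db, genome_db, annotations, config).fit()
    if outdir is not None:
        res.write(outdir)
    return res


# ---------------------------------------------------------------------------
# benchmark harness


@dataclass
class BenchmarkResults:
    """Nucleotide-level evaluation across datasets.

    ``table`` has one row per (variant, dataset) with confusion counts and
    metrics; variants are each engine unfiltered/filtered, plus the
    unfiltered and filtered unions.  ``partition`` holds the engine-only /
    shared attribution of filtered true-positive nucleotides.
    """

    table: pd.DataFrame
    partition: dict[str, float]

    def averages(self) -> pd.DataFrame:
        counts = {}
        for variant, grp in self.table.groupby("variant", sort=False):
            ccs = [ConfusionCounts(r.nTP, r.nFP, r.nFN, r.nTN)
                   for r in grp.itertuples()]
            counts[variant] = aggregate(ccs)
        return pd.DataFrame(counts).T

    def variant_mean(self, variant: str, column: str) -> float:
        sub = self.table[self.table["variant"] == variant][column].dropna()
        return float(sub.mean())


def _union_sites(motifs: list[MotifPrediction]):
    return [s for m in motifs for s in m.sites]


def evaluate_dataset(dataset: BenchmarkDataset, genome_db: PromoterDb,
                     config: PipelineConfig) -> tuple[list[dict], dict[str, list]]:
    """Run all engines on one dataset, filter, and score every variant."""
    lengths = dataset.seq_lengths()
    input_records = [PromoterRecord(sid, seq) for sid, seq in dataset.sequences]
    rows = []
    filtered_sites_per_engine: dict[str, list] = {}
    union_unfiltered: list[MotifPrediction] = []
    union_filtered: list[MotifPrediction] = []
    for engine in sorted(ENGINES):
        fc = replace(config.finder, seed=config.seed)
        preds = run_finder(engine, input_records, fc)
        fres = filter_motifs(preds, engine, input_records, genome_db,
                             seed=config.seed, cutoffs=config.cutoffs,
                             scan_p_threshold=config.scan_p_threshold,
                             background_sample_size=config.background_sample_size
                             ) if preds else []
        passed = [fr.motif for fr in fres if fr.passed]
        union_unfiltered.extend(preds)
        union_filtered.extend(passed)
        filtered_sites_per_engine[engine] = _union_sites(passed)
        for variant, motifs in ((engine, preds), (f"{engine}_filt", passed)):
            cc = confusion_nucleotides(dataset.truth, _union_sites(motifs),
                                       lengths)
            nSn, nCC, nFDR = metrics(cc)
            rows.append({"variant": variant, "nTP": cc.nTP, "nFP": cc.nFP,
                         "nFN": cc.nFN, "nTN": cc.nTN, "nSn": nSn, "nCC": nCC,
                         "nFDR": nFDR})
    for variant, motifs in (("combined", union_unfiltered),
                            ("combined_filt", union_filtered)):
        cc = confusion_nucleotides(dataset.truth, _union_sites(motifs), lengths)
        nSn, nCC, nFDR = metrics(cc)
        rows.append({"variant": variant, "nTP": cc.nTP, "nFP": cc.nFP,
                     "nFN": cc.nFN, "nTN": cc.nTN, "nSn": nSn, "nCC": nCC,
                     "nFDR": nFDR})
    return rows, filtered_sites_per_engine


def run_benchmark(datasets: list[BenchmarkDataset],
                  genome_db: PromoterDb | None = None,
                  config: PipelineConfig | None = None,
                  background_db_size: int = 200) -> BenchmarkResults:
    """Evaluate each engine alone (unfiltered and filtered) and the unions
    over a list of planted-motif datasets.

    When no genome db is supplied, a background promoter set of
    ``background_db_size`` implant-free sequences is generated from the first
    dataset's flavor to stand in for the genome during filtering.
    """
    if not datasets:
        raise ValueError("need at least one benchmark dataset")
    for d in datasets:
        if d.truth is None:
            raise ValueError("benchmark datasets must carry ground truth")
    config = config or PipelineConfig()
    if genome_db is None:
        first = datasets[0]
        seq_len = len(first.sequences[0][1])
        bgset = make_dataset(
            "markov", background_db_size, seq_len, first.planted_pwm,
            occurrence_rate=0.0, seed=config.seed + 7919,
        )
        genome_db = PromoterDb(
            [PromoterRecord(f"bg_{sid}", s) for sid, s in bgset.sequences],
            source="generated background",
        )
    all_rows = []
    part_counts: dict[str, float] = {}
    part_totals = 0.0
    agg_engine_sites: list[dict[str, list]] = []
    agg_truth, agg_lengths = [], {}
    for di, ds in enumerate(datasets):
        rows, engine_sites = evaluate_dataset(ds, genome_db, config)
        for r in rows:
            r["dataset"] = f"ds_{di + 1}"
        all_rows.extend(rows)
        # namespace sequence ids so datasets can be pooled for the partition
        prefix = f"ds{di + 1}:"
        agg_truth.extend((prefix + t[0], t[1], t[2]) for t in ds.truth)
        agg_lengths.update({prefix + sid: L for sid, L in ds.seq_lengths().items()})
        agg_engine_sites.append({
            e: [(prefix + s.seq_id, s.start, s.end) for s in sites]
            for e, sites in engine_sites.items()
        })
    pooled = {e: [iv for d in agg_engine_sites for iv in d[e]]
              for e in sorted(ENGINES)}
    partition = partition_true_positives(pooled, agg_truth, agg_lengths)
    table = pd.DataFrame(all_rows)
    return BenchmarkResults(table=table, partition=partition)
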