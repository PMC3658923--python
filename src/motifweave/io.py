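"""Sequence and annotation I/O, promoter-database construction, background sampling.

Promoters are the at-most-1-kb regions immediately upstream of annotated gene
starts (a TSS proxy), taken 5'->3' relative to the gene: minus-strand promoters
are reverse-complemented genomic sequence.  Internal coordinates are 0-based
half-open throughout; GFF3 is read as 1-based inclusive, BED as 0-based
half-open.  Soft-masked (lowercase) and N bases are preserved in sequences.
"""

from __future__ import annotations

import random
import tempfile
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "PromoterRecord",
    "PromoterDb",
    "AnnotationTable",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "extract_promoters",
    "read_bed_intervals",
    "promoters_from_bed",
    "sample_background",
    "read_annotation_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (soft masking) and N."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True)
class PromoterRecord:
    """One upstream promoter sequence with its genomic provenance.

    ``seq`` is the 5'->3' upstream sequence relative to the gene's TSS; for a
    minus-strand gene it is the reverse complement of the forward genomic
    interval [start, end).
    """

    gene_id: str
    seq: str
    chrom: str = "."
    start: int = 0
    end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end - self.start not in (0, len(self.seq)):
            raise ValueError(
                f"{self.gene_id}: interval [{self.start},{self.end}) does not "
                f"match sequence length {len(self.seq)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class PromoterDb:
    """A collection of promoters with unique gene ids."""

    records: list[PromoterRecord]
    source: str = ""
    masked: bool = False

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in promoter db: {dup[:5]}")
        self._index = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._index[gene_id]

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids: list[str]) -> "PromoterDb":
        missing = [g for g in gene_ids if g not in self._index]
        if missing:
            raise KeyError(f"gene ids not in promoter db: {missing[:10]}")
        return PromoterDb([self._index[g] for g in gene_ids], source=self.source,
                          masked=self.masked)

    # serialized as FASTA with headers "gene_id|chrom|start|end|strand"
    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.gene_id}|{r.chrom}|{r.start}|{r.end}|{r.strand}\n")
                for i in range(0, len(r.seq), 70):
                    fh.write(r.seq[i : i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, source: str = "") -> "PromoterDb":
        records = []
        for rid, seq in read_fasta(path):
            parts = rid.split("|")
            if len(parts) == 5:
                gene, chrom, start, end, strand = parts
                records.append(PromoterRecord(gene, seq, chrom, int(start),
                                              int(end), strand))
            else:
                records.append(PromoterRecord(rid, seq))
        return cls(records, source=source or str(path))


@dataclass
class AnnotationTable:
    """gene_id -> set of GO term ids, with optional term labels."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not g for g in self.gene_terms):
            raise ValueError("annotated gene_id must be a non-empty string")

    def terms_for(self, gene_id: str) -> set[str]:
        return self.gene_terms.get(gene_id, set())

    def annotated_genes(self) -> set[str]:
        return set(self.gene_terms)

    def genes_with_term(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, seq) pairs.

    Ids are the first whitespace-delimited token of the header; case is
    preserved so soft masking survives a round trip.  A sequence line before
    the first header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    text = path.read_text()
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(";"):
            continue
        if s.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
    if not seen_header:
        raise FastaParseError(f"{path}: no FASTA records found")
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(StringIO(text), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_promoters(
    genome_fasta: str | Path,
    gff3: str | Path,
    max_len: int = 1000,
    source: str = "",
    feature_type: str = "gene",
) -> PromoterDb:
    """Build a promoter database from a genome FASTA and GFF3 annotation.

    For a + strand gene with 1-based start s the promoter is the forward-strand
    interval [max(0, s-1-max_len), s-1); for a - strand gene with 1-based end e
    it is the reverse complement of [e, min(chrom_len, e+max_len)).  Promoters
    are truncated at chromosome edges; genes whose promoter window is empty are
    omitted.
    """
    import gffutils

    genome = {rid: seq for rid, seq in read_fasta(genome_fasta)}
    gff3 = Path(gff3)
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gff3), tmp.name, force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        records = []
        for gene in db.features_of_type(feature_type, order_by=("seqid", "start")):
            gid = gene.id
            if gene.seqid not in genome:
                raise ValueError(
                    f"gene {gid} references unknown chromosome {gene.seqid!r}"
                )
            if gene.strand not in ("+", "-"):
                raise ValueError(f"gene {gid} has no strand annotation")
            chrom_seq = genome[gene.seqid]
            if gene.strand == "+":
                p_end = gene.start - 1  # 0-based gene start
                p_start = max(0, p_end - max_len)
                seq = chrom_seq[p_start:p_end]
            else:
                p_start = gene.end  # 0-based position just past the gene
                p_end = min(len(chrom_seq), p_start + max_len)
                seq = reverse_complement(chrom_seq[p_start:p_end])
            if not seq:
                continue
            records.append(
                PromoterRecord(gid, seq, gene.seqid, p_start, p_end, gene.strand)
            )
    return PromoterDb(records, source=source or f"{genome_fasta}+{gff3}")


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read BED (>=3 columns) as (chrom, start, end, name, strand) tuples."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith(("#", "track", "browser")):
            continue
        f = s.split("\t") if "\t" in s else s.split()
        if len(f) < 3:
            raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
        name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
        strand = f[5] if len(f) > 5 else "+"
        out.append((f[0], int(f[1]), int(f[2]), name, strand))
    return out


def promoters_from_bed(bed_path: str | Path, genome_fasta: str | Path) -> PromoterDb:
    """Resolve BED intervals against a genome into a promoter-like db.

    Intervals are taken as the regions to search (e.g. ChIP peaks); minus
    strand intervals are reverse-complemented.
    """
    genome = {rid: seq for rid, seq in read_fasta(genome_fasta)}
    records = []
    for chrom, start, end, name, strand in read_bed_intervals(bed_path):
        if chrom not in genome:
            raise ValueError(f"interval {name} references unknown chromosome {chrom!r}")
        seq = genome[chrom][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        records.append(PromoterRecord(name, seq, chrom, start, end, strand))
    return PromoterDb(records, source=str(bed_path))


def sample_background(db: PromoterDb, n: int, seed: int) -> list[PromoterRecord]:
    """Uniform sample of n promoters without replacement, reproducible by seed."""
    if n > len(db):
        raise ValueError(f"cannot sample {n} from db of size {len(db)}")
    rng = random.Random(seed)
    return rng.sample(db.records, n)


def read_annotation_table(
    path: str | Path, term_names_path: str | Path | None = None
) -> AnnotationTable:
    """Read a 2-column TSV (gene_id, GO id); optional 2-column term-name TSV."""
    gene_terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
        gene, term = parts[0].strip(), parts[1].strip()
        if not gene:
            raise ValueError(f"{path}: line {lineno}: empty gene id")
        gene_terms.setdefault(gene, set()).add(term)
    term_names: dict[str, str] = {}
    if term_names_path is not None:
        for line in Path(term_names_path).read_text().splitlines():
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            tid, _, label = s.partition("\t")
            term_names[tid.strip()] = label.strip()
    return AnnotationTable(gene_terms, term_names)
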