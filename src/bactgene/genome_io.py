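"""Genome and annotation I/O.

Reads FASTA genomes and GFF3 CDS annotations, and writes predicted gene
models back out as GFF3 or CSV. All coordinates are held internally as
0-based half-open intervals on the forward strand, with the strand recorded
separately; the 1-based inclusive GFF convention exists only at the I/O
boundary in :func:`gff_to_internal` / :func:`internal_to_gff`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import AnnotationSet

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

#: Fixed CSV header for annotation output.
CSV_HEADER = ("seqid", "strand", "start", "end", "p_cds", "p_tis",
              "prediction_max_likelihood")


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence; the unit all coordinates refer to."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsAnnotation:
    """A CDS interval, 0-based half-open on the forward strand."""

    seqid: str
    start: int
    end: int
    strand: str
    source_line: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid CDS interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """Forward-strand coordinate of the 3' boundary (stop-codon side)."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        """Forward-strand coordinate of the 5' boundary (start-codon side)."""
        return self.start if self.strand == "+" else self.end


def _normalize(seq: str) -> tuple[str, int]:
    seq = seq.upper()
    bad = sum(1 for c in seq if c not in VALID_ALPHABET)
    if bad:
        seq = "".join(c if c in VALID_ALPHABET else "N" for c in seq)
    return seq, bad


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and any character outside {A,C,G,T,N} is
    replaced by ``N`` (the replacement count is logged). File order is
    preserved.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    n_replaced = 0
    with open(path) as handle:
        first = handle.readline()
        if not first:
            raise ValueError(f"empty FASTA file: {path}")
        if not first.startswith(">"):
            raise ValueError(
                f"malformed FASTA header at line 1 of {path}: {first.strip()!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, bad = _normalize(str(rec.seq))
        n_replaced += bad
        records.append(GenomeRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if n_replaced:
        logger.info("read_fasta(%s): replaced %d non-ACGTN characters with N",
                    path, n_replaced)
    return records


def gff_to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def internal_to_gff(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> GFF 1-based inclusive."""
    return start + 1, end


def read_gff_cds(path: str | Path) -> list[CdsAnnotation]:
    """Read CDS features from a GFF3 file.

    Only rows with feature type ``CDS`` are consumed; coordinates are
    converted to the internal 0-based half-open convention. CDS intervals
    whose length is not a multiple of 3 are kept but logged (partial or
    frame-shifted CDS rows occur in real annotations).
    """
    path = Path(path)
    out: list[CdsAnnotation] = []
    n_frame_violations = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"malformed GFF line {lineno} in {path}: {line!r}")
            seqid, _source, ftype, start_s, end_s, _score, strand = fields[:7]
            if ftype != "CDS":
                continue
            start_1, end_1 = int(start_s), int(end_s)
            if start_1 > end_1:
                raise ValueError(
                    f"GFF line {lineno}: start {start_1} > end {end_1}")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"GFF line {lineno}: unknown strand symbol {strand!r}")
            start, end = gff_to_internal(start_1, end_1)
            if (end - start) % 3 != 0:
                n_frame_violations += 1
            out.append(CdsAnnotation(seqid=seqid, start=start, end=end,
                                     strand=strand, source_line=line))
    if n_frame_violations:
        logger.info("read_gff_cds(%s): %d CDS rows with length not a "
                    "multiple of 3", path, n_frame_violations)
    return out


def write_annotation(annotations: "AnnotationSet", fmt: str,
                     path: str | Path) -> None:
    """Write an :class:`~bactgene.annotate.AnnotationSet` as GFF3 or CSV.

    GFF output is valid GFF3 (1-based inclusive, feature type CDS) with the
    CDS/TIS probabilities and the ``prediction_max_likelihood`` flag in the
    attributes column, so that ``read_gff_cds`` round-trips the coordinates
    exactly. The CSV dialect has the fixed header ``CSV_HEADER``.
    """
    path = Path(path)
    if fmt == "gff":
        lines = ["##gff-version 3"]
        for p in annotations.predictions:
            g_start, g_end = internal_to_gff(p.start, p.end)
            attrs = (f"ID={p.genome_id}_{p.strand}{p.end};"
                     f"p_cds={p.p_cds:.6f};p_tis={p.p_tis:.6f};"
                     f"prediction_max_likelihood={p.prediction_max_likelihood}")
            lines.append("\t".join([
                p.genome_id, "bactgene", "CDS", str(g_start), str(g_end),
                f"{p.p_cds:.6f}", p.strand, "0", attrs]))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for p in annotations.predictions:
                writer.writerow([p.genome_id, p.strand, p.start, p.end,
                                 f"{p.p_cds:.6f}", f"{p.p_tis:.6f}",
                                 p.prediction_max_likelihood])
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")


def write_fasta(records: Iterable[GenomeRecord], path: str | Path,
                width: int = 70) -> None:
    """Write genome records as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_gff_cds(annotations: Iterable[CdsAnnotation],
                  path: str | Path) -> None:
    """Write reference-style CDS annotations as GFF3."""
    lines = ["##gff-version 3"]
    for a in annotations:
        g_start, g_end = internal_to_gff(a.start, a.end)
        lines.append("\t".join([
            a.seqid, "bactgene_sim", "CDS", str(g_start), str(g_end),
            ".", a.strand, "0", f"ID=cds_{a.seqid}_{g_start}_{g_end}"]))
    Path(path).write_text("\n".join(lines) + "\n")
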