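"""ORF extraction and dataset construction.

Scans both strands of a genome for open reading frames (start codon to the
next in-frame stop codon, nested starts retained), groups candidates that
share a stop codon into ORF groups, labels coding examples against a
reference annotation, builds fixed-length windows around candidate
translation initiation sites (TIS), balances classes, and splits datasets
by organism so that evaluation measures cross-organism generalization.

Coordinates follow the package-wide convention: 0-based half-open on the
forward strand, strand recorded separately. Each candidate's ``seq`` is in
reading orientation (reverse-complemented for the minus strand).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genome_io import CdsAnnotation, GenomeRecord

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "TTG", "GTG", "CTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCandidate:
    """A start-codon -> stop-codon interval on one strand.

    ``start``/``end`` are forward-strand 0-based half-open; ``seq`` is the
    nucleotide sequence in reading orientation, beginning with the start
    codon and ending with the stop codon. ``frame`` is the reading frame
    index (0-2) on the oriented strand.
    """

    genome_id: str
    strand: str
    start: int
    end: int
    seq: str
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def stop_coord(self) -> int:
        """Forward-strand coordinate identifying the 3' (stop) boundary."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        """Forward-strand coordinate of the 5' (start-codon) boundary."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_key(self) -> tuple[str, str, int]:
        return (self.genome_id, self.strand, self.stop_coord)


@dataclass(frozen=True)
class OrfGroup:
    """Nested ORFs sharing one stop codon on one strand, longest first."""

    stop_key: tuple[str, str, int]
    members: tuple[OrfCandidate, ...]

    @property
    def longest(self) -> OrfCandidate:
        return self.members[0]

    @property
    def strand(self) -> str:
        return self.stop_key[1]

    @property
    def stop_coord(self) -> int:
        return self.stop_key[2]


@dataclass(frozen=True)
class CdsExample:
    """A coding/non-coding training example (one per ORF group)."""

    seq: str
    label: int
    orf_ref: OrfCandidate
    organism_id: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TisWindow:
    """A 60-nt window centered on a candidate start codon.

    ``candidate_start`` is the forward-strand 5'-boundary coordinate of the
    candidate (``start`` for +, ``end`` for -), so equality with a reference
    CDS 5' boundary identifies the true TIS.
    """

    seq: str
    label: int
    candidate_start: int
    group_key: tuple[str, str, int]
    organism_id: str


def extract_orfs(genome: GenomeRecord, min_len: int = 90,
                 start_codons: Sequence[str] = START_CODONS,
                 stop_codons: Sequence[str] = STOP_CODONS) -> list[OrfCandidate]:
    """Find all ORFs of length >= ``min_len`` on both strands.

    An ORF runs from a start codon to the next in-frame stop codon with no
    in-frame stop in between. Every qualifying start upstream of a stop
    yields its own candidate, so nested overlapping ORFs are retained.
    Codons containing N match neither start nor stop codons.
    """
    if min_len < 6 or min_len % 3 != 0:
        raise ValueError("min_len must be >= 6 and a multiple of 3")
    starts = frozenset(start_codons)
    stops = frozenset(stop_codons)
    L = genome.length
    out: list[OrfCandidate] = []
    for strand in "+-":
        oriented = genome.seq if strand == "+" else reverse_complement(genome.seq)
        for frame in range(3):
            pending: list[int] = []  # oriented start positions since last stop
            for pos in range(frame, L - 2, 3):
                codon = oriented[pos:pos + 3]
                if codon in stops:
                    stop_end = pos + 3
                    for s in pending:
                        if stop_end - s >= min_len:
                            if strand == "+":
                                fstart, fend = s, stop_end
                            else:
                                fstart, fend = L - stop_end, L - s
                            out.append(OrfCandidate(
                                genome_id=genome.id, strand=strand,
                                start=fstart, end=fend,
                                seq=oriented[s:stop_end], frame=frame))
                    pending = []
                elif codon in starts:
                    pending.append(pos)
    return out


def group_orfs(orfs: Sequence[OrfCandidate]) -> list[OrfGroup]:
    """Partition ORFs by (genome, strand, stop coordinate), longest first."""
    by_key: dict[tuple[str, str, int], list[OrfCandidate]] = defaultdict(list)
    for orf in orfs:
        by_key[orf.stop_key].append(orf)
    groups = []
    for key in sorted(by_key):
        members = tuple(sorted(by_key[key], key=lambda o: -o.length))
        groups.append(OrfGroup(stop_key=key, members=members))
    return groups


def _ref_3p_keys(cds: Sequence[CdsAnnotation]) -> set[tuple[str, str, int]]:
    return {(a.seqid, a.strand, a.three_prime) for a in cds}


def label_cds(groups: Sequence[OrfGroup], cds: Sequence[CdsAnnotation],
              max_len: int = 510,
              organism_id: Optional[str] = None) -> list[CdsExample]:
    """Create one coding/non-coding example per ORF group.

    The example sequence is the group's longest member, truncated to the
    first ``max_len`` nt in reading orientation (start-proximal sequence).
    Label 1 iff the group's stop codon (strand + 3' coordinate) coincides
    with an annotated CDS 3' end.
    """
    matched = _ref_3p_keys(cds)
    out = []
    for g in groups:
        orf = g.longest
        label = 1 if g.stop_key in matched else 0
        out.append(CdsExample(seq=orf.seq[:max_len], label=label,
                              orf_ref=orf,
                              organism_id=organism_id or orf.genome_id))
    return out


def build_tis_windows(groups: Sequence[OrfGroup], cds: Sequence[CdsAnnotation],
                      genome: GenomeRecord, flank: int = 30,
                      organism_id: Optional[str] = None,
                      labeled: bool = True) -> list[TisWindow]:
    """Build fixed windows around candidate start codons.

    Only groups whose stop matches a reference CDS 3' end contribute (when
    ``labeled``); for an unannotated genome pass ``labeled=False`` to emit
    windows (label -1) for every group, as the annotation pipeline needs.
    Each member's window spans ``flank`` nt upstream through ``flank`` nt
    downstream of the candidate start in reading orientation, so the start
    codon occupies window offsets ``flank .. flank+2``. Windows crossing a
    contig boundary are skipped (count logged).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ref_by_key = {(a.seqid, a.strand, a.three_prime): a for a in cds}
    L = genome.length
    rc = None
    out = []
    n_skipped = 0
    for g in groups:
        ref = ref_by_key.get(g.stop_key)
        if labeled and ref is None:
            continue
        for orf in g.members:
            # oriented coordinate of the first base of the start codon
            s = orf.start if orf.strand == "+" else L - orf.end
            if s - flank < 0 or s + flank > L:
                n_skipped += 1
                continue
            if orf.strand == "+":
                window = genome.seq[s - flank:s + flank]
            else:
                if rc is None:
                    rc = reverse_complement(genome.seq)
                window = rc[s - flank:s + flank]
            if labeled:
                label = 1 if orf.five_prime == ref.five_prime else 0
            else:
                label = -1
            out.append(TisWindow(seq=window, label=label,
                                 candidate_start=orf.five_prime,
                                 group_key=g.stop_key,
                                 organism_id=organism_id or orf.genome_id))
    if n_skipped:
        logger.info("build_tis_windows: skipped %d windows crossing the "
                    "contig boundary", n_skipped)
    return out


def length_balance(pos: Sequence[CdsExample], neg: Sequence[CdsExample],
                   bin_width: int = 50, seed: int = 0) -> list[CdsExample]:
    """Downsample negatives per length bin to at most the positive count.

    Negatives are sampled without replacement within each ``bin_width``-bp
    length bin so the negative length distribution matches the positive one;
    bins with positives but no negatives are logged and left under-filled.
    Returns positives plus the retained negatives, deterministically under
    ``seed``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(seed)
    pos_bins: dict[int, int] = defaultdict(int)
    for p in pos:
        pos_bins[p.length // bin_width] += 1
    neg_bins: dict[int, list[int]] = defaultdict(list)
    for i, n in enumerate(neg):
        neg_bins[n.length // bin_width].append(i)
    kept: list[CdsExample] = list(pos)
    for b in sorted(pos_bins):
        want = pos_bins[b]
        have = neg_bins.get(b, [])
        if not have:
            logger.warning("length_balance: bin %d has %d positives but no "
                           "negatives", b, want)
            continue
        take = min(want, len(have))
        chosen = rng.choice(len(have), size=take, replace=False)
        kept.extend(neg[have[j]] for j in sorted(chosen))
    return kept


def undersample(examples: Sequence, seed: int = 0) -> list:
    """Randomly downsample the majority class to the minority count."""
    pos = [e for e in examples if e.label == 1]
    neg = [e for e in examples if e.label == 0]
    if not pos or not neg:
        raise ValueError("undersample requires both classes present")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        big, small = pos, neg
    else:
        big, small = neg, pos
    idx = rng.choice(len(big), size=len(small), replace=False)
    return list(small) + [big[i] for i in sorted(idx)]


def write_example_shards(examples: Sequence, out_dir, shard_size: int = 10000,
                         prefix: str = "shard") -> list:
    """Write examples to CSV shards (seq, label, organism_id).

    Returns the shard paths; shards stream back with
    :func:`iter_example_shards` without loading the full set at once.
    """
    import pandas as pd
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(0, max(len(examples), 1), shard_size):
        chunk = examples[i:i + shard_size]
        path = out_dir / f"{prefix}-{i // shard_size:04d}.csv"
        pd.DataFrame({
            "seq": [e.seq for e in chunk],
            "label": [e.label for e in chunk],
            "organism_id": [e.organism_id for e in chunk],
        }).to_csv(path, index=False)
        paths.append(path)
    return paths


def iter_example_shards(shard_dir, prefix: str = "shard"):
    """Yield lightweight (seq, label, organism_id) records shard by shard."""
    import pandas as pd
    from pathlib import Path
    from types import SimpleNamespace
    for path in sorted(Path(shard_dir).glob(f"{prefix}-*.csv")):
        for row in pd.read_csv(path).itertuples(index=False):
            yield SimpleNamespace(seq=row.seq, label=int(row.label),
                                  organism_id=str(row.organism_id))


def split_by_organism(examples: Sequence, fractions: tuple[float, float, float],
                      seed: int = 0) -> tuple[list, list, list]:
    """Partition examples into train/test/eval with disjoint organism sets.

    Whole organisms are assigned to partitions, so the held-out sets contain
    only organisms absent from training.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    organisms = sorted({e.organism_id for e in examples})
    n_parts = sum(1 for f in fractions if f > 0)
    if len(organisms) < n_parts:
        raise ValueError(
            f"{len(organisms)} organisms cannot fill {n_parts} partitions")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(organisms))
    n = len(order)
    counts = [int(np.floor(f * n)) for f in fractions]
    # hand remainders to the largest fractional parts, then guarantee every
    # non-empty partition at least one organism
    rema = sorted(range(3), key=lambda i: -(fractions[i] * n - counts[i]))
    for i in rema[: n - sum(counts)]:
        counts[i] += 1
    for i in range(3):
        if fractions[i] > 0 and counts[i] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1
    sets = []
    at = 0
    for c in counts:
        sets.append(set(order[at:at + c]))
        at += c
    return tuple([e for e in examples if e.organism_id in s] for s in sets)
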