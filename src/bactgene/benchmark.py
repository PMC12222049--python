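"""Matched-end benchmarking and length-stratified analysis.

A predicted gene is "3'-matched" when some reference CDS shares its strand
and stop coordinate (gene identity); it is "5'+3'-matched" when the start
coordinate also agrees (correct TIS). Percentages are relative to the
number of reference genes. Length-stratified reports compute per-bin
precision/recall/accuracy over ORF-level classification labels, with the
default bins <300, [300, 1000), [1000, 2000) and >=2000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotate import AnnotationSet
from .genome_io import CdsAnnotation
from .training import MetricReport, metrics_from_confusion


@dataclass(frozen=True)
class BenchmarkResult:
    n_reference: int
    matched_5p3p: int
    matched_3p: int
    total_predicted: int

    @property
    def pct_5p3p(self) -> float:
        return 100.0 * self.matched_5p3p / self.n_reference

    @property
    def pct_3p(self) -> float:
        return 100.0 * self.matched_3p / self.n_reference


@dataclass(frozen=True)
class LengthBinReport:
    """Per-length-bin metrics: (label, n_orfs, MetricReport-or-None)."""

    bins: tuple[tuple[str, int, Optional[MetricReport]], ...]

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.bins)


def aggregate(results: Sequence[BenchmarkResult]) -> BenchmarkResult:
    """All-genomes row: sum counts first, then recompute percentages."""
    return BenchmarkResult(
        n_reference=sum(r.n_reference for r in results),
        matched_5p3p=sum(r.matched_5p3p for r in results),
        matched_3p=sum(r.matched_3p for r in results),
        total_predicted=sum(r.total_predicted for r in results))


def match_annotations(predicted: AnnotationSet,
                      reference: Sequence[CdsAnnotation]) -> BenchmarkResult:
    """Count reference genes matched at the 3' end and at both ends."""
    pred_3p = {}
    for p in predicted.predictions:
        key = (p.strand, p.end if p.strand == "+" else p.start)
        if key in pred_3p:
            raise ValueError(f"duplicate (strand, stop) {key} in predictions")
        pred_3p[key] = p
    matched_3p = matched_both = 0
    for ref in reference:
        p = pred_3p.get((ref.strand, ref.three_prime))
        if p is None:
            continue
        matched_3p += 1
        if p.start == ref.start and p.end == ref.end:
            matched_both += 1
    return BenchmarkResult(n_reference=len(reference),
                           matched_5p3p=matched_both, matched_3p=matched_3p,
                           total_predicted=len(predicted.predictions))


def length_stratified(lengths: Sequence[int], predicted: Sequence[int],
                      truth: Sequence[int],
                      bin_edges: Sequence[int] = (300, 1000, 2000)
                      ) -> LengthBinReport:
    """Per-bin confusion metrics over ORF-level labels.

    Bins are half-open ``[lo, hi)``: a 300-bp ORF falls in the second
    default bin. Empty bins report metrics as absent (None), not zero.
    """
    lengths = np.asarray(lengths)
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    edges = [0, *bin_edges, np.inf]
    labels = [f"<{bin_edges[0]}"] + [
        f"[{lo},{hi})" for lo, hi in zip(bin_edges[:-1], bin_edges[1:])
    ] + [f">={bin_edges[-1]}"]
    rows = []
    for label, lo, hi in zip(labels, edges[:-1], edges[1:]):
        sel = (lengths >= lo) & (lengths < hi)
        n = int(sel.sum())
        if n == 0:
            rows.append((label, 0, None))
            continue
        p, y = predicted[sel], truth[sel]
        tp = int(np.sum((p == 1) & (y == 1)))
        tn = int(np.sum((p == 0) & (y == 0)))
        fp = int(np.sum((p == 1) & (y == 0)))
        fn = int(np.sum((p == 0) & (y == 1)))
        rows.append((label, n, metrics_from_confusion(tp, tn, fp, fn)))
    return LengthBinReport(bins=tuple(rows))
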