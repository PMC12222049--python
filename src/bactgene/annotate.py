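"""Two-stage genome annotation.

Stage 1 scores every ORF group's longest member with the CDS classifier;
groups at or above the probability threshold are called coding. Stage 2
scores a 60-nt window around each candidate start codon in each coding
group with the TIS classifier and keeps the site with the highest predicted
probability, recorded with ``prediction_max_likelihood = 1``. Groups whose
candidate windows all cross a contig boundary fall back to the longest
member's start with the flag set to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome_io import GenomeRecord
from .orf_dataset import (OrfGroup, build_tis_windows, extract_orfs,
                          group_orfs)
from .tokenizer import (CDS_MAX_LEN, CDS_MAX_SEQ, TIS_MAX_LEN, Vocabulary,
                        encode_sequence)
from .training import examples_to_dataset
from .transformer import TransformerClassifier

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePrediction:
    """A predicted gene: selected TIS through stop codon."""

    genome_id: str
    strand: str
    start: int
    end: int
    p_cds: float
    p_tis: float
    prediction_max_likelihood: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("start must precede end")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("gene length must be a multiple of 3")


@dataclass
class AnnotationSet:
    """Predicted gene models for one genome plus provenance."""

    genome_id: str
    predictions: list[GenePrediction] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(p.strand, p.end if p.strand == "+" else p.start)
                for p in self.predictions]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (strand, stop) among predictions")


@dataclass
class AnnotateConfig:
    min_orf_len: int = 90
    cds_threshold: float = 0.5
    flank: int = 30
    max_cds_seq: int = CDS_MAX_SEQ
    #: rough per-example memory budget mapping for batched inference
    memory_budget_mb: int = 512

    def batch_size(self, seq_len: int, d_hidden: int) -> int:
        """Linear memory-budget -> batch-size mapping (clamped to [4, 256])."""
        per_example = seq_len * (seq_len + 8 * d_hidden) * 4  # bytes, approx
        return int(np.clip(self.memory_budget_mb * 2 ** 20 // max(
            per_example, 1), 4, 256))


class _SeqExample:
    __slots__ = ("seq", "label")

    def __init__(self, seq: str):
        self.seq = seq
        self.label = 0


def predict_cds(genome: GenomeRecord, model: TransformerClassifier,
                vocab: Vocabulary, threshold: float = 0.5,
                config: Optional[AnnotateConfig] = None
                ) -> list[tuple[OrfGroup, float]]:
    """Score every ORF group's longest member; return (group, p_cds) pairs.

    Scoring is per-group and therefore independent of group order.
    """
    config = config or AnnotateConfig(cds_threshold=threshold)
    orfs = extract_orfs(genome, min_len=config.min_orf_len)
    groups = group_orfs(orfs)
    if not groups:
        return []
    examples = [_SeqExample(g.longest.seq[:config.max_cds_seq])
                for g in groups]
    data = examples_to_dataset(examples, vocab, stride=3,
                               max_len=model.config.max_positions)
    bs = config.batch_size(model.config.max_positions,
                           model.config.d_hidden)
    p = model.classify_batch(data.ids, data.mask, batch_size=bs)
    return list(zip(groups, (float(x) for x in p)))


def predict_tis(group: OrfGroup, genome: GenomeRecord,
                model: TransformerClassifier, vocab: Vocabulary,
                config: Optional[AnnotateConfig] = None
                ) -> list[tuple[int, float]]:
    """Score each candidate start of a coding group.

    Returns (candidate_start, p_tis) pairs ordered upstream-to-downstream
    (longest ORF first); candidates whose windows cross the contig boundary
    are omitted.
    """
    config = config or AnnotateConfig()
    windows = build_tis_windows([group], [], genome, flank=config.flank,
                                labeled=False)
    if not windows:
        return []
    data = examples_to_dataset(
        [_SeqExample(w.seq) for w in windows], vocab, stride=1,
        max_len=model.config.max_positions)
    p = model.classify_batch(data.ids, data.mask)
    return [(w.candidate_start, float(pi)) for w, pi in zip(windows, p)]


def select_tis(scored: Sequence[tuple[int, float]]) -> int:
    """Argmax of p_tis; ties go to the first (5'-most, longest-ORF) entry."""
    if not scored:
        raise ValueError("select_tis on an empty candidate list")
    best = 0
    for i in range(1, len(scored)):
        if scored[i][1] > scored[best][1]:
            best = i
    return scored[best][0]


def _prediction_from(group: OrfGroup, candidate_start: int, p_cds: float,
                     p_tis: float, flag: int) -> GenePrediction:
    gid, strand, stop = group.stop_key
    if strand == "+":
        start, end = candidate_start, stop
    else:
        start, end = stop, candidate_start
    return GenePrediction(genome_id=gid, strand=strand, start=start, end=end,
                          p_cds=p_cds, p_tis=p_tis,
                          prediction_max_likelihood=flag)


def annotate_genome(genome: GenomeRecord, cds_model: TransformerClassifier,
                    tis_model: TransformerClassifier, vocab: Vocabulary,
                    config: Optional[AnnotateConfig] = None) -> AnnotationSet:
    """Full pipeline: extract -> group -> CDS stage -> TIS stage -> select."""
    config = config or AnnotateConfig()
    if cds_model.config.max_positions != CDS_MAX_LEN:
        raise ValueError(
            f"CDS model max_positions {cds_model.config.max_positions} != "
            f"{CDS_MAX_LEN}")
    if tis_model.config.max_positions != TIS_MAX_LEN:
        raise ValueError(
            f"TIS model max_positions {tis_model.config.max_positions} != "
            f"{TIS_MAX_LEN}")
    predictions = []
    for group, p_cds in predict_cds(genome, cds_model, vocab,
                                    config=config):
        if p_cds < config.cds_threshold:
            continue
        scored = predict_tis(group, genome, tis_model, vocab, config=config)
        if scored:
            chosen = select_tis(scored)
            p_tis = dict(scored)[chosen]
            predictions.append(_prediction_from(group, chosen, p_cds,
                                                p_tis, flag=1))
        else:
            logger.warning("group %s: all TIS windows crossed the contig "
                           "boundary; keeping longest member", group.stop_key)
            predictions.append(_prediction_from(
                group, group.longest.five_prime, p_cds, 0.0, flag=0))
    return AnnotationSet(
        genome_id=genome.id, predictions=predictions,
        provenance={"cds_threshold": config.cds_threshold,
                    "min_orf_len": config.min_orf_len,
                    "cds_model": cds_model.weight_hash(),
                    "tis_model": tis_model.weight_hash()})
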