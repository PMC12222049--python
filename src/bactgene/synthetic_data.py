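"""Synthetic bacterial genomes with planted, annotated genes.

Generates FASTA+GFF pairs in which every pipeline stage has ground truth:
genes with canonical start/stop codons and codon-usage-biased bodies are
placed on both strands, separated by i.i.d. intergenic background at a
configured GC content. Each organism draws its own codon-frequency profile
(a Dirichlet perturbation of a shared GC3-skewed bacterial-like profile), so
held-out-organism evaluation measures cross-organism generalization rather
than memorization. True starts carry a fixed purine-rich upstream hexamer
(a Shine-Dalgarno-like signal), and decoy in-frame start codons are planted
upstream of true starts — with no intervening in-frame stop — so each gene's
ORF group contains ambiguous TIS candidates.

What this emulates and what it does not: codon bias, start/stop codon usage,
TIS context and nested ORF structure are present; operons, overlapping
genes, GC skew, repeats and mobile elements are not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_io import CdsAnnotation, GenomeRecord, write_fasta, write_gff_cds
from .orf_dataset import STOP_CODONS, reverse_complement

BASES = "ACGT"
NON_STOP_CODONS = tuple(c for c in ("".join(p) for p in product(BASES, repeat=3))
                        if c not in STOP_CODONS)

#: Shine-Dalgarno-like hexamer planted upstream of every true start.
SD_MOTIF = "AGGAGG"

_START_CHOICES = ("ATG", "GTG", "TTG")
_START_WEIGHTS = (0.80, 0.12, 0.08)
_STOP_CHOICES = ("TAA", "TGA", "TAG")
_STOP_WEIGHTS = (0.60, 0.30, 0.10)


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    ``coding_codon_bias`` is the Dirichlet concentration multiplier around
    the shared codon profile: large values give organisms nearly identical
    strongly-biased codon usage, small values give noisy per-organism
    profiles. ``n_decoy_starts`` is the number of in-frame alternative start
    codons planted upstream of each true start. ``motif_offset`` places the
    3' end of the SD-like hexamer relative to the start codon (default -8:
    the motif occupies positions -14..-9).
    """

    n_organisms: int = 30
    genes_per_genome: int = 20
    genome_len: int = 22000
    gc_content: float = 0.5
    coding_codon_bias: float = 50.0
    n_decoy_starts: int = 2
    motif_offset: int = -8
    min_gene_codons: int = 30
    max_gene_codons: int = 160
    upstream_context: int = 36
    min_spacer: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        if self.genome_len < self.genes_per_genome * 300:
            raise ValueError("genome_len must be >= genes_per_genome * 300")


def _base_codon_profile() -> np.ndarray:
    """Shared bacterial-like codon profile: GC3-preferring, strongly skewed."""
    w = np.array([4.0 if c[2] in "GC" else 1.0 for c in NON_STOP_CODONS])
    return w / w.sum()


def _organism_codon_profile(cfg: SimConfig,
                            rng: np.random.Generator) -> np.ndarray:
    base = _base_codon_profile()
    alpha = np.maximum(cfg.coding_codon_bias * len(base) * base, 1e-3)
    return rng.dirichlet(alpha)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def _gene_cassette(cfg: SimConfig, profile: np.ndarray,
                   rng: np.random.Generator) -> tuple[str, int]:
    """Build one oriented gene with its upstream context.

    Returns ``(cassette, gene_offset)`` where the gene (start codon through
    stop codon) begins at ``gene_offset`` within the cassette. The upstream
    context is stop-free in the gene's frame, carries the SD motif and the
    planted decoy starts.
    """
    up = list(_random_dna(cfg.upstream_context, cfg.gc_content, rng))
    s = cfg.upstream_context  # gene start within cassette

    # SD-like motif with its 3' end at motif_offset relative to the start
    m_end = s + cfg.motif_offset
    m_start = m_end - len(SD_MOTIF)
    if m_start < 0:
        raise ValueError("upstream_context too short for the motif")
    up[m_start - 0:m_end] = list(SD_MOTIF)

    # remove in-frame stop codons from the upstream context so planted decoy
    # starts share the gene's ORF group
    frame_slots = [s - 3 * d for d in range(1, cfg.upstream_context // 3 + 1)
                   if s - 3 * d >= 0]
    motif_range = range(m_start, m_end)

    def overlaps_motif(slot: int) -> bool:
        return any(pos in motif_range for pos in range(slot, slot + 3))

    neutral = [c for c in NON_STOP_CODONS
               if c not in ("ATG", "GTG", "TTG", "CTG")]
    for slot in frame_slots:
        codon = "".join(up[slot:slot + 3])
        if codon not in STOP_CODONS:
            continue
        if overlaps_motif(slot):
            # only touch the bases outside the motif (C breaks every stop)
            for pos in range(slot, slot + 3):
                if pos not in motif_range:
                    up[pos] = "C"
        else:
            up[slot:slot + 3] = list(str(rng.choice(neutral)))

    free_slots = [sl for sl in frame_slots if not overlaps_motif(sl)]
    n_decoys = min(cfg.n_decoy_starts, len(free_slots))
    if n_decoys:
        chosen = rng.choice(len(free_slots), size=n_decoys, replace=False)
        for j in chosen:
            up[free_slots[j]:free_slots[j] + 3] = list(
                _START_CHOICES[rng.choice(3, p=_START_WEIGHTS)])

    start = _START_CHOICES[rng.choice(3, p=_START_WEIGHTS)]
    stop = _STOP_CHOICES[rng.choice(3, p=_STOP_WEIGHTS)]
    n_body = int(rng.integers(cfg.min_gene_codons, cfg.max_gene_codons + 1))
    body_idx = rng.choice(len(NON_STOP_CODONS), size=n_body, p=profile)
    body = "".join(NON_STOP_CODONS[i] for i in body_idx)
    return "".join(up) + start + body + stop, s


def simulate_genome(cfg: SimConfig, organism_id: str,
                    rng: Optional[np.random.Generator] = None,
                    profile: Optional[np.ndarray] = None
                    ) -> tuple[GenomeRecord, list[CdsAnnotation]]:
    """One genome with ``genes_per_genome`` non-overlapping planted genes.

    Genes alternate randomly between strands; annotations are returned in
    the internal 0-based half-open convention. Deterministic given the rng
    state (or ``cfg.seed`` + organism id hash when none is passed).
    """
    if rng is None:
        rng = np.random.default_rng(
            [cfg.seed, abs(hash(organism_id)) % (2 ** 31)])
    if profile is None:
        profile = _organism_codon_profile(cfg, rng)

    cassettes = []
    for _ in range(cfg.genes_per_genome):
        cas, off = _gene_cassette(cfg, profile, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        cassettes.append((cas, off, strand))

    n = cfg.genes_per_genome
    fixed = sum(len(c) for c, _, _ in cassettes) + (n + 1) * cfg.min_spacer
    slack = cfg.genome_len - fixed
    if slack < 0:
        raise ValueError(
            f"genome_len={cfg.genome_len} too small for {n} genes "
            f"(need >= {fixed}); increase genome_len")
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))

    parts: list[str] = []
    annotations: list[CdsAnnotation] = []
    pos = 0
    for i, (cas, off, strand) in enumerate(cassettes):
        spacer = _random_dna(cfg.min_spacer + int(extra[i]), cfg.gc_content,
                             rng)
        parts.append(spacer)
        pos += len(spacer)
        gene_len = len(cas) - off
        if strand == "+":
            parts.append(cas)
            g_start, g_end = pos + off, pos + len(cas)
        else:
            parts.append(reverse_complement(cas))
            g_start, g_end = pos, pos + gene_len
        annotations.append(CdsAnnotation(seqid=organism_id, start=g_start,
                                         end=g_end, strand=strand))
        pos += len(cas)
    parts.append(_random_dna(cfg.min_spacer + int(extra[n]), cfg.gc_content,
                             rng))
    genome = GenomeRecord(id=organism_id, seq="".join(parts))
    return genome, annotations


def simulate_corpus(cfg: SimConfig, out_dir: Optional[str | Path] = None
                    ) -> list[tuple[str, GenomeRecord, list[CdsAnnotation]]]:
    """One genome per organism, each with its own codon-profile draw.

    When ``out_dir`` is given, writes ``<organism>.fna`` and
    ``<organism>.gff`` per organism.
    """
    if cfg.n_organisms < 3:
        raise ValueError("need n_organisms >= 3 for organism-held-out splits")
    master = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_organisms):
        organism_id = f"org{i:03d}"
        rng = np.random.default_rng(master.integers(2 ** 31, size=4))
        genome, anns = simulate_genome(cfg, organism_id, rng=rng)
        out.append((organism_id, genome, anns))
        if out_dir is not None:
            out_path = Path(out_dir)
            out_path.mkdir(parents=True, exist_ok=True)
            write_fasta([genome], out_path / f"{organism_id}.fna")
            write_gff_cds(anns, out_path / f"{organism_id}.gff")
    return out
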