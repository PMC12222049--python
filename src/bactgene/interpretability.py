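"""Attention-based interpretability for the TIS classifier.

Computes the mean attention landscape of a chosen layer (per-sequence mean
over heads, then mean over sequences) for true-TIS windows, ranks
nucleotide positions by the attention they receive from the [CLS] token,
and runs the attention-guided disruption experiment: substituting bases at
the most- or least-attended positions at increasing ratios and re-scoring
the window, to test whether attended regions drive the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tokenizer import TokenSequence, Vocabulary, encode_sequence
from .transformer import TransformerClassifier

_BASES = "ACGT"


@dataclass(frozen=True)
class MeanAttentionLandscape:
    """Head- then sequence-averaged attention matrix of one layer."""

    layer: int
    matrix: np.ndarray
    n_sequences: int


@dataclass(frozen=True)
class DisruptionCurve:
    """Predicted positive probabilities per disruption ratio."""

    mode: str
    ratios: tuple[float, ...]
    prob_distributions: tuple[np.ndarray, ...]
    seed: int

    def means(self) -> np.ndarray:
        return np.array([d.mean() for d in self.prob_distributions])


def mean_attention(model: TransformerClassifier,
                   windows: Sequence[TokenSequence],
                   layer: int = -1) -> MeanAttentionLandscape:
    """Average the per-head attention of ``layer`` over heads, then windows.

    All windows must have equal length; the result is row-stochastic (an
    average of row-stochastic matrices).
    """
    if not windows:
        raise ValueError("mean_attention requires at least one window")
    n = windows[0].n_real
    acc = None
    for w in windows:
        if w.n_real != n:
            raise ValueError("all windows must have the same real length")
        maps = model.get_attention_maps(w)
        per_seq = maps[layer].weights.mean(axis=0)  # mean over heads
        acc = per_seq if acc is None else acc + per_seq
    layer_idx = layer if layer >= 0 else model.config.n_layers + layer
    return MeanAttentionLandscape(layer=layer_idx,
                                  matrix=acc / len(windows),
                                  n_sequences=len(windows))


def spread_token_attention(row: np.ndarray, seq_len: int, k: int,
                           stride: int) -> np.ndarray:
    """Distribute k-mer token attention uniformly over covered bases.

    ``row`` is a [CLS]-query attention row over ``n_real`` positions
    ([CLS], tokens, [EOS]); special positions are dropped, and token j
    (0-based among the k-mers) adds score/k to bases j*stride .. j*stride+k-1.
    """
    scores = np.zeros(seq_len)
    token_scores = row[1:-1]  # strip [CLS] and [EOS] positions
    for j, s in enumerate(token_scores):
        lo = j * stride
        scores[lo:lo + k] += s / k
    return scores


def rank_positions(attention_row: np.ndarray, seq_len: int, k: int = 6,
                   stride: int = 1) -> np.ndarray:
    """Nucleotide positions ordered by attention received, descending.

    Ties break toward the lower position index (stable sort on the negated
    scores).
    """
    scores = spread_token_attention(attention_row, seq_len, k, stride)
    return np.argsort(-scores, kind="stable")


def _cls_importance(model: TransformerClassifier, tokens: TokenSequence,
                    seq_len: int, k: int, stride: int) -> np.ndarray:
    maps = model.get_attention_maps(tokens)
    cls_row = maps[-1].weights.mean(axis=0)[0]  # head-mean, [CLS] query row
    return rank_positions(cls_row, seq_len, k=k, stride=stride)


def disrupt_sequence(seq: str, order: np.ndarray, ratio: float, mode: str,
                     seed: int) -> str:
    """Substitute ``ceil(ratio*len(seq))`` ranked positions.

    ``order`` ranks positions most- to least-attended; mode "high" takes the
    top of the ranking, "low" the bottom. Every chosen position is replaced
    by a base drawn uniformly from the three alternatives, so at ratio 1.0
    no position keeps its original base.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must be within [0, 1]")
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    n = int(np.ceil(ratio * len(seq)))
    targets = order[:n] if mode == "high" else order[::-1][:n]
    rng = np.random.default_rng(seed)
    mutated = list(seq)
    for pos in sorted(int(t) for t in targets):
        alternatives = [b for b in _BASES if b != seq[pos]]
        mutated[pos] = alternatives[rng.integers(3)]
    return "".join(mutated)


def disrupt_and_score(seq: str, model: TransformerClassifier,
                      vocab: Vocabulary, ratio: float, mode: str,
                      seed: int) -> float:
    """Substitute bases at the most/least-attended positions and re-score.

    ``ceil(ratio * len(seq))`` positions — the top-ranked for mode "high",
    the bottom-ranked for mode "low", ranked by the model's own final-layer
    [CLS] attention on the undisrupted window — are each replaced by a base
    drawn uniformly from the three alternatives. Ratio 0 returns the
    original probability bit-exactly.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must be within [0, 1]")
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    tokens = encode_sequence(seq, vocab, stride=1,
                             max_len=model.config.max_positions)
    if ratio == 0.0:
        return model.classify(tokens)[1]
    order = _cls_importance(model, tokens, len(seq), k=vocab.k, stride=1)
    mutated = disrupt_sequence(seq, order, ratio, mode, seed)
    new_tokens = encode_sequence(mutated, vocab, stride=1,
                                 max_len=model.config.max_positions)
    return model.classify(new_tokens)[1]


def disruption_curve(windows: Sequence[str], model: TransformerClassifier,
                     vocab: Vocabulary, ratios: Sequence[float], mode: str,
                     seed: int) -> DisruptionCurve:
    """Disruption experiment over many windows and a ratio sweep."""
    dists = []
    for r in ratios:
        probs = np.array([
            disrupt_and_score(w, model, vocab, r, mode,
                              seed=seed + 7919 * i)
            for i, w in enumerate(windows)])
        dists.append(probs)
    return DisruptionCurve(mode=mode, ratios=tuple(float(r) for r in ratios),
                           prob_distributions=tuple(dists), seed=seed)
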