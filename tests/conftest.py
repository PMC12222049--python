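import numpy as np
import pytest

from bactgene import pipeline
from bactgene.annotate import annotate_genome
from bactgene.benchmark import match_annotations
from bactgene.genome_io import GenomeRecord
from bactgene.synthetic_data import SimConfig, simulate_corpus, simulate_genome
from bactgene.tokenizer import Vocabulary
from bactgene.transformer import ModelConfig, TransformerClassifier


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary.build(k=6)


def random_genome(n: int, seed: int, gid: str = "g") -> GenomeRecord:
    rng = np.random.default_rng(seed)
    return GenomeRecord(id=gid, seq="".join(
        np.array(list("ACGT"))[rng.integers(0, 4, size=n)]))


@pytest.fixture
def tiny_tis_model(vocab):
    cfg = ModelConfig(vocab_size=len(vocab), max_positions=57, n_layers=1,
                      d_hidden=16, n_heads=2)
    return TransformerClassifier(cfg, seed=0)


@pytest.fixture
def tiny_cds_model(vocab):
    cfg = ModelConfig(vocab_size=len(vocab), max_positions=512, n_layers=1,
                      d_hidden=16, n_heads=2)
    return TransformerClassifier(cfg, seed=0)


@pytest.fixture(scope="session")
def desk_run():
    """Train the desk-scale two-stage pipeline on the default synthetic
    corpus (30 organisms) and annotate a held-out genome.

    Shared session-wide because training takes minutes.
    """
    cfg = SimConfig(seed=0)
    corpus = simulate_corpus(cfg)
    result = pipeline.train_desk_pipeline(corpus, seed=0)
    heldout_genome, heldout_cds = simulate_genome(
        cfg, "heldout", rng=np.random.default_rng(987654321))
    annotation = annotate_genome(heldout_genome, result["cds_model"],
                                 result["tis_model"], result["vocab"])
    result.update(sim_config=cfg, corpus=corpus,
                  heldout_genome=heldout_genome, heldout_cds=heldout_cds,
                  annotation=annotation,
                  benchmark=match_annotations(annotation, heldout_cds))
    return result
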