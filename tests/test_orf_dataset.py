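from collections import Counter, defaultdict

import numpy as np
import pytest

from bactgene.genome_io import CdsAnnotation, GenomeRecord
from bactgene.orf_dataset import (START_CODONS, STOP_CODONS, CdsExample,
                                  build_tis_windows, extract_orfs,
                                  group_orfs, label_cds, length_balance,
                                  reverse_complement, split_by_organism,
                                  undersample)
from conftest import random_genome


def brute_force_orfs(genome, min_len):
    """Enumerate every (start codon, next in-frame stop) pair directly."""
    found = set()
    L = genome.length
    for strand in "+-":
        s = genome.seq if strand == "+" else reverse_complement(genome.seq)
        for i in range(L - 2):
            if s[i:i + 3] not in START_CODONS:
                continue
            j = i + 3
            while j + 3 <= L:
                if s[j:j + 3] in STOP_CODONS:
                    if j + 3 - i >= min_len:
                        if strand == "+":
                            found.add((strand, i, j + 3))
                        else:
                            found.add((strand, L - (j + 3), L - i))
                    break
                j += 3
    return found


def test_smallest_orf():
    orfs = extract_orfs(GenomeRecord(id="g", seq="ATGTAA"), min_len=6)
    plus = [o for o in orfs if o.strand == "+"]
    assert [(o.start, o.end, o.seq) for o in plus] == [(0, 6, "ATGTAA")]


def test_nested_orfs_retained():
    orfs = extract_orfs(GenomeRecord(id="g", seq="ATGATGTTTTAA"), min_len=6)
    plus = sorted((o.start, o.end) for o in orfs if o.strand == "+")
    assert plus == [(0, 12), (3, 12)]


def test_min_len_validation():
    g = GenomeRecord(id="g", seq="ATGTAA")
    with pytest.raises(ValueError):
        extract_orfs(g, min_len=5)
    with pytest.raises(ValueError):
        extract_orfs(g, min_len=7)


@pytest.mark.parametrize("seed", [7, 8, 9])
def test_extract_matches_brute_force(seed):
    g = random_genome(2000, seed)
    got = {(o.strand, o.start, o.end) for o in extract_orfs(g, min_len=30)}
    assert got == brute_force_orfs(g, 30)


def test_orf_sequences_have_no_internal_stop():
    g = random_genome(3000, 11)
    for o in extract_orfs(g, min_len=30):
        codons = [o.seq[i:i + 3] for i in range(0, len(o.seq) - 3, 3)]
        assert o.seq[:3] in START_CODONS
        assert o.seq[-3:] in STOP_CODONS
        assert not any(c in STOP_CODONS for c in codons[:-1])
        assert (o.end - o.start) % 3 == 0


def test_group_orfs_nested_and_singletons():
    orfs = extract_orfs(GenomeRecord(id="g", seq="ATGATGTTTTAA"), min_len=6)
    plus = [o for o in orfs if o.strand == "+"]
    groups = group_orfs(plus)
    assert len(groups) == 1 and len(groups[0].members) == 2
    assert groups[0].longest.length == 12  # longest first


def test_group_count_matches_key_partition():
    g = random_genome(5000, 21)
    orfs = extract_orfs(g, min_len=30)
    groups = group_orfs(orfs)
    keys = defaultdict(list)
    for o in orfs:
        keys[(o.strand, o.stop_coord)].append(o)
    assert len(groups) == len(keys)
    assert sum(len(gr.members) for gr in groups) == len(orfs)
    for gr in groups:
        lens = [m.length for m in gr.members]
        assert lens == sorted(lens, reverse=True)


def _genome_with_gene():
    # 30 nt padding + gene ATG (AAA)x12 TAA + padding; decoy ATG in frame
    gene = "ATG" + "GCT" * 4 + "ATG" + "GCA" * 7 + "TAA"
    seq = "C" * 60 + gene + "C" * 60
    g = GenomeRecord(id="g", seq=seq)
    ann = CdsAnnotation(seqid="g", start=60, end=60 + len(gene), strand="+")
    return g, ann


def test_label_cds_stop_anchored():
    g, ann = _genome_with_gene()
    groups = group_orfs(extract_orfs(g, min_len=6))
    examples = label_cds(groups, [ann])
    by_label = {e.label: e for e in examples}
    assert 1 in by_label
    pos = by_label[1]
    assert pos.orf_ref.stop_coord == ann.three_prime
    assert pos.seq == pos.orf_ref.seq  # longest member, under max_len
    # every group yields exactly one example
    assert len(examples) == len(groups)


def test_label_cds_truncates_to_510():
    long_orf = "ATG" + "GCT" * 400 + "TAA"
    g = GenomeRecord(id="g", seq=long_orf)
    ann = CdsAnnotation(seqid="g", start=0, end=len(long_orf), strand="+")
    groups = group_orfs(extract_orfs(g, min_len=6))
    (ex,) = [e for e in label_cds(groups, [ann]) if e.label == 1]
    assert len(ex.seq) == 510
    assert ex.seq == long_orf[:510]  # 5'-most kept


def test_tis_windows_one_positive_per_gene():
    g, ann = _genome_with_gene()
    groups = group_orfs(extract_orfs(g, min_len=6))
    wins = build_tis_windows(groups, [ann], g)
    assert len(wins) == 2  # true start + internal decoy ATG
    assert sum(w.label for w in wins) == 1
    for w in wins:
        assert len(w.seq) == 60
        assert w.seq[30:33] in START_CODONS
    true = [w for w in wins if w.label == 1][0]
    assert true.candidate_start == ann.five_prime


def test_tis_window_boundary_skip():
    gene = "ATG" + "GCT" * 10 + "TAA"
    g = GenomeRecord(id="g", seq="C" * 10 + gene + "C" * 60)
    ann = CdsAnnotation(seqid="g", start=10, end=10 + len(gene), strand="+")
    groups = group_orfs(extract_orfs(g, min_len=6))
    wins = build_tis_windows(groups, [ann], g, flank=30)
    assert wins == []  # start at 10 < flank -> skipped


def test_tis_windows_only_matched_groups():
    g = random_genome(3000, 31)
    groups = group_orfs(extract_orfs(g, min_len=30))
    assert build_tis_windows(groups, [], g) == []


def _mk_examples(lengths, label):
    out = []
    for i, ln in enumerate(lengths):
        orf = None
        out.append(CdsExample(seq="A" * ln, label=label, orf_ref=orf,
                              organism_id=f"org{i % 5}"))
    return out


def test_length_balance_per_bin_counts():
    rng = np.random.default_rng(0)
    pos = _mk_examples(rng.integers(300, 350, size=10), 1)
    neg = _mk_examples(rng.integers(300, 350, size=100), 0)
    out = length_balance(pos, neg, bin_width=50, seed=1)
    assert sum(1 for e in out if e.label == 0) == 10
    # determinism
    out2 = length_balance(pos, neg, bin_width=50, seed=1)
    assert [e.seq for e in out] == [e.seq for e in out2]


def test_length_balance_histogram_oracle():
    rng = np.random.default_rng(3)
    pos = _mk_examples(rng.integers(90, 600, size=200), 1)
    neg = _mk_examples(rng.integers(90, 300, size=400), 0)
    out = length_balance(pos, neg, bin_width=50, seed=2)
    pos_hist = Counter(e.length // 50 for e in pos)
    neg_hist = Counter(e.length // 50 for e in neg)
    kept_neg = Counter(e.length // 50 for e in out if e.label == 0)
    for b in pos_hist:
        assert kept_neg.get(b, 0) == min(pos_hist[b], neg_hist.get(b, 0))
    assert sum(1 for e in out if e.label == 0) <= len(pos)


def test_undersample_balances_classes():
    rng = np.random.default_rng(4)
    ex = _mk_examples(rng.integers(90, 200, size=140), 0)[:100] + \
        _mk_examples(rng.integers(90, 200, size=40), 1)
    out = undersample(ex, seed=0)
    counts = Counter(e.label for e in out)
    assert counts[0] == counts[1] == 40
    assert undersample(_mk_examples([100] * 5, 0) +
                       _mk_examples([100] * 5, 1), seed=0).__len__() == 10
    with pytest.raises(ValueError):
        undersample(_mk_examples([100] * 5, 1), seed=0)


def test_example_shards_round_trip(tmp_path):
    examples = _mk_examples(range(100, 160), 1) + _mk_examples([90] * 7, 0)
    from bactgene.orf_dataset import (iter_example_shards,
                                      write_example_shards)
    paths = write_example_shards(examples, tmp_path, shard_size=25)
    assert len(paths) == 3
    back = list(iter_example_shards(tmp_path))
    assert [(b.seq, b.label, b.organism_id) for b in back] == \
        [(e.seq, e.label, e.organism_id) for e in examples]


def test_split_by_organism_disjoint_and_deterministic():
    examples = [CdsExample(seq="A", label=0, orf_ref=None,
                           organism_id=f"org{i}")
                for i in range(10) for _ in range(3)]
    tr, te, ev = split_by_organism(examples, (0.6, 0.2, 0.2), seed=5)
    orgs = [{e.organism_id for e in part} for part in (tr, te, ev)]
    assert len(orgs[0]) == 6 and len(orgs[1]) == 2 and len(orgs[2]) == 2
    assert not (orgs[0] & orgs[1]) and not (orgs[0] & orgs[2]) \
        and not (orgs[1] & orgs[2])
    tr2, te2, ev2 = split_by_organism(examples, (0.6, 0.2, 0.2), seed=5)
    assert [e.organism_id for e in tr] == [e.organism_id for e in tr2]
    with pytest.raises(ValueError):
        split_by_organism(examples[:3], (0.5, 0.25, 0.25), seed=0)
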