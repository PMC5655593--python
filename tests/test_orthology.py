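import numpy as np
import pytest
from Bio.Align import substitution_matrices

from omegapair.orthology import (
    align_proteins_global,
    cluster_paralogs,
    find_bbh_pairs,
    hybrid_ortholog_pairs,
)

B62 = substitution_matrices.load("BLOSUM62")
AAS = "ARNDCQEGHILKMFPSTWYV"


def test_self_alignment_scores_diagonal():
    aln = align_proteins_global("MKV", "MKV")
    assert aln.pct_identity == 100.0
    assert "-" not in aln.aligned_query + aln.aligned_subject
    expected = sum(B62[c, c] for c in "MKV")
    assert aln.score == pytest.approx(expected)


def test_single_mismatch_alignment():
    # brute-force check over the tiny DP: substitution beats any gap here
    aln = align_proteins_global("MKV", "MRV")
    assert aln.aligned_query == "MKV" and aln.aligned_subject == "MRV"
    assert aln.pct_identity == pytest.approx(100 * 2 / 3)
    assert aln.score == pytest.approx(B62["M", "M"] + B62["K", "R"] + B62["V", "V"])


def test_coverage_asymmetric_lengths():
    aln = align_proteins_global("MK", "MKKK")
    assert aln.query_coverage == pytest.approx(100.0)
    assert aln.subject_coverage == pytest.approx(50.0)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_proteins_global("", "MKV")


def _mutate(seq, n_subs, rng):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_subs, replace=False):
        s[pos] = AAS[(AAS.index(s[pos]) + 1 + rng.integers(18)) % 20]
    return "".join(s)


def test_cluster_identical_sequences_single_cluster():
    prot = {"a": "MKVLW" * 10, "b": "MKVLW" * 10, "c": "MKVLW" * 10}
    clusters = cluster_paralogs(prot, 90, 90)
    assert len(clusters) == 1
    assert clusters[0].members == ["a", "b", "c"]
    assert clusters[0].representative == "a"  # tie on length -> lexicographic


def test_cluster_unrelated_sequences_are_singletons():
    rng = np.random.default_rng(0)
    prot = {
        "a": "".join(rng.choice(list(AAS), 60)),
        "b": "".join(rng.choice(list(AAS), 60)),
    }
    clusters = cluster_paralogs(prot, 80, 80)
    assert len(clusters) == 2


def test_cluster_single_linkage_chain():
    rng = np.random.default_rng(1)
    base = "".join(rng.choice(list(AAS), 100))
    a = base
    b = _mutate(base, 10, rng)  # ~90% id to a
    c = _mutate(b, 10, rng)  # ~90% id to b, ~80% to a
    clusters = cluster_paralogs({"A": a, "B": b, "C": c}, 85, 80)
    assert len(clusters) == 1 and clusters[0].members == ["A", "B", "C"]


def test_bbh_identical_proteomes_full_matching():
    rng = np.random.default_rng(2)
    prot = {f"g{i}": "".join(rng.choice(list(AAS), 80)) for i in range(6)}
    prot_b = {f"h{i}": prot[f"g{i}"] for i in range(6)}
    pairs = find_bbh_pairs(prot, prot_b)
    assert len(pairs) == 6
    assert all(p.gene_a[1:] == p.gene_b[1:] for p in pairs)


def test_bbh_equals_bruteforce_mutual_argmax():
    """With all pairwise scores distinct, BBH must equal the mutual-argmax
    of the exhaustively computed score matrix."""
    from omegapair.orthology import DEFAULT_SCORING

    rng = np.random.default_rng(3)
    # varying lengths keep all 25 pairwise scores distinct
    ancestors = ["".join(rng.choice(list(AAS), 60 + 13 * i)) for i in range(5)]
    pa = {f"a{i}": ancestors[i] for i in range(5)}
    pb = {f"b{i}": _mutate(ancestors[i], 12, rng) for i in range(5)}

    aligner = DEFAULT_SCORING.make_aligner()
    scores = {
        (ga, gb): aligner.score(sa, sb)
        for ga, sa in pa.items()
        for gb, sb in pb.items()
    }
    # the oracle needs unique best hits (ties elsewhere are irrelevant)
    for ga in pa:
        row = sorted((scores[(ga, gb)] for gb in pb), reverse=True)
        assert row[0] > row[1], "test needs a unique best hit per query"
    for gb in pb:
        col = sorted((scores[(ga, gb)] for ga in pa), reverse=True)
        assert col[0] > col[1], "test needs a unique best hit per subject"
    expected = set()
    for ga in pa:
        gb = max(pb, key=lambda g: scores[(ga, g)])
        if max(pa, key=lambda g: scores[(g, gb)]) == ga:
            expected.add((ga, gb))

    got = {(p.gene_a, p.gene_b) for p in find_bbh_pairs(pa, pb, prefilter="never")}
    assert got == expected


def test_bbh_symmetric_and_partial_matching():
    rng = np.random.default_rng(4)
    ancestors = ["".join(rng.choice(list(AAS), 70)) for _ in range(6)]
    pa = {f"a{i}": ancestors[i] for i in range(6)}
    pb = {f"b{i}": _mutate(ancestors[i], 15, rng) for i in range(4)}
    fwd = {(p.gene_a, p.gene_b) for p in find_bbh_pairs(pa, pb)}
    rev = {(p.gene_b, p.gene_a) for p in find_bbh_pairs(pb, pa)}
    assert fwd == rev
    genes = [g for pair in fwd for g in pair]
    assert len(genes) == len(set(genes))


def test_hybrid_recall_on_simulated_pair(small_pair):
    rec_a, rec_b, truth = small_pair
    pairs = hybrid_ortholog_pairs(rec_a.proteome(), rec_b.proteome())
    found = {(p.gene_a, p.gene_b) for p in pairs}
    true_pairs = set(map(tuple, truth.ortholog_pairs))
    recall = len(found & true_pairs) / len(true_pairs)
    assert recall >= 0.99
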