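import dataclasses

import pytest

from omegapair.genome_model import (
    CdsFeature,
    GenomeRecord,
    GenomeValidationError,
    coding_density,
    genome_size_metrics,
    read_genome,
    write_genome,
)


def _write_fasta(path, contigs):
    with open(path, "w") as fh:
        for cid, seq in contigs:
            fh.write(f">{cid}\n{seq}\n")


def _write_gff(path, rows):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, start, end, strand, gid in rows:
            fh.write(
                f"{contig}\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={gid}\n"
            )


def _simple_cds(n_codons_body):
    # ATG + n AAA codons (Lys) + TAA
    return "ATG" + "AAA" * n_codons_body + "TAA"


def test_read_genome_extracts_and_translates(tmp_path):
    seq = _simple_cds(98)  # 300 bp total
    assert len(seq) == 300
    _write_fasta(tmp_path / "g.fna", [("c1", seq)])
    _write_gff(tmp_path / "g.gff3", [("c1", 1, 300, "+", "gene1")])
    rec = read_genome(tmp_path / "g.fna", tmp_path / "g.gff3")
    assert len(rec.contigs) == 1 and len(rec.cds_list) == 1
    cds = rec.cds_list[0]
    assert len(cds.aa_seq) == 99  # terminal stop removed
    assert cds.aa_seq == "M" + "K" * 98


def test_read_genome_skips_bad_frames_and_internal_stops(tmp_path):
    good = _simple_cds(8)  # 30 bp
    bad_frame = good + "A"  # 31 bp, not divisible by 3
    internal_stop = "ATG" + "TAA" + "AAA" + "TAA"  # stop at codon 2
    seq = good + bad_frame + internal_stop + "G" * 10
    _write_fasta(tmp_path / "g.fna", [("c1", seq)])
    _write_gff(
        tmp_path / "g.gff3",
        [
            ("c1", 1, 30, "+", "ok"),
            ("c1", 31, 61, "+", "frame"),
            ("c1", 62, 73, "+", "stopgene"),
        ],
    )
    rec = read_genome(tmp_path / "g.fna", tmp_path / "g.gff3")
    assert [c.gene_id for c in rec.cds_list] == ["ok"]
    reasons = dict(rec.skip_report)
    assert "not divisible by 3" in reasons["frame"]
    assert "internal stop" in reasons["stopgene"]


def test_minus_strand_cds_is_reverse_complement(tmp_path):
    from Bio.Seq import Seq

    cds = _simple_cds(8)
    genomic = str(Seq(cds).reverse_complement())
    _write_fasta(tmp_path / "g.fna", [("c1", genomic + "ACGT" * 3)])
    _write_gff(tmp_path / "g.gff3", [("c1", 1, 30, "-", "rev")])
    rec = read_genome(tmp_path / "g.fna", tmp_path / "g.gff3")
    assert rec.cds_list[0].nt_seq == cds


def test_unknown_contig_raises_naming_the_feature(tmp_path):
    _write_fasta(tmp_path / "g.fna", [("c1", _simple_cds(8))])
    _write_gff(tmp_path / "g.gff3", [("cX", 1, 30, "+", "lost")])
    with pytest.raises(GenomeValidationError, match="lost"):
        read_genome(tmp_path / "g.fna", tmp_path / "g.gff3")


def test_cds_table_fallback(tmp_path):
    seq = _simple_cds(8)
    _write_fasta(tmp_path / "g.fna", [("c1", seq)])
    with open(tmp_path / "g.tsv", "w") as fh:
        fh.write("gene_id\tcontig_id\tstart\tend\tstrand\n")
        fh.write("t1\tc1\t1\t30\t+\n")
    rec = read_genome(tmp_path / "g.fna", tmp_path / "g.tsv")
    assert rec.cds_list[0].gene_id == "t1"
    assert rec.cds_list[0].nt_seq == seq


def _toy_genome(cds_spans, length=1000):
    seq = ("ACGT" * ((length // 4) + 1))[:length]
    feats = [
        CdsFeature(gene_id=f"g{i}", contig_id="c1", start=s, end=e, strand="+")
        for i, (s, e) in enumerate(cds_spans)
    ]
    return GenomeRecord(genome_id="toy", contigs=[("c1", seq)], cds_list=feats)


def test_coding_density_union_vs_literal_on_overlap():
    g = _toy_genome([(1, 300), (1, 300)])
    assert coding_density(g, mode="union") == pytest.approx(30.0)
    assert coding_density(g, mode="literal") == pytest.approx(60.0)


def test_coding_density_modes_agree_without_overlap():
    g = _toy_genome([(1, 300), (401, 700)])
    assert coding_density(g, "union") == pytest.approx(coding_density(g, "literal"))
    assert coding_density(g, "union") == pytest.approx(60.0)


def test_union_density_invariant_under_permutation_and_splitting():
    base = _toy_genome([(11, 310), (401, 700)])
    permuted = _toy_genome([(401, 700), (11, 310)])
    split = _toy_genome([(11, 150), (151, 310), (401, 700)])
    ref = coding_density(base, "union")
    assert coding_density(permuted, "union") == pytest.approx(ref)
    assert coding_density(split, "union") == pytest.approx(ref)


def test_no_cds_density_zero_and_metrics():
    g = GenomeRecord(genome_id="e", contigs=[("c1", "ACGT" * 100)])
    assert coding_density(g) == 0.0
    m = genome_size_metrics(g)
    assert m.size_cds == 0 and m.size_bp == 400


def test_size_metrics_counts(small_pair):
    rec_a, _, truth = small_pair
    m = genome_size_metrics(rec_a)
    assert m.size_cds == truth.n_genes
    assert m.size_bp == truth.size_bp_a
    # simulator bookkeeping vs independent recomputation of density
    expected = 100.0 * (1.0 - truth.noncoding_fraction_realized)
    assert m.coding_density_pct == pytest.approx(expected, abs=1.0)


def test_fasta_gff_roundtrip(tmp_path, small_pair):
    rec_a, _, _ = small_pair
    write_genome(rec_a, tmp_path / "a.fna", tmp_path / "a.gff3")
    back = read_genome(tmp_path / "a.fna", tmp_path / "a.gff3", genome_id="sim_A")
    assert back.contigs == rec_a.contigs
    assert [dataclasses.astuple(c) for c in back.cds_list] == [
        dataclasses.astuple(c) for c in rec_a.cds_list
    ]
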