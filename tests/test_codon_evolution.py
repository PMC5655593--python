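import math
import warnings

import numpy as np
import pytest

from omegapair.codon_evolution import (
    CodonAlignment,
    CodonError,
    DnDsEstimate,
    apply_saturation_filters,
    backthread_codon_alignment,
    code_tables,
    ng86_count_differences,
    ng86_count_sites,
    ng86_estimate,
    summarize_genome_pair,
    yn00_estimate,
)
from omegapair.orthology import ProteinAlignment

TABLES = code_tables(11)


def _cols(pairs):
    return CodonAlignment(gene_a="a", gene_b="b", codon_columns=list(pairs))


# ---------------------------------------------------------------------------
# counting


def test_site_counts_reference_codons():
    assert ng86_count_sites("TTT") == pytest.approx((1 / 3, 8 / 3))
    assert ng86_count_sites("ATG") == pytest.approx((0.0, 3.0))


def test_site_counts_sum_to_three_for_all_sense_codons(sense_codons):
    for codon in sense_codons:
        s, n = ng86_count_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert s >= 0 and n >= 0


def test_stop_and_ambiguous_codons_rejected():
    with pytest.raises(CodonError):
        ng86_count_sites("TAA")
    with pytest.raises(CodonError):
        ng86_count_sites("ANA")
    with pytest.raises(CodonError):
        ng86_count_differences("TAG", "TTT")


def test_difference_counts_examples():
    assert ng86_count_differences("TTT", "TTA") == pytest.approx((0.0, 1.0))
    assert ng86_count_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))
    assert ng86_count_differences("ACA", "ACA") == (0.0, 0.0)


def test_difference_counts_symmetric_and_sum_to_hamming(sense_codons):
    rng = np.random.default_rng(11)
    for _ in range(300):
        a, b = rng.choice(sense_codons, size=2)
        sd, nd = ng86_count_differences(a, b)
        assert (sd, nd) == pytest.approx(ng86_count_differences(b, a))
        hamming = sum(x != y for x, y in zip(a, b))
        assert sd + nd == pytest.approx(hamming)


# ---------------------------------------------------------------------------
# back-threading


def _gapless_alignment(aa_a, aa_b):
    return ProteinAlignment(
        query_id="a", subject_id="b", aligned_query=aa_a, aligned_subject=aa_b,
        score=0.0, pct_identity=0.0, query_coverage=100.0, subject_coverage=100.0,
    )


def test_backthread_identical_pair():
    cds = "ATG" + "AAA" * 98 + "TAA"
    aa = "M" + "K" * 98
    ca = backthread_codon_alignment(_gapless_alignment(aa, aa), cds, cds)
    assert len(ca.codon_columns) == 99
    assert ca.n_columns_removed == 0


def test_backthread_drops_gap_and_ambiguous_columns():
    cds_a = "ATGAAACCC"
    cds_b = "ATGCCC"
    aln = ProteinAlignment(
        query_id="a", subject_id="b",
        aligned_query="MKP", aligned_subject="M-P",
        score=0, pct_identity=0, query_coverage=0, subject_coverage=0,
    )
    ca = backthread_codon_alignment(aln, cds_a, cds_b)
    assert len(ca.codon_columns) == 2 and ca.n_columns_removed == 1

    cds_b_n = "ATGCCN"
    aln2 = _gapless_alignment("MP", "MX")
    ca2 = backthread_codon_alignment(aln2, "ATGCCC", cds_b_n)
    assert len(ca2.codon_columns) == 1 and ca2.n_columns_removed == 1


def test_backthread_translation_mismatch_names_gene():
    with pytest.raises(CodonError, match="a"):
        backthread_codon_alignment(_gapless_alignment("MK", "MK"), "ATGCCC", "ATGAAA")


# ---------------------------------------------------------------------------
# estimators


def test_identical_sequences_sentinel_omega():
    ca = _cols([("ATG", "ATG"), ("AAA", "AAA"), ("CCC", "CCC")])
    for est in (ng86_estimate(ca), yn00_estimate(ca)):
        assert est.dS == 0.0 and est.dN == 0.0
        assert est.omega == 999.0


def test_zero_nonsynonymous_gives_omega_zero():
    # TTT->TTC is synonymous (Phe), no nonsynonymous changes present
    ca = _cols([("TTT", "TTC")] * 3 + [("AAA", "AAA")] * 60)
    est = ng86_estimate(ca)
    assert est.Nd == 0.0
    assert est.omega == 0.0


def test_ng86_estimator_symmetric_in_roles():
    rng = np.random.default_rng(12)
    cols = [tuple(rng.choice(TABLES.sense_codons, 2)) for _ in range(200)]
    fwd = ng86_estimate(_cols(cols))
    rev = ng86_estimate(_cols([(b, a) for a, b in cols]))
    assert fwd.S == pytest.approx(rev.S)
    assert fwd.dS == pytest.approx(rev.dS)
    assert fwd.dN == pytest.approx(rev.dN)


def test_ng86_sites_sum_matches_alignment_length():
    rng = np.random.default_rng(13)
    cols = [tuple(rng.choice(TABLES.sense_codons, 2)) for _ in range(150)]
    est = ng86_estimate(_cols(cols))
    assert est.S + est.N == pytest.approx(3 * 150, abs=1e-6)


def test_yn00_symmetric_in_roles():
    rng = np.random.default_rng(14)
    cols = [tuple(rng.choice(TABLES.sense_codons, 2)) for _ in range(200)]
    fwd = yn00_estimate(_cols(cols))
    rev = yn00_estimate(_cols([(b, a) for a, b in cols]))
    assert fwd.dS == pytest.approx(rev.dS)
    assert fwd.dN == pytest.approx(rev.dN)


def test_empty_alignment_rejected():
    with pytest.raises(ValueError):
        ng86_estimate(_cols([]))
    with pytest.raises(ValueError):
        yn00_estimate(_cols([]))


def test_estimators_match_independent_implementation(small_pair):
    """Cross-check both counting methods against Bio.codonalign on real
    simulated divergence (same codon columns fed to both)."""
    from Bio.Data import CodonTable
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rec_a, rec_b, _ = small_pair
    cols = []
    for fa, fb in zip(rec_a.cds_list[:20], rec_b.cds_list[:20]):
        for i in range(0, len(fa.nt_seq) - 3, 3):  # skip terminal stop
            ca_, cb_ = fa.nt_seq[i : i + 3], fb.nt_seq[i : i + 3]
            if ca_ in TABLES.index and cb_ in TABLES.index:
                cols.append((ca_, cb_))
    ca = _cols(cols)
    t11 = CodonTable.generic_by_id[11]
    seq_a = CodonSeq("".join(a for a, _ in cols))
    seq_b = CodonSeq("".join(b for _, b in cols))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dn_ref, ds_ref = cal_dn_ds(seq_a, seq_b, method="NG86", codon_table=t11)
        dn2_ref, ds2_ref = cal_dn_ds(seq_a, seq_b, method="YN00", codon_table=t11)
    ng = ng86_estimate(ca)
    yn = yn00_estimate(ca)
    # the two codebases implement different variants of the kappa/frequency
    # weighting, so agreement is expected on the 10% scale, not exactly
    assert ng.dN == pytest.approx(dn_ref, rel=0.10)
    assert ng.dS == pytest.approx(ds_ref, rel=0.10)
    assert yn.dN == pytest.approx(dn2_ref, rel=0.10)
    assert yn.dS == pytest.approx(ds2_ref, rel=0.10)


# ---------------------------------------------------------------------------
# filters & summaries


def _est(ds, omega):
    return DnDsEstimate(
        gene_a="a", gene_b="b", method="NG86", S=100, N=200, Sd=1, Nd=1,
        dS=ds, dN=ds * omega if math.isfinite(ds) else 0.0, omega=omega,
    )


def test_filters_reasons_and_order():
    retained, discarded = apply_saturation_filters(
        [_est(0.05, 0.3), _est(0.5, 0.2), _est(0.8, 100.0)]
    )
    assert [e.gene_a for e in retained] == ["a"] and retained[0].dS == 0.5
    reasons = [r for _, r in discarded]
    assert reasons == ["dS < 0.1", "dN/dS > 99"]


def test_filters_catch_sentinels_and_saturation():
    retained, discarded = apply_saturation_filters(
        [_est(0.0, 999.0), _est(math.inf, 0.0)]
    )
    assert retained == []
    assert [r for _, r in discarded] == ["dS < 0.1", "dS > 1.6"]


def test_filters_order_independent():
    ests = [_est(0.05, 0.3), _est(0.5, 0.2), _est(2.0, 0.2), _est(0.3, 120.0)]
    ret_fwd, _ = apply_saturation_filters(ests)
    ret_rev, _ = apply_saturation_filters(ests[::-1])
    assert {id(e) for e in ret_fwd} == {id(e) for e in ret_rev}


def test_pair_summary_mean_sem_and_retention():
    retained = [_est(0.5, w) for w in (0.1, 0.2, 0.3)]
    s = summarize_genome_pair(retained, 10, 40, 40)
    assert s.mean_omega == pytest.approx(0.2)
    assert s.sem_omega == pytest.approx(0.1 / math.sqrt(3))
    assert s.retained_fraction_of_capacity == pytest.approx(3 / 40)
    assert s.keep  # 7.5% of capacity, above the 5% rule

    below = summarize_genome_pair(retained, 10, 100, 100)
    assert not below.keep  # 3% of capacity

    single = summarize_genome_pair(retained[:1], 10, 10, 10)
    assert single.sem_omega is None and not single.keep  # SEM undefined
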