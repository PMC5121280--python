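import itertools
import warnings

import numpy as np
import pytest
from Bio.Data import CodonTable

from famsynt._codon import SENSE_CODONS, STOP_CODONS
from famsynt.kaks import CodonAlignment, backtranslate, ng86, sliding_window
from famsynt.simulate import evolve_cds

_CT = CodonTable.unambiguous_dna_by_id[1]


def _aa(codon):
    return "*" if codon in _CT.stop_codons else _CT.forward_table[codon]


def oracle_pathway_diff(c1, c2):
    """Independent exhaustive pathway enumeration (test oracle)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid, blocked = [], []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _CT.stop_codons:
                ok = False
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (valid if ok else blocked).append((sd, nd))
    paths = valid or blocked
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


def test_identical_pair_has_zero_rates_and_undefined_ratio():
    cds = "ATGGCTAAGTGC" * 10
    res = ng86(CodonAlignment("a", "b", cds, cds))
    assert res.Sd == res.Nd == 0
    assert res.Ka == 0 and res.Ks == 0
    assert res.ratio is None
    assert res.classification == "undefined"


def test_single_synonymous_codon_difference():
    res = ng86(CodonAlignment("a", "b", "TTT", "TTC"))
    assert res.Sd == 1 and res.Nd == 0
    # only the third-position T->C change in TTT is synonymous: S = 1/3
    assert res.S == pytest.approx(1 / 3)
    assert res.N == pytest.approx(3 - 1 / 3)


def test_ng86_is_symmetric_in_sequence_order():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 30))
        b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 30))
        ra = ng86(CodonAlignment("a", "b", a, b))
        rb = ng86(CodonAlignment("b", "a", b, a))
        assert ra.Sd == rb.Sd and ra.Nd == rb.Nd
        assert ra.S == rb.S and ra.N == rb.N


def test_site_counts_sum_to_three_per_codon_column():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(5, 50))
        a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n))
        b = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n))
        res = ng86(CodonAlignment("a", "b", a, b))
        assert res.S + res.N == pytest.approx(3 * n, abs=1e-6)


def test_pathway_averaging_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    from famsynt._codon import diff_table

    table = diff_table()
    for _ in range(1000):
        c1 = SENSE_CODONS[rng.integers(0, 61)]
        c2 = SENSE_CODONS[rng.integers(0, 61)]
        sd, nd = table[(c1, c2)]
        osd, ond = oracle_pathway_diff(c1, c2)
        assert sd == pytest.approx(osd, abs=1e-12), (c1, c2)
        assert nd == pytest.approx(ond, abs=1e-12), (c1, c2)


def test_ng86_close_to_biopython_reference_on_diverged_pair():
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore")
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import codonalign
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rng = np.random.default_rng(3)
    anc = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 200))
    der = evolve_cds(anc, 0.4, omega=0.5, kappa=1.0, seed=9)
    mine = ng86(CodonAlignment("a", "b", anc, der))
    dn, ds = cal_dn_ds(CodonSeq(anc), CodonSeq(der), method="NG86")
    # Biopython keeps stop-crossing pathways; tiny discrepancies allowed
    assert mine.Ka == pytest.approx(dn, abs=0.01)
    assert mine.Ks == pytest.approx(ds, abs=0.01)


def test_gap_columns_excluded_from_sites_and_differences():
    aln = CodonAlignment("a", "b", "ATG---AAA", "ATGGGGAAG")
    res = ng86(aln)
    assert res.S + res.N == pytest.approx(6.0, abs=1e-6)  # two gap-free codons


def test_high_divergence_flags_undefined_correction():
    # saturated synonymous signal: pS >= 3/4 has no Jukes-Cantor correction
    from famsynt.kaks import _jc_correct

    assert _jc_correct(0.74) is not None
    assert _jc_correct(0.75) is None


@pytest.mark.parametrize(
    "length,expected", [(150, 1), (300, 17), (159, 2), (149, 0)]
)
def test_sliding_window_count_formula(length, expected):
    n = length - (length % 3)
    aln = CodonAlignment("a", "b", "A" * n, "A" * n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = sliding_window(aln, window_bp=150, step_bp=9)
    assert len(series.starts) == expected
    if expected:
        assert series.starts[0] == 1
        assert series.starts[-1] == 1 + (expected - 1) * 9


def test_sliding_window_rejects_bad_parameters():
    aln = CodonAlignment("a", "b", "A" * 300, "A" * 300)
    with pytest.raises(ValueError):
        sliding_window(aln, window_bp=100)  # not divisible by 3
    with pytest.raises(ValueError):
        sliding_window(aln, step_bp=0)


def test_backtranslate_threads_gaps_as_codon_triplets():
    caln = backtranslate("M-K", "MAK", "ATGAAA", "ATGGCTAAG")
    assert caln.seq_a == "ATG---AAA"
    assert caln.seq_b == "ATGGCTAAG"
    # ungapping recovers each CDS
    assert caln.seq_a.replace("-", "") == "ATGAAA"


def test_backtranslate_names_discordant_residue():
    with pytest.raises(ValueError, match="residue 2"):
        backtranslate("MK", "MK", "ATGGCT", "ATGAAA", id_a="x", id_b="y")


def test_backtranslate_round_trip_on_evolved_pair():
    from famsynt._codon import translate_cds
    from famsynt.msa import align_pair

    rng = np.random.default_rng(4)
    anc = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, 120))
    der = evolve_cds(anc, 0.3, seed=5)
    pa, pb = align_pair(translate_cds(anc), translate_cds(der))
    caln = backtranslate(pa, pb, anc, der)
    assert caln.seq_a.replace("-", "") == anc
    assert caln.seq_b.replace("-", "") == der
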