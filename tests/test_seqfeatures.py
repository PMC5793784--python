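import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicefid.genome import Intron
from splicefid.junctions import SpliceEvent
from splicefid.seqfeatures import (
    KMER_NAMES,
    WINDOWS,
    build_feature_matrix,
    extract_site_windows,
    feature_registry,
    find_branch_point,
    fold_energy_proxy,
    kmer_frequencies,
    nussinov_max_pairs,
    rescale_scores,
    revcomp,
    score_sequence,
    train_pwm,
    window_sequence,
)
from splicefid.synthetic_data import SimulationConfig, make_genome

SEQS = st.text(alphabet="ACGU", min_size=1, max_size=12)


def enumerate_max_pairs(seq, min_loop=3):
    """Independent oracle: explicit enumeration of all nested pairings."""
    pairs = {"AU", "UA", "GC", "CG", "GU", "UG", "AT", "TA", "GT", "TG"}
    s = seq.upper()
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(positions):
        if not positions:
            return 0
        first, rest = positions[0], positions[1:]
        best = rec(rest)  # leave first unpaired
        for idx, j in enumerate(rest):
            if j - first > min_loop and s[first] + s[j] in pairs:
                inside = rest[:idx]
                outside = rest[idx + 1:]
                best = max(best, 1 + rec(inside) + rec(outside))
        return best

    return rec(tuple(range(len(s))))


# ---------------------------------------------------------------------------
# windows

def test_5ss_window_plus_strand():
    contig = "".join("ACGT"[i % 4] for i in range(300))
    seq, trunc = window_sequence(contig, 100, "+", *WINDOWS["5ss"])
    assert seq == contig[96:107]
    assert len(seq) == 11
    assert not trunc


def test_window_lengths():
    contig = "A" * 200
    for key, (u, d) in WINDOWS.items():
        seq, _ = window_sequence(contig, 100, "+", u, d)
        assert len(seq) == u + d


def test_minus_strand_window_is_revcomp_of_mirror():
    """Brute-force strand-flip oracle: extracting on the minus strand
    equals extracting from the reverse-complemented contig at the
    mirrored anchor."""
    rng = np.random.default_rng(0)
    contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    flipped = revcomp(contig)
    for anchor in (50, 100, 333):
        for u, d in WINDOWS.values():
            minus, t1 = window_sequence(contig, anchor, "-", u, d)
            mirror_anchor = len(contig) - 1 - anchor
            plus, t2 = window_sequence(flipped, mirror_anchor, "+", u, d)
            assert minus == plus
            assert t1 == t2


def test_window_truncation_flagged():
    seq, trunc = window_sequence("ACGTACGT", 1, "+", *WINDOWS["3ss"])
    assert trunc
    assert len(seq) < sum(WINDOWS["3ss"])


def test_extract_site_windows_anchors():
    # intron [100, 200) on + strand inside a readable contig
    contig = "".join("ACGT"[i % 4] for i in range(300))
    iv = Intron("chrI", 100, 200, "+", "G", "T", 0, bp_pos=160)
    wins = extract_site_windows(iv, {"chrI": contig})
    assert wins["5ss"][0] == contig[96:107]
    assert wins["3ss"][0] == contig[183:203]  # anchor = last intron base 199
    assert wins["bp"][0] == contig[153:163]


def test_extract_site_windows_no_bp():
    contig = "A" * 300
    iv = Intron("chrI", 100, 200, "+", "G", "T", 0)
    wins = extract_site_windows(iv, {"chrI": contig})
    assert wins["bp"] == (None, False)


# ---------------------------------------------------------------------------
# PWM train / score / rescale

def test_pwm_identical_sequences_no_pseudocount():
    pwm = train_pwm(["ACGT"] * 10, pseudocount=0.0)
    assert pwm.weights[0, 0] == 1.0  # A at pos 0
    assert pwm.weights[1, 1] == 1.0  # C at pos 1
    assert np.allclose(pwm.weights.sum(axis=1), 1.0)


def test_pwm_pseudocount_hand_arithmetic():
    pwm = train_pwm(["A"], pseudocount=0.5)
    # counts: A = 1.5, C/G/T = 0.5 each; total 3.0
    assert pwm.weights[0, 0] == pytest.approx(1.5 / 3.0)
    assert pwm.weights[0, 1] == pytest.approx(0.5 / 3.0)


def test_pwm_columns_sum_to_one_random_input():
    rng = np.random.default_rng(3)
    seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 8)) for _ in range(40)]
    pwm = train_pwm(seqs)
    assert np.allclose(pwm.weights.sum(axis=1), 1.0)


def test_pwm_unequal_lengths_rejected():
    with pytest.raises(ValueError):
        train_pwm(["ACGT", "ACG"])


def test_score_uniform_pwm():
    pwm = train_pwm(["ACGT", "CGTA", "GTAC", "TACG"], pseudocount=0.0)
    # every base equally frequent at every position -> p = 0.25
    assert score_sequence(pwm, "AAAA") == pytest.approx(-8.0)


def test_score_consensus_deterministic_pwm_is_zero():
    pwm = train_pwm(["GTATGT"] * 5, pseudocount=0.0)
    assert score_sequence(pwm, "GTATGT") == pytest.approx(0.0)


def test_score_matches_direct_product_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        k = int(rng.integers(4, 12))
        w = rng.dirichlet(np.ones(4), size=k)
        from splicefid.seqfeatures import PWM

        pwm = PWM("x", w)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, k))
        direct = np.log2(np.prod([w[i, "ACGT".index(b)] for i, b in enumerate(seq)]))
        assert score_sequence(pwm, seq) == pytest.approx(direct, rel=1e-10)


def test_score_length_mismatch():
    pwm = train_pwm(["ACGT"])
    with pytest.raises(ValueError):
        score_sequence(pwm, "ACGTA")


def test_rescale_linear_map():
    y, degenerate = rescale_scores([-10.0, -5.0, 0.0])
    assert np.allclose(y, [0.0, 50.0, 100.0])
    assert not degenerate


def test_rescale_degenerate_all_100():
    y, degenerate = rescale_scores([-3.0, -3.0])
    assert np.allclose(y, 100.0)
    assert degenerate


def test_rescale_affine_invariance_of_order():
    rng = np.random.default_rng(11)
    x = rng.normal(size=30)
    y1, _ = rescale_scores(x)
    y2, _ = rescale_scores(2.5 * x + 7.0)
    assert np.allclose(y1, y2, atol=1e-9)
    assert np.argmax(y1) == np.argmax(x)
    assert y1.max() == pytest.approx(100.0)
    assert y1.min() == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# branch point

def _bp_pwm():
    return train_pwm(
        ["CGCTACTAACGCA"[1:11]] * 3 + ["GTTTACTAACTTG"[1:11]] * 3,
        site_class="bp",
    )


def test_find_branch_point_unique_consensus():
    pwm = train_pwm(["GGTACTAACG"] * 4, site_class="bp", pseudocount=0.5)
    intron = "GTATGT" + "C" * 20 + "GGTACTAACG" + "C" * 12 + "TAG"
    # branch A of TACTAAC = 6th motif base; motif starts at 6+20+2
    expect = 6 + 20 + 2 + 5
    assert intron[expect] == "A"
    assert find_branch_point(intron, pwm) == expect


def test_find_branch_point_tie_prefers_3prime():
    pwm = train_pwm(["GGTACTAACG"] * 4, site_class="bp", pseudocount=0.5)
    site = "GGTACTAACG"
    intron = "GTATGT" + site + "CCCC" + site + "CCCCCCCCCC" + "TAG"
    first = 6 + 2 + 5
    second = 6 + 10 + 4 + 2 + 5
    found = find_branch_point(intron, pwm)
    assert found == second > first


def test_find_branch_point_no_adenosine():
    pwm = _bp_pwm()
    assert find_branch_point("G" * 40, pwm) is None


def test_generator_branch_points_recovered():
    """Planted BPs in consensus-strength-1 introns are recovered at the
    planted position for >=99% of introns."""
    cfg = SimulationConfig(seed=13, n_genes=60, frac_intron_containing=1.0,
                           consensus_strength=1.0, n_cryptic_intronless=0)
    sg = make_genome(cfg)
    from splicefid.seqfeatures import train_pwms_from_genome

    gm = sg.to_genome_model()
    pwms = train_pwms_from_genome(gm, sg.seqs)
    hits = total = 0
    for g in sg.genes:
        S, E = g.intron
        iseq = sg.seqs[g.chrom][S:E]
        if g.strand == "-":
            iseq = revcomp(iseq)
        rel = find_branch_point(iseq, pwms["bp"])
        expect = (g.bp_pos - S) if g.strand == "+" else (E - 1 - g.bp_pos)
        total += 1
        hits += rel == expect
    assert total == 60
    assert hits / total >= 0.99


# ---------------------------------------------------------------------------
# k-mers

def test_kmer_homopolymer():
    v = kmer_frequencies("AAAA")
    d = dict(zip(KMER_NAMES, v))
    assert d["A"] == 1.0 and d["AA"] == 1.0 and d["AAA"] == 1.0
    assert sum(v) == pytest.approx(3.0)  # one full unit per k


def test_kmer_acgt():
    d = dict(zip(KMER_NAMES, kmer_frequencies("ACGT")))
    assert all(d[b] == 0.25 for b in "ACGT")
    assert d["AC"] == pytest.approx(1 / 3)


def test_kmer_vector_has_84_entries():
    assert len(KMER_NAMES) == 84
    assert kmer_frequencies("ACGTACGTAC").shape == (84,)


def test_kmer_short_sequence_flags_missing():
    v = dict(zip(KMER_NAMES, kmer_frequencies("AC")))
    assert v["A"] == 0.5
    assert np.isnan(v["AAA"])


@given(st.text(alphabet="ACGT", min_size=3, max_size=60))
def test_kmer_frequencies_properties(seq):
    v = kmer_frequencies(seq)
    assert np.all((v >= 0) & (v <= 1))
    assert v[:4].sum() == pytest.approx(1.0)  # one-mers partition the sequence


# ---------------------------------------------------------------------------
# folding proxy

def test_fold_no_complementarity():
    assert fold_energy_proxy("AAAA") == 0.0


def test_fold_gggccc_single_pair():
    # min loop 3 allows exactly one nested pair in GGGCCC
    assert nussinov_max_pairs("GGGCCC") == 1
    assert fold_energy_proxy("GGGCCC") == pytest.approx(-1 / 6)


@settings(max_examples=150, deadline=None)
@given(SEQS)
def test_fold_matches_enumeration_oracle(seq):
    assert nussinov_max_pairs(seq) == enumerate_max_pairs(seq)


def test_fold_proxy_nonpositive_and_monotone_in_structure():
    rng = np.random.default_rng(5)
    for _ in range(30):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        assert fold_energy_proxy(seq) <= 0.0
    hairpin = "GGGGGGAAAACCCCCC"
    loose = "GGGGGGAAAAGGGGGG"
    assert fold_energy_proxy(hairpin) < fold_energy_proxy(loose)


def test_fold_external_engine_hook():
    called = {}

    def engine(seq):
        called["seq"] = seq
        return -12.0

    assert fold_energy_proxy("ACGTACGT", engine=engine) == pytest.approx(-1.5)
    assert called["seq"] == "ACGTACGT"


# ---------------------------------------------------------------------------
# feature matrix

def test_feature_registry_size():
    cols = feature_registry()
    assert len(cols) == 180
    assert sum(c.startswith("annot_kmer_") for c in cols) == 84
    assert sum(c.startswith("novel_kmer_") for c in cols) == 84


def test_build_feature_matrix_on_generator_events():
    cfg = SimulationConfig(seed=21, n_genes=30, frac_intron_containing=1.0,
                           n_cryptic_intronless=0)
    sg = make_genome(cfg)
    gm = sg.to_genome_model()
    from splicefid.junctions import classify_junction_event
    from conftest import make_junction

    events = []
    for te in sg.truth.events:
        j = make_junction(chrom=te.chrom, start=te.start, end=te.end,
                          strand=te.strand)
        events.append(classify_junction_event(j, gm, event_id=te.event_id))
    fm = build_feature_matrix(events, gm, sg.seqs)
    assert fm.shape == (len(events), 180)
    # paired annotated intron present for every alt event -> no missing values
    assert not fm.isna().any().any()
    # intron lengths consistent with annotation
    for te in sg.truth.events:
        g = next(g for g in sg.genes if g.id == te.gene_id)
        annot_len = g.intron[1] - g.intron[0]
        assert fm.loc[te.event_id, "annot_length"] == annot_len
        assert fm.loc[te.event_id, "novel_length"] == te.end - te.start
    # rescaled scores live on the 0..100 scale
    for col in ("annot_score_3ss", "novel_score_3ss", "annot_score_5ss"):
        assert fm[col].between(0, 100).all()
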