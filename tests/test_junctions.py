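import pytest

from splicefid.genome import GenomeModel
from splicefid.junctions import (
    JunctionRecord,
    classify_junction_event,
    classify_junctions,
    filter_junctions,
    merge_samples,
    parse_sj_tab,
    write_sj_tab,
)
from splicefid.synthetic_data import (
    SimulationConfig,
    make_genome,
    simulate_junction_counts,
)

from conftest import make_junction, two_exon_gene


# ---------------------------------------------------------------------------
# parsing

def test_parse_sj_row(tmp_path):
    p = tmp_path / "sj.tab"
    p.write_text("chrI\t101\t200\t1\t1\t1\t42\t7\t25\n")
    (rec,) = parse_sj_tab(str(p), sample="s1")
    assert (rec.chrom, rec.start, rec.end) == ("chrI", 100, 200)
    assert rec.strand == "+"
    assert rec.annotated
    assert rec.unique_by_sample == {"s1": 42}
    assert rec.multi_by_sample == {"s1": 7}
    assert rec.overhang_by_sample == {"s1": 25}


@pytest.mark.parametrize(
    "motif,expected", [(1, "+"), (2, "-"), (3, "+"), (4, "-"), (0, ".")]
)
def test_strand_code_zero_resolved_from_motif(tmp_path, motif, expected):
    p = tmp_path / "sj.tab"
    p.write_text(f"chrI\t101\t200\t0\t{motif}\t0\t5\t0\t20\n")
    (rec,) = parse_sj_tab(str(p))
    assert rec.strand == expected


def test_malformed_row_reports_line_number(tmp_path):
    p = tmp_path / "sj.tab"
    p.write_text("chrI\t101\t200\t1\t1\t1\t42\t7\t25\nchrI\t5\t6\n")
    with pytest.raises(ValueError, match=":2"):
        parse_sj_tab(str(p))


def test_write_parse_roundtrip(tmp_path):
    cfg = SimulationConfig(seed=5, n_genes=20)
    sg = make_genome(cfg)
    per_sample, _, _ = simulate_junction_counts(sg)
    sample = "WT_1"
    path = str(tmp_path / "rt.tab")
    write_sj_tab(per_sample[sample], path, sample)
    back = parse_sj_tab(path, sample=sample)
    orig = sorted(per_sample[sample], key=lambda r: r.key())
    assert len(back) == len(orig)
    for a, b in zip(sorted(back, key=lambda r: r.key()), orig):
        assert a.key() == b.key()
        assert a.strand == b.strand
        assert a.motif == b.motif
        assert a.annotated == b.annotated
        assert a.unique_by_sample == b.unique_by_sample
        assert a.overhang_by_sample == b.overhang_by_sample


def test_junction_record_rejects_bad_span():
    with pytest.raises(ValueError):
        JunctionRecord("chrI", 200, 100, "+", 1, False)


# ---------------------------------------------------------------------------
# filters

def test_low_count_junction_excluded_across_all_samples():
    counts = {f"s{i}": 4 for i in range(6)}
    rec = make_junction(counts=counts)
    assert filter_junctions([rec]) == []


def test_single_sample_at_threshold_retained():
    counts = {f"s{i}": 0 for i in range(5)}
    counts["s5"] = 5
    rec = make_junction(counts=counts)
    assert filter_junctions([rec]) == [rec]


def test_annotated_overhang_threshold():
    keep = make_junction(annotated=True, overhangs={"WT_1": 3})
    drop = make_junction(start=300, end=400, annotated=True,
                         overhangs={"WT_1": 2})
    assert filter_junctions([keep, drop]) == [keep]


def test_novel_overhang_strictly_greater_than_12():
    drop = make_junction(overhangs={"WT_1": 12})
    keep = make_junction(start=300, end=400, overhangs={"WT_1": 13})
    assert filter_junctions([drop, keep]) == [keep]


def test_mitochondrial_contigs_excluded_by_default():
    recs = [make_junction(chrom=c) for c in ("chrM", "Mito", "chrI")]
    kept = filter_junctions(recs)
    assert [r.chrom for r in kept] == ["chrI"]


def test_annotated_flag_recomputed_from_genome(simple_genome):
    rec = make_junction(start=100, end=200, annotated=False)
    kept = filter_junctions([rec], genome=simple_genome)
    assert kept[0].annotated  # matches GPLUS intron


# ---------------------------------------------------------------------------
# classification

def test_annotated_junction_classified_annotated(simple_genome):
    ev = classify_junction_event(
        make_junction(start=100, end=200, annotated=True), simple_genome
    )
    assert ev.event_class == "annotated"


def test_alt3_up_plus_strand_label(simple_genome):
    # same donor, acceptor 7 nt toward the transcript 5' end
    ev = classify_junction_event(make_junction(start=100, end=193), simple_genome)
    assert ev.event_class == "alt3_up"
    assert ev.offset == -7
    assert ev.label == "u3-7"
    assert ev.paired_intron.key() == ("chrI", 100, 200)


def test_alt3_down_plus_strand(simple_genome):
    ev = classify_junction_event(make_junction(start=100, end=205), simple_genome)
    assert ev.event_class == "alt3_down"
    assert ev.label == "d3-5"


def test_alt5_down_minus_strand_label(simple_genome):
    # GMINUS intron [1100, 1200), donor at the high-coordinate end.
    # Donor moved 4 nt toward the transcript 3' end (coordinates decrease).
    ev = classify_junction_event(
        make_junction(start=1100, end=1196, strand="-", motif=2), simple_genome
    )
    assert ev.event_class == "alt5_down"
    assert ev.offset == 4
    assert ev.label == "d5-4"


def test_alt5_up_minus_strand(simple_genome):
    ev = classify_junction_event(
        make_junction(start=1100, end=1206, strand="-", motif=2), simple_genome
    )
    assert ev.event_class == "alt5_up"
    assert ev.label == "u5-6"


def test_minus_strand_mirror_of_plus_case(simple_genome):
    """Brute-force coordinate-flip oracle: a u3-7 event on the plus-strand
    gene must classify identically to its mirrored minus-strand twin."""
    plus = classify_junction_event(make_junction(start=100, end=193), simple_genome)
    # GMINUS mirrors GPLUS around the contig: intron [1100, 1200), acceptor
    # at the low end; 7 nt toward transcript 5' = coordinate increase.
    minus = classify_junction_event(
        make_junction(start=1107, end=1200, strand="-", motif=2), simple_genome
    )
    assert plus.event_class == minus.event_class == "alt3_up"
    assert plus.label == minus.label == "u3-7"


def test_exon_skip(skip_genome):
    # exon1 end (100) joined to exon3 start (300)
    ev = classify_junction_event(make_junction(start=100, end=300), skip_genome)
    assert ev.event_class == "exon_skip"
    assert ev.paired_intron.key() == ("chrI", 100, 150)
    assert ev.skip_second_intron.key() == ("chrI", 250, 300)


def test_cryptic_intron_in_intronless_gene(simple_genome):
    ev = classify_junction_event(
        make_junction(start=2100, end=2200), simple_genome
    )
    assert ev.event_class == "cryptic_intron"
    assert ev.gene_id == "GNOINTRON"
    assert not ev.host_has_introns


def test_cryptic_intron_inside_intron_gene_flagged(simple_genome):
    # shares neither end with the annotated intron of GPLUS
    ev = classify_junction_event(make_junction(start=110, end=190), simple_genome)
    assert ev.event_class == "cryptic_intron"
    assert ev.host_has_introns


def test_junction_without_gene_unassigned(simple_genome):
    ev = classify_junction_event(
        make_junction(start=5000, end=5100), simple_genome
    )
    assert ev.event_class == "unassigned"


def test_two_gene_tie_prefers_shared_splice_site():
    ga, ta = two_exon_gene("GA", exon1=(0, 100), intron=(100, 200),
                           exon2=(200, 300))
    gb, tb = two_exon_gene("GB", exon1=(0, 150), intron=(150, 260),
                           exon2=(260, 360))
    gm = GenomeModel([ga, gb], [ta, tb])
    ev = classify_junction_event(make_junction(start=100, end=230), gm)
    assert ev.gene_id == "GA"  # shares the donor at 100


def test_every_filtered_junction_maps_to_one_bucket(simple_genome):
    recs = [
        make_junction(start=100, end=200, annotated=True),
        make_junction(start=100, end=193),
        make_junction(start=5000, end=5100),
    ]
    events = classify_junctions(recs, simple_genome)
    classes = [e.event_class for e in events]
    assert classes == ["annotated", "alt3_up", "unassigned"]


def test_generator_event_classes_recovered_exactly():
    """On generator output, recovered classes/labels equal planted ones
    for 100% of events (coordinates carry no noise)."""
    cfg = SimulationConfig(seed=7, n_genes=50, n_exon_skip_genes=2)
    sg = make_genome(cfg)
    gm = sg.to_genome_model()
    per_sample, _, _ = simulate_junction_counts(sg)
    kept = filter_junctions(merge_samples(per_sample), gm)
    events = {e.event_id: e for e in classify_junctions(kept, gm)}
    assert sg.truth.events, "generator planted no events"
    for te in sg.truth.events:
        ev = events[te.event_id]
        assert ev.event_class == te.event_class
        assert ev.label == te.label
        assert ev.gene_id == te.gene_id
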