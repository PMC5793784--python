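"""Shared fixtures: tiny hand-built genomes and junction helpers."""

from __future__ import annotations

import pytest

from splicefid.genome import Exon, Gene, GenomeModel, Transcript
from splicefid.junctions import JunctionRecord


def make_junction(
    chrom="chrI",
    start=100,
    end=200,
    strand="+",
    motif=1,
    annotated=False,
    counts=None,
    overhangs=None,
):
    counts = counts or {"WT_1": 10}
    overhangs = overhangs or {s: 30 for s in counts}
    return JunctionRecord(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        motif=motif,
        annotated=annotated,
        unique_by_sample=dict(counts),
        overhang_by_sample=dict(overhangs),
    )


def two_exon_gene(
    gene_id="GENE1",
    chrom="chrI",
    strand="+",
    exon1=(0, 100),
    intron=(100, 200),
    exon2=(200, 300),
    is_rp=False,
):
    """One gene, one transcript, one intron, in genomic coordinates."""
    exons = sorted([exon1, exon2])
    g = Gene(gene_id, chrom, strand, exons[0][0], exons[-1][1], is_rp=is_rp)
    t = Transcript(
        f"{gene_id}_t1",
        gene_id,
        chrom,
        strand,
        [Exon(chrom, s, e, strand) for s, e in exons],
    )
    assert exons[0][1] == intron[0] and exons[1][0] == intron[1]
    return g, t


@pytest.fixture
def simple_genome():
    """Plus-strand and minus-strand single-intron genes plus an
    intron-less gene, on one contig."""
    g1, t1 = two_exon_gene("GPLUS", strand="+", exon1=(0, 100),
                           intron=(100, 200), exon2=(200, 300))
    g2, t2 = two_exon_gene("GMINUS", strand="-", exon1=(1000, 1100),
                           intron=(1100, 1200), exon2=(1200, 1300))
    g3 = Gene("GNOINTRON", "chrI", "+", 2000, 2500)
    t3 = Transcript("GNOINTRON_t1", "GNOINTRON", "chrI", "+",
                    [Exon("chrI", 2000, 2500, "+")])
    return GenomeModel([g1, g2, g3], [t1, t2, t3])


@pytest.fixture
def skip_genome():
    """A two-intron (three-exon) gene for exon-skipping cases."""
    g = Gene("GSKIP", "chrI", "+", 0, 500)
    t = Transcript(
        "GSKIP_t1", "GSKIP", "chrI", "+",
        [Exon("chrI", 0, 100, "+"), Exon("chrI", 150, 250, "+"),
         Exon("chrI", 300, 500, "+")],
    )
    return GenomeModel([g], [t])
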