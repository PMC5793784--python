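"""Gene/transcript/intron models and GTF ingestion.

Coordinate conventions
----------------------
All *internal* coordinates are 0-based, half-open ``[start, end)``.
GTF input/output is 1-based, fully-closed; the conversion happens only at
the parse/write boundary.  An intron between exons ``(1..100)`` and
``(201..300)`` (1-based GTF) is represented internally as ``[100, 200)``.

The donor (5'SS) of an intron is the end nearer the transcript 5' end:
the low genomic boundary on the plus strand, the high boundary on minus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import gffutils

__all__ = [
    "Exon",
    "Intron",
    "Transcript",
    "Gene",
    "GenomeModel",
    "parse_gtf",
    "read_fasta",
]


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


@dataclass(frozen=True)
class Intron:
    """An intron derived from the gap between consecutive exons.

    ``index`` counts introns in transcript orientation (0 = nearest the
    transcript 5' end).  ``bp_pos`` is the genomic position of the branch
    adenosine when known (0-based), else None.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    index: int
    bp_pos: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def donor_boundary(self) -> int:
        """Genomic boundary coordinate of the 5'SS (half-open convention)."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor_boundary(self) -> int:
        return self.end if self.strand == "+" else self.start

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)  # sorted by start

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[Intron]:
        """Introns in genomic order; ``index`` is transcript-oriented."""
        out = []
        n_gaps = len(self.exons) - 1
        for i in range(n_gaps):
            gap_start = self.exons[i].end
            gap_end = self.exons[i + 1].start
            idx = i if self.strand == "+" else n_gaps - 1 - i
            out.append(
                Intron(
                    chrom=self.chrom,
                    start=gap_start,
                    end=gap_end,
                    strand=self.strand,
                    gene_id=self.gene_id,
                    transcript_id=self.id,
                    index=idx,
                )
            )
        return out


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    is_rp: bool = False
    has_introns: bool = False
    name: Optional[str] = None

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


class GenomeModel:
    """Container for genes, transcripts and derived introns.

    The annotated-junction set (intron coordinate keys) is the source of
    truth for deciding whether an observed splice junction is annotated.
    """

    def __init__(self, genes: Iterable[Gene], transcripts: Iterable[Transcript]):
        self.genes: dict[str, Gene] = {g.id: g for g in genes}
        self.transcripts: dict[str, Transcript] = {t.id: t for t in transcripts}
        self.introns: list[Intron] = []
        for t in self.transcripts.values():
            self.introns.extend(t.introns())
        self._introns_by_gene: dict[str, list[Intron]] = {}
        for iv in self.introns:
            self._introns_by_gene.setdefault(iv.gene_id, []).append(iv)
        for gid, g in self.genes.items():
            if gid in self._introns_by_gene:
                g.has_introns = True
        self._genes_by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._genes_by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._genes_by_chrom.values():
            glist.sort(key=lambda g: (g.start, g.id))
        self.annotated_junctions: set[tuple[str, int, int]] = {
            iv.key() for iv in self.introns
        }

    def gene_introns(self, gene_id: str) -> list[Intron]:
        return sorted(
            self._introns_by_gene.get(gene_id, []), key=lambda iv: iv.start
        )

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: Optional[str] = None
    ) -> list[Gene]:
        hits = []
        for g in self._genes_by_chrom.get(chrom, []):
            if g.start >= end:
                break
            if g.end <= start:
                continue
            if strand is not None and strand in "+-" and g.strand != strand:
                continue
            hits.append(g)
        return hits

    def set_branch_points(self, bp_by_intron: dict[tuple[str, int, int], int]) -> None:
        """Attach annotated branch-point positions (genomic, 0-based)."""
        new = []
        for iv in self.introns:
            bp = bp_by_intron.get(iv.key())
            new.append(
                Intron(
                    iv.chrom, iv.start, iv.end, iv.strand,
                    iv.gene_id, iv.transcript_id, iv.index, bp,
                )
                if bp is not None
                else iv
            )
        self.introns = new
        self._introns_by_gene = {}
        for iv in self.introns:
            self._introns_by_gene.setdefault(iv.gene_id, []).append(iv)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenomeModel({len(self.genes)} genes, "
            f"{len(self.transcripts)} transcripts, {len(self.introns)} introns)"
        )


def _flag(attrs, key: str) -> bool:
    vals = attrs.get(key, [])
    return bool(vals) and str(vals[0]).lower() in {"1", "true", "yes"}


def parse_gtf(path: str, gene_flags: Optional[dict[str, dict]] = None) -> GenomeModel:
    """Parse a GTF (1-based inclusive) into a :class:`GenomeModel`.

    Transcripts with overlapping exons are rejected with a warning;
    records with unknown strand are skipped.  Optional boolean gene
    attributes ``rp`` and (if present) explicit ``gene`` features supply
    the ribosomal-protein flag; ``gene_flags`` may override per gene id,
    e.g. ``{"YAL001C": {"is_rp": True}}``.
    """
    db = gffutils.create_db(
        path,
        ":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_meta: dict[str, dict] = {}
    for f in db.features_of_type("gene"):
        gid = f.attributes.get("gene_id", [f.id])[0]
        gene_meta[gid] = {
            "is_rp": _flag(f.attributes, "rp"),
            "name": f.attributes.get("gene_name", [None])[0],
        }

    exons_by_tx: dict[str, list] = {}
    tx_info: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    for f in db.features_of_type("exon"):
        if f.strand not in {"+", "-"}:
            warnings.warn(f"skipping exon with unknown strand: {f.id}")
            continue
        tid = f.attributes.get("transcript_id", [None])[0]
        gid = f.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            warnings.warn("skipping exon without transcript_id/gene_id")
            continue
        exons_by_tx.setdefault(tid, []).append(f)
        tx_info[tid] = (gid, f.seqid, f.strand)

    transcripts: list[Transcript] = []
    for tid, feats in exons_by_tx.items():
        gid, chrom, strand = tx_info[tid]
        exons = sorted(
            (Exon(chrom, f.start - 1, f.end, strand) for f in feats),
            key=lambda e: e.start,
        )
        ok = all(a.end <= b.start for a, b in zip(exons, exons[1:]))
        if not ok:
            warnings.warn(f"transcript {tid} has overlapping exons; rejected")
            continue
        transcripts.append(Transcript(tid, gid, chrom, strand, exons))

    genes: dict[str, Gene] = {}
    for t in transcripts:
        meta = gene_meta.get(t.gene_id, {})
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = Gene(
                id=t.gene_id,
                chrom=t.chrom,
                strand=t.strand,
                start=t.start,
                end=t.end,
                is_rp=bool(meta.get("is_rp", False)),
                name=meta.get("name"),
            )
        else:
            g.start = min(g.start, t.start)
            g.end = max(g.end, t.end)

    if gene_flags:
        for gid, flags in gene_flags.items():
            if gid in genes and "is_rp" in flags:
                genes[gid].is_rp = bool(flags["is_rp"])

    return GenomeModel(genes.values(), transcripts)


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file as a dict of upper-case sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
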