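"""Splice-junction evidence: SJ.out.tab I/O, filtering, event classification.

SJ.out.tab dialect (9 tab-separated columns, as emitted by STAR):

    1. chromosome
    2. first intron base (1-based)
    3. last intron base (1-based)
    4. strand code: 0 = undefined, 1 = +, 2 = -
    5. intron motif code: 0 = non-canonical, 1 = GT/AG, 2 = CT/AC,
       3 = GC/AG, 4 = CT/GC, 5 = AT/AC, 6 = GT/AT
    6. annotated flag: 0 = novel, 1 = annotated
    7. number of uniquely mapping reads crossing the junction
    8. number of multi-mapping reads (parsed, never used in statistics)
    9. maximum spliced alignment overhang

Internally junction coordinates are 0-based half-open: a row with columns
2-3 equal to 101/200 becomes ``[100, 200)``.

Event classes follow the transcript-oriented taxonomy: ``u3``/``d3`` are
alternative 3'SSs upstream/downstream of the annotated acceptor, ``u5``/
``d5`` alternative 5'SSs, plus cryptic introns and exon skipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .genome import GenomeModel, Gene, Intron

__all__ = [
    "JunctionRecord",
    "SpliceEvent",
    "parse_sj_tab",
    "write_sj_tab",
    "merge_samples",
    "filter_junctions",
    "classify_junction_event",
    "classify_junctions",
    "NOVEL_CLASSES",
    "DEFAULT_EXCLUDE_CONTIGS",
]

#: motif codes implying a strand (odd = +, even = -; 0 = unknown)
_MOTIF_STRAND = {1: "+", 2: "-", 3: "+", 4: "-", 5: "+", 6: "-"}

DEFAULT_EXCLUDE_CONTIGS = frozenset({"chrM", "Mito", "chrMito", "MT"})

NOVEL_CLASSES = (
    "alt5_up",
    "alt5_down",
    "alt3_up",
    "alt3_down",
    "cryptic_intron",
    "exon_skip",
)

_CLASS_PREFIX = {
    "alt5_up": "u5",
    "alt5_down": "d5",
    "alt3_up": "u3",
    "alt3_down": "d3",
    "cryptic_intron": "ci",
    "exon_skip": "es",
}


@dataclass
class JunctionRecord:
    """One observed splice junction, possibly merged across samples.

    ``unique_by_sample`` / ``overhang_by_sample`` map sample name to the
    unique-read count and max overhang seen in that sample.
    """

    chrom: str
    start: int  # 0-based half-open intron span
    end: int
    strand: str  # '+', '-' or '.' (undetermined)
    motif: int
    annotated: bool
    unique_by_sample: dict[str, int] = field(default_factory=dict)
    multi_by_sample: dict[str, int] = field(default_factory=dict)
    overhang_by_sample: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"junction start >= end: {self.start} >= {self.end}")

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def max_overhang(self) -> int:
        return max(self.overhang_by_sample.values(), default=0)

    def unique_total(self, samples: Optional[Iterable[str]] = None) -> int:
        if samples is None:
            return sum(self.unique_by_sample.values())
        return sum(self.unique_by_sample.get(s, 0) for s in samples)


def parse_sj_tab(path: str, sample: str = "sample") -> list[JunctionRecord]:
    """Parse one SJ.out.tab file; counts are keyed under ``sample``.

    Strand code 0 is resolved from the motif code when the motif is
    canonical, otherwise the strand is left undetermined ('.').
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                chrom = parts[0]
                start1, end1 = int(parts[1]), int(parts[2])
                strand_code = int(parts[3])
                motif = int(parts[4])
                annotated = bool(int(parts[5]))
                uniq, multi, overhang = (
                    int(parts[6]),
                    int(parts[7]),
                    int(parts[8]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            if strand_code == 1:
                strand = "+"
            elif strand_code == 2:
                strand = "-"
            else:
                strand = _MOTIF_STRAND.get(motif, ".")
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    motif=motif,
                    annotated=annotated,
                    unique_by_sample={sample: uniq},
                    multi_by_sample={sample: multi},
                    overhang_by_sample={sample: overhang},
                )
            )
    return records


def write_sj_tab(records: Sequence[JunctionRecord], path: str, sample: str) -> None:
    """Write one sample's counts in the SJ.out.tab dialect."""
    strand_code = {"+": 1, "-": 2, ".": 0}
    rows = sorted(records, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom,
                        r.start + 1,
                        r.end,
                        strand_code[r.strand],
                        r.motif,
                        int(r.annotated),
                        r.unique_by_sample.get(sample, 0),
                        r.multi_by_sample.get(sample, 0),
                        r.overhang_by_sample.get(sample, 0),
                    )
                )
                + "\n"
            )


def merge_samples(per_sample: dict[str, Sequence[JunctionRecord]]) -> list[JunctionRecord]:
    """Merge per-sample parses into one record per junction.

    The annotated flag is OR-ed; the motif/strand must agree (first
    occurrence wins; a junction absent from a sample simply has no entry
    for that sample, equivalent to a count of zero).
    """
    merged: dict[tuple[str, int, int], JunctionRecord] = {}
    for sample, records in per_sample.items():
        for r in records:
            m = merged.get(r.key())
            if m is None:
                m = JunctionRecord(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    strand=r.strand,
                    motif=r.motif,
                    annotated=r.annotated,
                )
                merged[r.key()] = m
            m.annotated = m.annotated or r.annotated
            m.unique_by_sample[sample] = r.unique_by_sample.get(sample, 0)
            m.multi_by_sample[sample] = r.multi_by_sample.get(sample, 0)
            m.overhang_by_sample[sample] = r.overhang_by_sample.get(sample, 0)
    return sorted(merged.values(), key=lambda r: (r.chrom, r.start, r.end))


def filter_junctions(
    records: Sequence[JunctionRecord],
    genome: Optional[GenomeModel] = None,
    min_reads: int = 5,
    overhang_annotated: int = 3,
    overhang_novel: int = 12,
    exclude_contigs: Iterable[str] = DEFAULT_EXCLUDE_CONTIGS,
) -> list[JunctionRecord]:
    """Apply the junction-level inclusion filters.

    A junction is kept iff all of:

    * unique reads >= ``min_reads`` in at least one sample;
    * max overhang >= ``overhang_annotated`` if the junction is annotated,
      or strictly > ``overhang_novel`` if novel;
    * its contig is not excluded (mitochondrial decoys by default).

    When a ``genome`` is given, the annotated flag is recomputed from the
    annotation rather than trusted from the aligner.
    """
    excl = set(exclude_contigs)
    kept = []
    for r in records:
        if r.chrom in excl:
            continue
        annotated = r.annotated
        if genome is not None:
            annotated = r.key() in genome.annotated_junctions
            r.annotated = annotated
        if not any(v >= min_reads for v in r.unique_by_sample.values()):
            continue
        if annotated:
            if r.max_overhang < overhang_annotated:
                continue
        else:
            if r.max_overhang <= overhang_novel:
                continue
        kept.append(r)
    return kept


@dataclass
class SpliceEvent:
    """A classified junction: annotated, a novel event, or unassigned.

    ``offset`` is the signed nt distance between the novel and annotated
    splice site in transcript orientation (positive = downstream, toward
    the transcript 3' end); the label encodes class and distance, e.g.
    ``u3-7`` for an alternative 3'SS 7 nt upstream of the annotated one.
    """

    event_id: str
    event_class: str  # one of NOVEL_CLASSES | 'annotated' | 'unassigned'
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: Optional[str] = None
    paired_intron: Optional[Intron] = None
    skip_second_intron: Optional[Intron] = None  # exon_skip only
    offset: Optional[int] = None
    label: str = ""
    host_has_introns: bool = False
    host_is_rp: bool = False

    @property
    def is_novel(self) -> bool:
        return self.event_class in NOVEL_CLASSES

    def junction_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def _assign_gene(junction: JunctionRecord, genome: GenomeModel) -> Optional[Gene]:
    """Host-gene assignment with deterministic tie-breaking.

    Preference order: a gene sharing a splice site with the junction,
    then the gene with the larger overlap, then lexicographic gene id.
    """
    hits = genome.genes_overlapping(
        junction.chrom, junction.start, junction.end, junction.strand
    )
    if not hits and junction.strand == ".":
        hits = genome.genes_overlapping(junction.chrom, junction.start, junction.end)
    if not hits:
        return None
    if len(hits) == 1:
        return hits[0]

    def shares_site(g: Gene) -> bool:
        for iv in genome.gene_introns(g.id):
            if iv.start == junction.start or iv.end == junction.end:
                return True
        return False

    sharing = sorted((g for g in hits if shares_site(g)), key=lambda g: g.id)
    if sharing:
        return sharing[0]
    return sorted(
        hits,
        key=lambda g: (-g.overlap(junction.start, junction.end), g.id),
    )[0]


def classify_junction_event(
    junction: JunctionRecord, genome: GenomeModel, event_id: str = ""
) -> SpliceEvent:
    """Classify one junction against the annotation.

    Returns a :class:`SpliceEvent` whose ``event_class`` is ``annotated``
    when both ends match an annotated intron, ``unassigned`` when no host
    gene overlaps, and one of :data:`NOVEL_CLASSES` otherwise.
    """
    gene = _assign_gene(junction, genome)
    base = dict(
        event_id=event_id,
        chrom=junction.chrom,
        start=junction.start,
        end=junction.end,
        strand=junction.strand,
    )
    if gene is None:
        return SpliceEvent(event_class="unassigned", **base)

    base["gene_id"] = gene.id
    base["host_has_introns"] = gene.has_introns
    base["host_is_rp"] = gene.is_rp
    strand = gene.strand if junction.strand == "." else junction.strand
    base["strand"] = strand
    s, e = junction.start, junction.end
    introns = genome.gene_introns(gene.id)

    if junction.key() in genome.annotated_junctions:
        return SpliceEvent(event_class="annotated", label="annotated", **base)

    # exon skipping: junction spans two genomically adjacent introns of
    # one transcript (exon1 donor joined to exon3 acceptor)
    for t in genome.transcripts_of_gene(gene.id):
        ivs = sorted(t.introns(), key=lambda iv: iv.start)
        for first, second in zip(ivs, ivs[1:]):
            if s == first.start and e == second.end:
                return SpliceEvent(
                    event_class="exon_skip",
                    paired_intron=first,
                    skip_second_intron=second,
                    label="es",
                    **base,
                )

    donor_matches = []  # annotated introns sharing the donor site
    acceptor_matches = []
    for iv in introns:
        if iv.strand != strand:
            continue
        same_donor = (s == iv.start) if strand == "+" else (e == iv.end)
        same_acceptor = (e == iv.end) if strand == "+" else (s == iv.start)
        if same_donor and not same_acceptor:
            donor_matches.append(iv)
        elif same_acceptor and not same_donor:
            acceptor_matches.append(iv)

    if donor_matches:
        # novel acceptor -> alternative 3'SS; offset in transcript frame
        iv = min(
            donor_matches,
            key=lambda iv: abs((e - iv.end) if strand == "+" else (iv.start - s)),
        )
        offset = (e - iv.end) if strand == "+" else (iv.start - s)
        cls = "alt3_down" if offset > 0 else "alt3_up"
        return SpliceEvent(
            event_class=cls,
            paired_intron=iv,
            offset=offset,
            label=f"{_CLASS_PREFIX[cls]}-{abs(offset)}",
            **base,
        )
    if acceptor_matches:
        iv = min(
            acceptor_matches,
            key=lambda iv: abs((s - iv.start) if strand == "+" else (iv.end - e)),
        )
        offset = (s - iv.start) if strand == "+" else (iv.end - e)
        cls = "alt5_down" if offset > 0 else "alt5_up"
        return SpliceEvent(
            event_class=cls,
            paired_intron=iv,
            offset=offset,
            label=f"{_CLASS_PREFIX[cls]}-{abs(offset)}",
            **base,
        )

    # shares neither end: cryptic intron (host_has_introns distinguishes
    # cryptic splicing inside intron-containing genes)
    return SpliceEvent(event_class="cryptic_intron", label="ci", **base)


def classify_junctions(
    records: Sequence[JunctionRecord], genome: GenomeModel
) -> list[SpliceEvent]:
    """Classify every junction; event ids are stable and coordinate-based."""
    events = []
    for r in records:
        eid = f"{r.chrom}:{r.start}-{r.end}"
        events.append(classify_junction_event(r, genome, event_id=eid))
    return events
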