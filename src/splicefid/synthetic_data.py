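"""Self-contained yeast-like test universe with known ground truth.

The generator lays out a small genome (single short introns carrying
5'SS ``GTATGT``, branch-point ``TACTAAC`` and 3'SS ``YAG`` consensus-like
motifs, preceded by a pyrimidine tract), plants one novel splicing event
per intron-containing gene plus optional cryptic introns in intron-less
genes, and draws junction read counts:

* annotated-junction reads ~ negative binomial around the gene abundance
  (dispersion configurable, 0 = Poisson);
* novel-junction reads ~ Binomial(annotated reads, true SEF x strain
  multiplier), independently per replicate.

Everything is deterministic under a fixed seed: two runs with the same
config produce byte-identical FASTA/GTF/SJ.out.tab/TSV/JSON outputs.
A mitochondrial decoy contig and low-count/short-overhang decoy
junctions are included by default to exercise the exclusion filters.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Exon, Gene, GenomeModel, Transcript
from .junctions import JunctionRecord, write_sj_tab
from .seqfeatures import revcomp

__all__ = [
    "SimulationConfig",
    "PlantedEvent",
    "GroundTruth",
    "SyntheticGenome",
    "make_genome",
    "simulate_junction_counts",
    "simulate_interval_reads",
    "simulate_all",
    "write_fasta",
    "write_gtf",
]

_MOTIF_5SS = "GTATGT"
_MOTIF_BP = "TACTAAC"  # branch adenosine = index 5
_TRACT_LEN = 14  # pyrimidine tract upstream of the 3'SS triplet
# minimum intron able to host 5'SS + spacer + BP + 10 nt BP->3'SS distance
_MIN_INTRON = 12 + len(_MOTIF_BP) + 10


@dataclass
class SimulationConfig:
    n_genes: int = 60
    frac_intron_containing: float = 0.5
    frac_rp: float = 0.5  # fraction of intron-containing genes flagged RP
    intron_length_range: tuple[int, int] = (60, 160)
    exon_length_range: tuple[int, int] = (120, 300)
    consensus_strength: float = 0.9
    base_sef_range: tuple[float, float] = (1e-3, 2e-2)
    strain_fold_changes: dict[str, float] = field(
        default_factory=lambda: {"WT": 1.0, "fast": 3.0, "slow": 2.0}
    )
    annotated_depth_range: tuple[float, float] = (2000.0, 20000.0)
    n_replicates: int = 2
    seed: int = 0
    dispersion: float = 0.1  # NB dispersion; 0 -> Poisson
    n_cryptic_intronless: int = 2
    n_exon_skip_genes: int = 0
    include_chrM: bool = True
    include_filter_decoys: bool = True
    # planted SEF structure (for recovery experiments):
    feature_linked_sef: bool = False  # SEF down in intron length & 3'SS quality
    abundance_linked_sef: bool = False  # SEF down in abundance
    sef_noise_sd: float = 0.25  # lognormal noise (log2 sd) on planted links

    def validate(self) -> None:
        for name in ("intron_length_range", "exon_length_range",
                     "base_sef_range", "annotated_depth_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low > high")
        for name in ("frac_intron_containing", "frac_rp", "consensus_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.intron_length_range[0] < _MIN_INTRON:
            raise ValueError(
                f"intron_length_range too small to host splice motifs "
                f"(minimum {_MIN_INTRON} nt)"
            )
        if any(m <= 0 for m in self.strain_fold_changes.values()):
            raise ValueError("strain fold changes must be positive")
        max_mult = max(self.strain_fold_changes.values())
        if self.base_sef_range[1] * max_mult >= 1.0:
            raise ValueError(
                "base SEF x strain multiplier reaches 1; reduce base_sef_range "
                "or the fold changes"
            )
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")

    @property
    def strains(self) -> list[str]:
        return list(self.strain_fold_changes)

    @property
    def samples(self) -> list[str]:
        return [
            f"{s}_{r}" for s in self.strains
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class PlantedEvent:
    event_id: str
    gene_id: str
    chrom: str
    start: int  # novel junction, 0-based half-open
    end: int
    strand: str
    event_class: str
    offset: Optional[int]
    label: str
    base_sef: float
    true_sef: dict[str, float]  # strain -> base_sef x multiplier


@dataclass
class GroundTruth:
    events: list[PlantedEvent]
    abundance: dict[str, float]  # gene -> expected depth
    bp_positions: dict[str, int]  # "chrom:start-end" intron key -> branch A pos
    coefficients: dict[str, float]

    def to_json(self, path: str) -> None:
        payload = {
            "events": [asdict(e) for e in self.events],
            "abundance": self.abundance,
            "bp_positions": self.bp_positions,
            "coefficients": self.coefficients,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            events=[PlantedEvent(**e) for e in payload["events"]],
            abundance=payload["abundance"],
            bp_positions=payload["bp_positions"],
            coefficients=payload["coefficients"],
        )


@dataclass
class _SimGene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]  # genomic, sorted
    intron: Optional[tuple[int, int]] = None
    intron2: Optional[tuple[int, int]] = None  # exon-skip genes only
    bp_pos: Optional[int] = None
    bp_pos2: Optional[int] = None
    is_rp: bool = False
    abundance: float = 0.0
    tract_quality: float = 0.5
    cryptic_span: Optional[tuple[int, int]] = None


@dataclass
class SyntheticGenome:
    config: SimulationConfig
    seqs: dict[str, str]
    genes: list[_SimGene]
    truth: GroundTruth

    def to_genome_model(self) -> GenomeModel:
        genes, transcripts = [], []
        for g in self.genes:
            genes.append(
                Gene(g.id, g.chrom, g.strand, g.start, g.end, is_rp=g.is_rp,
                     name=g.id)
            )
            exons = [Exon(g.chrom, s, e, g.strand) for s, e in g.exons]
            transcripts.append(
                Transcript(f"{g.id}_t1", g.id, g.chrom, g.strand, exons)
            )
        gm = GenomeModel(genes, transcripts)
        bp = {}
        for g in self.genes:
            if g.intron is not None and g.bp_pos is not None:
                bp[(g.chrom,) + g.intron] = g.bp_pos
            if g.intron2 is not None and g.bp_pos2 is not None:
                bp[(g.chrom,) + g.intron2] = g.bp_pos2
        gm.set_branch_points(bp)
        return gm


def _degenerate(motif: str, strength: float, rng: np.random.Generator,
                keep: Sequence[int] = ()) -> str:
    """Replace each motif base with a random one with prob 1 - strength."""
    out = []
    for i, b in enumerate(motif):
        if i in keep or rng.random() < strength:
            out.append(b)
        else:
            out.append("ACGT"[rng.integers(4)])
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _build_intron(length: int, cfg: SimulationConfig,
                  rng: np.random.Generator, quality: float) -> tuple[str, int]:
    """Intron sequence in transcript orientation; returns (seq, branch_A_idx).

    Layout: 5'SS motif, spacer, BP motif ending 10-45 nt before the 3'SS,
    pyrimidine tract whose per-position T probability scales with
    ``quality``, and a terminal YAG.
    """
    cs = cfg.consensus_strength
    d_max = min(45, length - 12 - len(_MOTIF_BP))
    d = int(rng.integers(10, d_max + 1))
    bp_end = length - d
    bp_start = bp_end - len(_MOTIF_BP)

    five = _degenerate(_MOTIF_5SS, cs, rng)
    bp = _degenerate(_MOTIF_BP, cs, rng, keep=(5,))  # branch A always kept
    spacer = _random_seq(bp_start - len(_MOTIF_5SS), rng)
    tail_len = d  # bp_end .. length
    yag = ("T" if rng.random() < 0.5 else "C") + "AG"
    yag = yag[0] + _degenerate("AG", cs, rng)
    tract_len = min(_TRACT_LEN, tail_len - 3)
    p_t = 0.25 + 0.75 * quality
    tract = "".join(
        ("T" if rng.random() < p_t else "ACG"[rng.integers(3)])
        for _ in range(tract_len)
    )
    mid = _random_seq(tail_len - 3 - tract_len, rng)
    seq = five + spacer + bp + mid + tract + yag
    assert len(seq) == length
    return seq, bp_start + 5


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome, annotation and planted ground truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    chrom = "chrI"
    spacer = 100

    n_ic = int(round(config.n_genes * config.frac_intron_containing))
    n_skip = min(config.n_exon_skip_genes, n_ic)
    ic_flags = np.zeros(config.n_genes, dtype=bool)
    ic_flags[:n_ic] = True
    rng.shuffle(ic_flags)
    ic_indices = [i for i in range(config.n_genes) if ic_flags[i]]
    skip_set = set(ic_indices[:n_skip])
    n_rp = int(round(len(ic_indices) * config.frac_rp))
    rp_set = set(rng.permutation(ic_indices)[:n_rp].tolist())
    il_lo, il_hi = config.intron_length_range
    ex_lo, ex_hi = config.exon_length_range

    intronless = [i for i in range(config.n_genes) if not ic_flags[i]]
    cryptic_set = set(intronless[: config.n_cryptic_intronless])

    parts: list[str] = []
    cursor = 0
    genes: list[_SimGene] = []
    bp_positions: dict[str, int] = {}

    def put(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    put(_random_seq(spacer, rng))
    for i in range(config.n_genes):
        gid = f"G{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        quality = float(rng.uniform(0.0, 1.0))
        two_introns = i in skip_set
        if ic_flags[i]:
            e1 = int(rng.integers(ex_lo, ex_hi + 1))
            e2 = int(rng.integers(ex_lo, ex_hi + 1))
            il = int(rng.integers(il_lo, il_hi + 1))
            iseq, bp_rel = _build_intron(il, config, rng, quality)
            tx_parts = [_random_seq(e1, rng), iseq, _random_seq(e2, rng)]
            if two_introns:
                il2 = int(rng.integers(il_lo, il_hi + 1))
                iseq2, bp_rel2 = _build_intron(il2, config, rng, quality)
                e3 = int(rng.integers(ex_lo, ex_hi + 1))
                tx_parts += [iseq2, _random_seq(e3, rng)]
            tx_seq = "".join(tx_parts)
            gseq = revcomp(tx_seq) if strand == "-" else tx_seq
            g0 = put(gseq)
            L = len(tx_seq)
            if strand == "+":
                exons = [(g0, g0 + e1), (g0 + e1 + il, g0 + e1 + il + e2)]
                intron = (g0 + e1, g0 + e1 + il)
                bp_pos = g0 + e1 + bp_rel
                if two_introns:
                    o = e1 + il + e2
                    intron2 = (g0 + o, g0 + o + il2)
                    exons.append((g0 + o + il2, g0 + L))
                    bp_pos2 = g0 + o + bp_rel2
            else:
                # transcript runs right-to-left on the genome
                exons = [
                    (g0 + L - e1 - il - e2, g0 + L - e1 - il),
                    (g0 + L - e1, g0 + L),
                ]
                intron = (g0 + L - e1 - il, g0 + L - e1)
                bp_pos = intron[1] - 1 - bp_rel
                if two_introns:
                    o = e1 + il + e2
                    intron2 = (g0 + L - o - il2, g0 + L - o)
                    exons.insert(0, (g0, g0 + L - o - il2))
                    bp_pos2 = intron2[1] - 1 - bp_rel2
                exons.sort()
            sg = _SimGene(
                id=gid, chrom=chrom, strand=strand, start=g0, end=g0 + L,
                exons=exons, intron=intron, bp_pos=bp_pos,
                is_rp=i in rp_set, tract_quality=quality,
            )
            if two_introns:
                sg.intron2, sg.bp_pos2 = intron2, bp_pos2
            genes.append(sg)
            bp_positions[f"{chrom}:{intron[0]}-{intron[1]}"] = bp_pos
            if two_introns:
                bp_positions[f"{chrom}:{intron2[0]}-{intron2[1]}"] = bp_pos2
        else:
            L = int(rng.integers(ex_lo + il_lo + 60, ex_hi + il_hi + 200))
            tx_seq = _random_seq(L, rng)
            cryptic_span = None
            if i in cryptic_set:
                il = int(rng.integers(il_lo, il_hi + 1))
                c0 = 30
                iseq, _ = _build_intron(il, config, rng, quality)
                tx_seq = tx_seq[:c0] + iseq + tx_seq[c0 + il:]
                if strand == "+":
                    cryptic_span = (0 + c0, c0 + il)  # offsets; fixed below
                else:
                    cryptic_span = (L - c0 - il, L - c0)
            gseq = revcomp(tx_seq) if strand == "-" else tx_seq
            g0 = put(gseq)
            if cryptic_span is not None:
                cryptic_span = (g0 + cryptic_span[0], g0 + cryptic_span[1])
            genes.append(
                _SimGene(
                    id=gid, chrom=chrom, strand=strand, start=g0, end=g0 + L,
                    exons=[(g0, g0 + L)], cryptic_span=cryptic_span,
                    tract_quality=quality,
                )
            )
        put(_random_seq(spacer, rng))

    seqs = {chrom: "".join(parts)}
    if config.include_chrM:
        seqs["chrM"] = _random_seq(600, rng)

    # abundance and planted SEFs
    dep_lo, dep_hi = config.annotated_depth_range
    for g in genes:
        g.abundance = _loguniform(rng, dep_lo, dep_hi)

    events, coefficients = _plant_events(genes, config, rng)
    truth = GroundTruth(
        events=events,
        abundance={g.id: g.abundance for g in genes},
        bp_positions=bp_positions,
        coefficients=coefficients,
    )
    return SyntheticGenome(config=config, seqs=seqs, genes=genes, truth=truth)


_ALT_CLASSES = ("alt5_up", "alt5_down", "alt3_up", "alt3_down")
_LABEL_PREFIX = {"alt5_up": "u5", "alt5_down": "d5",
                 "alt3_up": "u3", "alt3_down": "d3"}


def _novel_coords(g: _SimGene, cls: str, off: int) -> tuple[int, int]:
    S, E = g.intron
    plus = g.strand == "+"
    if cls == "alt3_up":
        return (S, E - off) if plus else (S + off, E)
    if cls == "alt3_down":
        return (S, E + off) if plus else (S - off, E)
    if cls == "alt5_up":
        return (S - off, E) if plus else (S, E + off)
    if cls == "alt5_down":
        return (S + off, E) if plus else (S, E - off)
    raise ValueError(cls)


def _plant_events(
    genes: list[_SimGene], cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[list[PlantedEvent], dict[str, float]]:
    sef_lo, sef_hi = cfg.base_sef_range
    geo_mid = math.sqrt(sef_lo * sef_hi)
    mean_len = np.mean([g.intron[1] - g.intron[0] for g in genes if g.intron]) \
        if any(g.intron for g in genes) else 0.0
    span = max(cfg.intron_length_range[1] - cfg.intron_length_range[0], 1)
    dep_lo, dep_hi = cfg.annotated_depth_range
    log_mid_dep = 0.5 * (np.log(dep_lo) + np.log(dep_hi)) if dep_lo > 0 else 0.0

    coeff = {
        "c_length": -1.2,  # log2 SEF per normalized intron length
        "c_tract": -2.5,  # log2 SEF per unit 3'SS tract quality (0..1)
        "c_abundance": -0.8,  # log2 SEF per natural-log depth unit
        "noise_sd": cfg.sef_noise_sd,
    }

    def base_sef(g: _SimGene, intron: Optional[tuple[int, int]]) -> float:
        if cfg.feature_linked_sef and intron is not None:
            il = intron[1] - intron[0]
            x = (
                np.log2(geo_mid)
                + coeff["c_length"] * (il - mean_len) / span * 4.0
                + coeff["c_tract"] * (g.tract_quality - 0.5) * 2.0
                + rng.normal(0.0, coeff["noise_sd"])
            )
            return float(np.clip(2.0 ** x, sef_lo / 4, sef_hi * 4))
        if cfg.abundance_linked_sef:
            x = (
                np.log2(geo_mid)
                + coeff["c_abundance"] * (np.log(g.abundance) - log_mid_dep)
                + rng.normal(0.0, coeff["noise_sd"])
            )
            return float(np.clip(2.0 ** x, sef_lo / 4, sef_hi * 4))
        return _loguniform(rng, sef_lo, sef_hi)

    max_mult = max(cfg.strain_fold_changes.values())
    events: list[PlantedEvent] = []
    for g in genes:
        if g.intron is not None and g.intron2 is None:
            cls = _ALT_CLASSES[rng.integers(len(_ALT_CLASSES))]
            off = int(rng.integers(3, 21))
            if cls == "alt3_up" or cls == "alt5_down":
                # keep the shortened intron clear of the BP region
                S, E = g.intron
                bp_rel_5 = (g.bp_pos - S) if g.strand == "+" else (E - 1 - g.bp_pos)
                il = E - S
                room = (il - bp_rel_5 - 11) if cls == "alt3_up" else (bp_rel_5 - 9)
                off = int(rng.integers(3, max(4, min(21, room))))
            s, e = _novel_coords(g, cls, off)
            sef = base_sef(g, g.intron)
            sef = min(sef, 0.9 / max_mult)
            events.append(
                PlantedEvent(
                    event_id=f"{g.chrom}:{s}-{e}",
                    gene_id=g.id, chrom=g.chrom, start=s, end=e,
                    strand=g.strand, event_class=cls, offset=off,
                    label=f"{_LABEL_PREFIX[cls]}-{off}",
                    base_sef=sef,
                    true_sef={
                        st: sef * m for st, m in cfg.strain_fold_changes.items()
                    },
                )
            )
        elif g.intron2 is not None:
            s = min(g.intron[0], g.intron2[0])
            e = max(g.intron[1], g.intron2[1])
            sef = min(base_sef(g, g.intron), 0.9 / max_mult)
            events.append(
                PlantedEvent(
                    event_id=f"{g.chrom}:{s}-{e}",
                    gene_id=g.id, chrom=g.chrom, start=s, end=e,
                    strand=g.strand, event_class="exon_skip", offset=None,
                    label="es", base_sef=sef,
                    true_sef={
                        st: sef * m for st, m in cfg.strain_fold_changes.items()
                    },
                )
            )
        elif g.cryptic_span is not None:
            s, e = g.cryptic_span
            sef = min(base_sef(g, None), 0.9 / max_mult)
            events.append(
                PlantedEvent(
                    event_id=f"{g.chrom}:{s}-{e}",
                    gene_id=g.id, chrom=g.chrom, start=s, end=e,
                    strand=g.strand, event_class="cryptic_intron", offset=None,
                    label="ci", base_sef=sef,
                    true_sef={
                        st: sef * m for st, m in cfg.strain_fold_changes.items()
                    },
                )
            )
    return events, coeff


_MOTIF_CODE = {
    ("GT", "AG"): 1, ("CT", "AC"): 2, ("GC", "AG"): 3,
    ("CT", "GC"): 4, ("AT", "AC"): 5, ("GT", "AT"): 6,
}


def _motif_code(seqs: dict[str, str], chrom: str, start: int, end: int) -> int:
    donor = seqs[chrom][start: start + 2]
    acceptor = seqs[chrom][end - 2: end]
    return _MOTIF_CODE.get((donor, acceptor), 0)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def simulate_junction_counts(
    sg: SyntheticGenome,
) -> tuple[dict[str, list[JunctionRecord]], pd.DataFrame, dict[str, float]]:
    """Draw per-sample junction tables, gene read counts and library sizes.

    Returns ``(per_sample_records, gene_counts, total_mapped)``; gene
    counts (index gene, one column per sample) feed RPKM for cryptic
    events.  Junctions with zero unique reads in a sample are absent
    from that sample's table, as an aligner would report.
    """
    cfg = sg.config
    rng = np.random.default_rng([cfg.seed, 1])
    seqs = sg.seqs
    truth_by_gene: dict[str, list[PlantedEvent]] = {}
    for ev in sg.truth.events:
        truth_by_gene.setdefault(ev.gene_id, []).append(ev)

    per_sample: dict[str, list[JunctionRecord]] = {s: [] for s in cfg.samples}
    gene_counts = pd.DataFrame(
        0, index=[g.id for g in sg.genes], columns=cfg.samples, dtype=int
    )

    def add(sample: str, chrom: str, s: int, e: int, strand: str,
            annotated: bool, uniq: int, overhang: int) -> None:
        if uniq <= 0:
            return
        per_sample[sample].append(
            JunctionRecord(
                chrom=chrom, start=s, end=e, strand=strand,
                motif=_motif_code(seqs, chrom, s, e), annotated=annotated,
                unique_by_sample={sample: uniq},
                multi_by_sample={sample: int(rng.integers(0, 5))},
                overhang_by_sample={sample: overhang},
            )
        )

    for g in sg.genes:
        planted = truth_by_gene.get(g.id, [])
        for strain, mult in cfg.strain_fold_changes.items():
            for rep in range(1, cfg.n_replicates + 1):
                sample = f"{strain}_{rep}"
                gene_reads = _nb_draw(rng, g.abundance, cfg.dispersion)
                gene_counts.loc[g.id, sample] = gene_reads
                if g.intron is not None:
                    annot = _nb_draw(rng, g.abundance, cfg.dispersion)
                    oh = int(rng.integers(20, 41))
                    add(sample, g.chrom, *g.intron, g.strand, True, annot, oh)
                    annot2 = 0
                    if g.intron2 is not None:
                        annot2 = _nb_draw(rng, g.abundance, cfg.dispersion)
                        oh = int(rng.integers(20, 41))
                        add(sample, g.chrom, *g.intron2, g.strand, True, annot2, oh)
                    for ev in planted:
                        p = min(ev.true_sef[strain], 0.999)
                        base = annot if ev.event_class != "exon_skip" else annot
                        novel = int(rng.binomial(base, p)) if base > 0 else 0
                        oh = int(rng.integers(13, 41))
                        add(sample, ev.chrom, ev.start, ev.end, ev.strand,
                            False, novel, oh)
                else:
                    for ev in planted:
                        p = min(ev.true_sef[strain], 0.999)
                        novel = (
                            int(rng.binomial(gene_reads, p))
                            if gene_reads > 0 else 0
                        )
                        oh = int(rng.integers(13, 41))
                        add(sample, ev.chrom, ev.start, ev.end, ev.strand,
                            False, novel, oh)

    if cfg.include_chrM and "chrM" in seqs:
        for sample in cfg.samples:
            add(sample, "chrM", 100, 200, "+", False,
                int(rng.integers(20, 80)), 25)

    if cfg.include_filter_decoys:
        host = next((g for g in sg.genes if g.intron is not None), None)
        if host is not None:
            S, E = host.intron
            low = (S, E + 31) if host.strand == "+" else (S - 31, E)
            shallow = (S, E + 37) if host.strand == "+" else (S - 37, E)
            for sample in cfg.samples:
                # never reaches 5 reads in any sample
                add(sample, host.chrom, *low, host.strand, False,
                    int(rng.integers(1, 5)), 30)
                # plenty of reads but novel overhang <= 12
                add(sample, host.chrom, *shallow, host.strand, False,
                    int(rng.integers(20, 60)), 10)

    total_mapped = {
        s: float(gene_counts[s].sum()) for s in cfg.samples
    }
    return per_sample, gene_counts, total_mapped


_READ_LEN = 50


def simulate_interval_reads(
    sg: SyntheticGenome,
    n_reads: int = 1000,
    class_mix: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Labelled read-interval table over the intron-containing genes.

    ``class_mix`` gives the requested proportions of
    {junction, boundary, intron, exonic} reads (default: equal parts).
    Blocks are 0-based half-open, encoded ``start-end`` joined by ';'.
    """
    cfg = sg.config
    rng = np.random.default_rng([cfg.seed, 2])
    if class_mix is None:
        class_mix = {"junction": 0.25, "boundary": 0.25,
                     "intron": 0.25, "exonic": 0.25}
    total = sum(class_mix.values())
    if total <= 0:
        raise ValueError("class mix must have positive mass")
    hosts = [g for g in sg.genes if g.intron is not None]
    if not hosts:
        raise ValueError("genome has no introns")

    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes]) / total
    rows = []
    for i in range(n_reads):
        cls = classes[rng.choice(len(classes), p=probs)]
        g = hosts[rng.integers(len(hosts))]
        S, E = g.intron
        il = E - S
        exon_low = min(g.exons, key=lambda x: x[0])
        if cls == "junction":
            a = int(rng.integers(10, _READ_LEN - 9))
            blocks = [(S - a, S), (E, E + (_READ_LEN - a))]
        elif cls == "boundary":
            a = int(rng.integers(max(5, _READ_LEN - il + 1), _READ_LEN - 4))
            blocks = [(S - a, S - a + _READ_LEN)]
        elif cls == "intron":
            rl = min(_READ_LEN, il - 2)
            off = int(rng.integers(1, il - rl)) if il - rl > 1 else 1
            blocks = [(S + off, S + off + rl)]
        elif cls == "exonic":
            xs, xe = exon_low
            off = int(rng.integers(0, max(1, xe - xs - _READ_LEN)))
            blocks = [(xs + off, min(xs + off + _READ_LEN, xe))]
        else:
            raise ValueError(f"unknown read class: {cls}")
        rows.append(
            {
                "read_id": f"r{i:06d}",
                "chrom": g.chrom,
                "blocks": ";".join(f"{s}-{e}" for s, e in blocks),
                "strand": g.strand,
                "gene": g.id,
                "true_class": cls,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers

def write_fasta(seqs: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i: i + width] + "\n")


def write_gtf(sg: SyntheticGenome, path: str) -> None:
    """GTF (1-based inclusive) with gene/transcript/exon features.

    Gene lines carry a boolean ``rp`` attribute consumed by the parser.
    """
    src = "splicefid_sim"
    with open(path, "w") as fh:
        for g in sg.genes:
            attrs = (
                f'gene_id "{g.id}"; gene_name "{g.id}"; '
                f'rp "{int(g.is_rp)}";'
            )
            fh.write(
                "\t".join(
                    [g.chrom, src, "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                ) + "\n"
            )
            tid = f"{g.id}_t1"
            tattrs = f'gene_id "{g.id}"; transcript_id "{tid}";'
            fh.write(
                "\t".join(
                    [g.chrom, src, "transcript", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", tattrs]
                ) + "\n"
            )
            for s, e in g.exons:
                fh.write(
                    "\t".join(
                        [g.chrom, src, "exon", str(s + 1), str(e),
                         ".", g.strand, ".", tattrs]
                    ) + "\n"
                )


def simulate_all(config: SimulationConfig, outdir: str) -> dict[str, str]:
    """Run the full generator and write every artifact to ``outdir``.

    Returns a dict of output paths (fasta, gtf, truth, per-sample
    SJ tables, gene counts, interval reads).
    """
    os.makedirs(outdir, exist_ok=True)
    sg = make_genome(config)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "gtf": os.path.join(outdir, "annotation.gtf"),
        "truth": os.path.join(outdir, "ground_truth.json"),
        "gene_counts": os.path.join(outdir, "gene_counts.tsv"),
        "interval_reads": os.path.join(outdir, "interval_reads.tsv"),
    }
    write_fasta(sg.seqs, paths["fasta"])
    write_gtf(sg, paths["gtf"])
    sg.truth.to_json(paths["truth"])
    per_sample, gene_counts, total_mapped = simulate_junction_counts(sg)
    for sample, records in per_sample.items():
        p = os.path.join(outdir, f"{sample}.SJ.out.tab")
        write_sj_tab(records, p, sample)
        paths[f"sj_{sample}"] = p
    gene_counts.to_csv(paths["gene_counts"], sep="\t")
    with open(os.path.join(outdir, "total_mapped.json"), "w") as fh:
        json.dump(total_mapped, fh, indent=1, sort_keys=True)
    paths["total_mapped"] = os.path.join(outdir, "total_mapped.json")
    reads = simulate_interval_reads(sg)
    reads.to_csv(paths["interval_reads"], sep="\t", index=False)
    return paths
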