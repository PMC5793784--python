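"""End-to-end orchestration: simulate/load -> classify -> SEF -> contrasts
-> features -> model, with a config echo and per-stage funnel logging."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import differential, predictor, sef_quant, seqfeatures
from .genome import GenomeModel, parse_gtf, read_fasta
from .junctions import (
    DEFAULT_EXCLUDE_CONTIGS,
    classify_junctions,
    filter_junctions,
    merge_samples,
    parse_sj_tab,
)
from .synthetic_data import SimulationConfig, make_genome, simulate_junction_counts

log = logging.getLogger("splicefid")

__all__ = ["RunConfig", "run", "report", "count_read_classes"]


@dataclass
class RunConfig:
    """Run parameters; defaults are min 5 supporting reads,
    Fisher P < 0.01 and FDR < 0.03."""

    outdir: str = "splicefid_run"
    seed: int = 0
    # either simulate...
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # ...or load real inputs
    gtf: Optional[str] = None
    fasta: Optional[str] = None
    sj_tabs: dict[str, str] = field(default_factory=dict)  # sample -> path
    gene_counts: Optional[str] = None
    total_mapped: Optional[str] = None
    # thresholds
    min_reads: int = 5
    overhang_annotated: int = 3
    overhang_novel: int = 12
    p_cut: float = 0.01
    q_cut: float = 0.03
    exclude_contigs: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDE_CONTIGS))
    wt_strain: str = "WT"
    fit_model: bool = True
    model_trees: int = 500

    def echo(self) -> dict:
        d = asdict(self)
        return d


def _strains_from_samples(samples: Sequence[str], wt: str) -> list[str]:
    seen = []
    for s in samples:
        st = s.rsplit("_", 1)[0]
        if st not in seen:
            seen.append(st)
    if wt in seen:
        seen.remove(wt)
        seen.insert(0, wt)
    return seen


def run(config: RunConfig) -> str:
    """Execute the pipeline; returns the run directory.

    Deterministic under a fixed seed: every emitted file is byte
    identical across runs with the same config.
    """
    os.makedirs(config.outdir, exist_ok=True)
    with open(os.path.join(config.outdir, "config_echo.json"), "w") as fh:
        json.dump(config.echo(), fh, indent=1, sort_keys=True, default=str)

    if config.simulate:
        sim_cfg = config.sim
        sim_cfg.seed = config.seed
        sg = make_genome(sim_cfg)
        genome = sg.to_genome_model()
        seqs = sg.seqs
        per_sample, gene_counts, total_mapped = simulate_junction_counts(sg)
        samples = sim_cfg.samples
        sg.truth.to_json(os.path.join(config.outdir, "ground_truth.json"))
    else:
        if not (config.gtf and config.fasta and config.sj_tabs):
            raise ValueError(
                "non-simulation runs need gtf, fasta and sj_tabs inputs"
            )
        genome = parse_gtf(config.gtf)
        seqs = read_fasta(config.fasta)
        samples = list(config.sj_tabs)
        per_sample = {
            s: parse_sj_tab(path, sample=s) for s, path in config.sj_tabs.items()
        }
        gene_counts = (
            pd.read_csv(config.gene_counts, sep="\t", index_col=0)
            if config.gene_counts else None
        )
        total_mapped = None
        if config.total_mapped:
            with open(config.total_mapped) as fh:
                total_mapped = json.load(fh)

    strains = _strains_from_samples(samples, config.wt_strain)
    merged = merge_samples(per_sample)
    log.info("junctions observed: %d", len(merged))
    kept = filter_junctions(
        merged,
        genome,
        min_reads=config.min_reads,
        overhang_annotated=config.overhang_annotated,
        overhang_novel=config.overhang_novel,
        exclude_contigs=config.exclude_contigs,
    )
    log.info("junctions after filters: %d", len(kept))

    events = classify_junctions(kept, genome)
    novel = [e for e in events if e.is_novel]
    unassigned = [e for e in events if e.event_class == "unassigned"]
    log.info(
        "events: %d novel, %d annotated, %d unassigned",
        len(novel), sum(e.event_class == "annotated" for e in events),
        len(unassigned),
    )

    catalogue = pd.DataFrame(
        {
            "event_id": e.event_id,
            "gene": e.gene_id,
            "class": e.event_class,
            "label": e.label,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "strand": e.strand,
            "offset": e.offset,
            "is_rp": e.host_is_rp,
            "host_has_introns": e.host_has_introns,
        }
        for e in events
    )
    catalogue.to_csv(
        os.path.join(config.outdir, "event_catalogue.tsv"), sep="\t", index=False
    )

    by_key = {r.key(): r for r in kept}
    sef = sef_quant.sef_table(
        novel, by_key, genome, strains, samples,
        gene_counts=gene_counts, total_mapped=total_mapped,
        strict_min_reads=config.min_reads,
    )
    sef.to_csv(os.path.join(config.outdir, "sef_table.tsv"), sep="\t", index=False)

    contrasts = differential.contrast_events(
        sef, wt_strain=config.wt_strain, p_cut=config.p_cut, q_cut=config.q_cut
    )
    contrasts.to_csv(
        os.path.join(config.outdir, "contrasts.tsv"), sep="\t", index=False
    )
    strata = differential.stratify(contrasts)
    strata.to_csv(os.path.join(config.outdir, "strata.tsv"), sep="\t", index=False)

    # SEF-vs-abundance correlation (annotated junction reads as abundance)
    corr = _sef_abundance_correlation(sef, config.wt_strain)

    model_summary = None
    if config.fit_model and not sef.empty:
        fm, targets = _model_inputs(novel, genome, seqs, sef)
        if len(targets) >= 3 and np.std(targets) > 0:
            fm.to_csv(os.path.join(config.outdir, "feature_matrix.tsv"), sep="\t")
            rep = predictor.fit_cv(
                fm, targets, folds=3, seed=config.seed,
                n_estimators=config.model_trees,
            )
            rep.predictions.to_csv(
                os.path.join(config.outdir, "oof_predictions.tsv"), sep="\t"
            )
            model_summary = {
                "n_events": rep.n_events,
                "pearson_pooled": rep.pearson_pooled,
                "pearson_per_fold": rep.pearson_per_fold,
                "hyperparams": rep.hyperparams,
                "top_importances": rep.importances_ranked().head(10).to_dict(),
            }

    summary = {
        "n_junctions_observed": len(merged),
        "n_junctions_filtered": len(kept),
        "n_novel_events": len(novel),
        "n_unassigned": len(unassigned),
        "events_by_class": catalogue[catalogue["class"].isin(
            [e.event_class for e in novel] or ["-"]
        )]["class"].value_counts().to_dict() if novel else {},
        "strata": strata.to_dict(orient="records"),
        "sef_abundance_pearson": corr,
        "model": model_summary,
        "thresholds": {
            "min_reads": config.min_reads,
            "p_cut": config.p_cut,
            "q_cut": config.q_cut,
            "overhang_annotated": config.overhang_annotated,
            "overhang_novel": config.overhang_novel,
        },
        "seed": config.seed,
    }
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    return config.outdir


def _sef_abundance_correlation(sef: pd.DataFrame, wt: str) -> Optional[float]:
    """Pearson R of log2 abundance vs log2 SEF over defined WT events."""
    w = sef[(sef["strain"] == wt) & sef["defined"] & (sef["sef"] > 0)]
    w = w[w["denominator"] > 0]
    if len(w) < 3:
        return None
    r = predictor.pearson_r(
        np.log2(w["denominator"].astype(float)), np.log2(w["sef"].astype(float))
    )
    return r


def _model_inputs(novel, genome, seqs, sef):
    """Feature matrix + log2 mean-SEF targets for strict-filter events."""
    ok = sef[sef["passes_strict_filter"] & sef["defined"] & (sef["sef"] > 0)]
    mean_sef = ok.groupby("event_id")["sef"].mean()
    mean_sef = mean_sef[mean_sef > 0]
    keep = [e for e in novel if e.event_id in mean_sef.index]
    fm = seqfeatures.build_feature_matrix(keep, genome, seqs)
    fm = fm.loc[[e.event_id for e in keep]]
    targets = np.log2(mean_sef.loc[fm.index].to_numpy(dtype=float))
    return fm, targets


def count_read_classes(
    reads: pd.DataFrame, genome: GenomeModel
) -> pd.DataFrame:
    """Classify an interval-read table and summarize per gene.

    ``reads`` columns: read_id, chrom, blocks ('s-e;s-e', 0-based
    half-open), strand, gene.  Output has one row per gene with class
    counts and the pre-mRNA fraction (NaN when undefined).
    """
    counts: dict[str, sef_quant.ReadClassCounts] = {}
    per_read = []
    for row in reads.itertuples(index=False):
        blocks = [
            tuple(int(x) for x in b.split("-")) for b in row.blocks.split(";")
        ]
        gid = row.gene
        txs = genome.transcripts_of_gene(gid)
        cls = sef_quant.classify_read(blocks, txs[0]) if txs else "ambiguous"
        per_read.append(cls)
        c = counts.setdefault(gid, sef_quant.ReadClassCounts(gid))
        if cls in ("boundary", "intron", "junction", "exonic"):
            setattr(c, cls, getattr(c, cls) + 1)
    reads = reads.assign(predicted_class=per_read)
    rows = []
    for gid, c in sorted(counts.items()):
        frac = sef_quant.premrna_fraction(c)
        rows.append(
            {
                "gene": gid,
                "boundary": c.boundary,
                "intron": c.intron,
                "junction": c.junction,
                "exonic": c.exonic,
                "premrna_fraction": float("nan") if frac is None else frac,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["per_read"] = reads
    return out


def report(run_dir: str) -> str:
    """Human-readable summary of a completed (or partial) run."""
    lines = []
    summary_path = os.path.join(run_dir, "summary.json")
    if not os.path.exists(summary_path):
        return f"run directory {run_dir}: no summary.json (incomplete run)"
    with open(summary_path) as fh:
        s = json.load(fh)
    lines.append(f"splicefid run: {run_dir}")
    lines.append(
        f"junctions: {s['n_junctions_observed']} observed, "
        f"{s['n_junctions_filtered']} after filters"
    )
    n_novel = s["n_novel_events"]
    lines.append(f"novel events: {n_novel}")
    if n_novel == 0:
        lines.append("zero novel events detected")
    for cls, n in sorted(s.get("events_by_class", {}).items()):
        lines.append(f"  {cls}: {n}")
    for row in s.get("strata", []):
        ratio = row["ratio_reduced_increased"]
        ratio_s = "undefined" if ratio in (None, "nan") or (
            isinstance(ratio, float) and np.isnan(ratio)
        ) else f"{ratio:.2f}"
        lines.append(
            f"{row['contrast']} [{row['stratum']}]: "
            f"{row['reduced']} reduced / {row['increased']} increased "
            f"fidelity (ratio {ratio_s})"
        )
    corr = s.get("sef_abundance_pearson")
    if corr is not None:
        lines.append(f"SEF vs abundance Pearson R: {corr:.3f}")
    model = s.get("model")
    if model:
        lines.append(
            f"SEF predictor: pooled out-of-fold Pearson R = "
            f"{model['pearson_pooled']:.3f} over {model['n_events']} events"
        )
    return "\n".join(lines)
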