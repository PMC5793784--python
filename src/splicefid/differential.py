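"""Mutant-vs-WT differential splicing fidelity.

For each novel event and each mutant strain, a 2x2 table of
(novel, annotated) x (mutant, WT) pooled replicate counts is tested with
a two-sided Fisher's exact test; q-values come from the
Benjamini-Hochberg step-up.  An event is called at the default
thresholds P < 0.01 and q < 0.03; direction is ``reduced_fidelity``
when the mutant SEF exceeds WT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ContrastResult",
    "fisher_exact_2x2",
    "bh_fdr",
    "call_direction",
    "contrast_events",
    "stratify",
]

# relative slack when summing hypergeometric probabilities <= observed,
# guarding against float ties (the usual two-sided convention)
_TIE_SLACK = 1e-7


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact P for a 2x2 contingency table.

    The P-value is the sum of hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's (minimum-likelihood two-sided convention).  An empty
    margin gives P = 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be nonnegative integers")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    k = np.arange(lo, hi + 1)
    # log C(r1,k) + log C(r2,c1-k) - log C(n,c1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logp)
    observed = pmf[a - lo]
    p = float(pmf[pmf <= observed * (1.0 + _TIE_SLACK)].sum())
    return min(p, 1.0)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j)``,
    clipped to [0, 1]; monotone nondecreasing in sorted-p order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ContrastResult:
    event_id: str
    contrast: str  # e.g. "fast_vs_WT"
    table: tuple[int, int, int, int]  # novel_mut, annot_mut, novel_wt, annot_wt
    p: float
    q: float = float("nan")
    sef_mutant: Optional[float] = None
    sef_wt: Optional[float] = None
    log2_ratio: float = float("nan")
    direction: str = "ns"
    flags: list[str] = field(default_factory=list)


def call_direction(
    result: ContrastResult, p_cut: float = 0.01, q_cut: float = 0.03
) -> str:
    """Direction call: significance gate then sign of the SEF ratio.

    Zero-SEF sides fall back to a direct novel-count comparison so a
    significant 0-vs-something contrast still gets a direction.
    """
    if result.sef_mutant is None and result.sef_wt is None:
        result.flags.append("both_sef_undefined")
        return "ns"
    if not (result.p < p_cut and result.q < q_cut):
        return "ns"
    sm = result.sef_mutant if result.sef_mutant is not None else 0.0
    sw = result.sef_wt if result.sef_wt is not None else 0.0
    if sm > sw:
        return "reduced_fidelity"
    if sm < sw:
        return "increased_fidelity"
    nm, _, nw, _ = result.table
    if nm != nw:
        return "reduced_fidelity" if nm > nw else "increased_fidelity"
    return "ns"


def contrast_events(
    sef: pd.DataFrame,
    wt_strain: str = "WT",
    mutants: Optional[Sequence[str]] = None,
    p_cut: float = 0.01,
    q_cut: float = 0.03,
    strict_only: bool = True,
) -> pd.DataFrame:
    """Fisher contrasts of every event's mutant vs WT counts.

    ``sef`` is the per-event-per-strain table from
    :func:`splicefid.sef_quant.sef_table`.  BH correction is applied
    within each contrast across events.  Cryptic (RPKM-denominator)
    events are tested on novel counts vs rounded denominator reads only
    when an integer annotated count exists; otherwise they are skipped
    with a flag column entry.
    """
    out_columns = [
        "event_id", "contrast", "novel_mut", "annot_mut", "novel_wt",
        "annot_wt", "p", "q", "log2_ratio", "direction", "gene", "class",
        "is_rp",
    ]
    if sef.empty:
        return pd.DataFrame(columns=out_columns)
    df = sef.copy()
    if strict_only:
        df = df[df["passes_strict_filter"]]
    if mutants is None:
        mutants = [s for s in df["strain"].unique() if s != wt_strain]

    all_rows = []
    for mutant in mutants:
        rows = []
        for event_id, g in df.groupby("event_id", sort=True):
            gm = g[g["strain"] == mutant]
            gw = g[g["strain"] == wt_strain]
            if gm.empty or gw.empty:
                continue
            gm, gw = gm.iloc[0], gw.iloc[0]
            if gm["annotated"] is None or gw["annotated"] is None or (
                pd.isna(gm["annotated"]) or pd.isna(gw["annotated"])
            ):
                continue  # no integer denominator (cryptic/RPKM event)
            tbl = (
                int(gm["novel"]), int(gm["annotated"]),
                int(gw["novel"]), int(gw["annotated"]),
            )
            p = fisher_exact_2x2([[tbl[0], tbl[1]], [tbl[2], tbl[3]]])
            sef_m = gm["sef"] if gm["defined"] else None
            sef_w = gw["sef"] if gw["defined"] else None
            if sef_m and sef_w:
                log2_ratio = float(np.log2(sef_m / sef_w))
            else:
                log2_ratio = float("nan")
            rows.append(
                ContrastResult(
                    event_id=event_id,
                    contrast=f"{mutant}_vs_{wt_strain}",
                    table=tbl,
                    p=p,
                    sef_mutant=sef_m,
                    sef_wt=sef_w,
                    log2_ratio=log2_ratio,
                )
            )
        if not rows:
            continue
        q = bh_fdr([r.p for r in rows])
        for r, qv in zip(rows, q):
            r.q = float(qv)
            r.direction = call_direction(r, p_cut=p_cut, q_cut=q_cut)
        all_rows.extend(rows)

    if not all_rows:
        return pd.DataFrame(columns=out_columns)
    meta = sef.drop_duplicates("event_id").set_index("event_id")
    return pd.DataFrame(
        {
            "event_id": r.event_id,
            "contrast": r.contrast,
            "novel_mut": r.table[0],
            "annot_mut": r.table[1],
            "novel_wt": r.table[2],
            "annot_wt": r.table[3],
            "p": r.p,
            "q": r.q,
            "log2_ratio": r.log2_ratio,
            "direction": r.direction,
            "gene": meta.loc[r.event_id, "gene"],
            "class": meta.loc[r.event_id, "class"],
            "is_rp": bool(meta.loc[r.event_id, "is_rp"]),
        }
        for r in all_rows
    )


def stratify(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Direction counts and reduced:increased ratios per RP stratum.

    One row per (contrast, stratum); the ratio is NaN (flagged) when a
    stratum has no increased-fidelity events.
    """
    rows = []
    if contrasts.empty:
        return pd.DataFrame(
            columns=[
                "contrast", "stratum", "n_events", "reduced", "increased",
                "ns", "ratio_reduced_increased",
            ]
        )
    for (contrast, is_rp), g in contrasts.groupby(["contrast", "is_rp"]):
        reduced = int((g["direction"] == "reduced_fidelity").sum())
        increased = int((g["direction"] == "increased_fidelity").sum())
        rows.append(
            {
                "contrast": contrast,
                "stratum": "RP" if is_rp else "non-RP",
                "n_events": len(g),
                "reduced": reduced,
                "increased": increased,
                "ns": int((g["direction"] == "ns").sum()),
                "ratio_reduced_increased": (
                    reduced / increased if increased > 0 else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
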