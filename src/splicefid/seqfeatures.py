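"""Intron sequence features: PWM site scores, k-mer composition, folding.

Site windows (transcript orientation, anchored on the indicated base and
half-open on the downstream side, so the anchor counts toward the
downstream span):

* 5'SS: 4 nt upstream .. 7 nt downstream of the first intron base (11 nt)
* 3'SS: 16 nt upstream .. 4 nt downstream of the last intron base (20 nt)
* BP:   7 nt upstream .. 3 nt downstream of the branch adenosine (10 nt)

PWM scoring is the per-position product of empirical nucleotide
frequencies; scores are reported as log2 probabilities and linearly
rescaled to [0, 100] over the scored gene set.

Folding energy uses a pluggable engine; the built-in proxy is
base-pair maximization (Watson-Crick + GU wobble, minimum hairpin loop
of 3 unpaired bases) scored at -1 energy unit per pair and normalized
per nucleotide.  An external folding program can be supplied through
``fold_energy_proxy(engine=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, Intron
from .junctions import SpliceEvent

__all__ = [
    "PWM",
    "WINDOWS",
    "extract_site_windows",
    "window_sequence",
    "train_pwm",
    "score_sequence",
    "rescale_scores",
    "find_branch_point",
    "kmer_frequencies",
    "KMER_NAMES",
    "fold_energy_proxy",
    "nussinov_max_pairs",
    "build_feature_matrix",
    "feature_registry",
]

_ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: (upstream, downstream) spans per site class; window length = u + d
WINDOWS = {"5ss": (4, 7), "3ss": (16, 4), "bp": (7, 3)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix of per-position nucleotide frequencies."""

    site_class: str
    weights: np.ndarray  # shape (k, 4), rows sum to 1
    pseudocount: float = 0.5

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, columns=list(_ALPHABET))


def window_sequence(
    contig_seq: str, anchor: int, strand: str, upstream: int, downstream: int
) -> tuple[str, bool]:
    """Extract ``[anchor-u, anchor+d)`` in transcript orientation.

    On the minus strand the window is taken from the mirrored genomic
    interval and reverse-complemented.  Returns ``(sequence, truncated)``
    — windows running off the contig are clipped and flagged.
    """
    if strand == "+":
        lo, hi = anchor - upstream, anchor + downstream
    else:
        lo, hi = anchor - downstream + 1, anchor + upstream + 1
    truncated = lo < 0 or hi > len(contig_seq)
    seq = contig_seq[max(lo, 0): min(hi, len(contig_seq))]
    if strand == "-":
        seq = revcomp(seq)
    return seq, truncated


def extract_site_windows(
    intron: Intron,
    seqs: dict[str, str],
    bp_pos: Optional[int] = None,
) -> dict[str, tuple[Optional[str], bool]]:
    """5'SS / 3'SS / BP window sequences for one intron.

    Anchors: first intron base (5'SS), last intron base (3'SS), branch
    adenosine (BP; ``bp_pos`` overrides ``intron.bp_pos``).  The BP entry
    is ``(None, False)`` when no branch position is available.
    """
    contig = seqs[intron.chrom]
    if intron.strand == "+":
        a5, a3 = intron.start, intron.end - 1
    else:
        a5, a3 = intron.end - 1, intron.start
    out = {
        "5ss": window_sequence(contig, a5, intron.strand, *WINDOWS["5ss"]),
        "3ss": window_sequence(contig, a3, intron.strand, *WINDOWS["3ss"]),
    }
    bp = bp_pos if bp_pos is not None else intron.bp_pos
    if bp is None:
        out["bp"] = (None, False)
    else:
        out["bp"] = window_sequence(contig, bp, intron.strand, *WINDOWS["bp"])
    return out


def train_pwm(
    sequences: Sequence[str], site_class: str = "", pseudocount: float = 0.5
) -> PWM:
    """Empirical per-position frequencies with an additive pseudocount.

    All sequences must share one length; non-ACGT characters at a
    position are simply not counted (the pseudocount keeps the column
    normalizable).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    k = len(sequences[0])
    if any(len(s) != k for s in sequences):
        raise ValueError("sequences must have equal lengths")
    counts = np.full((k, 4), pseudocount, dtype=float)
    for s in sequences:
        for i, base in enumerate(s.upper()):
            j = _IDX.get(base)
            if j is not None:
                counts[i, j] += 1.0
    row_sums = counts.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("zero column mass; use a positive pseudocount")
    return PWM(site_class, counts / row_sums, pseudocount)


def score_sequence(pwm: PWM, sequence: str) -> float:
    """log2 probability of ``sequence`` under the PWM (sum of log2 p_i)."""
    if len(sequence) != pwm.k:
        raise ValueError(
            f"sequence length {len(sequence)} != PWM width {pwm.k}"
        )
    x = 0.0
    for i, base in enumerate(sequence.upper()):
        j = _IDX.get(base)
        if j is None:
            return float("nan")
        p = pwm.weights[i, j]
        if p == 0.0:
            return float("-inf")
        x += float(np.log2(p))
    return x


def rescale_scores(scores: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Linear rescale of log2 scores to [0, 100] over the given set.

    ``Y = (X - min X) / (max X - min X) * 100``; the set max maps to 100
    and the min to 0.  A degenerate set (max == min) maps everything to
    100 — every sequence is maximal — with the flag returned True.
    """
    x = np.asarray(scores, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return np.full_like(x, np.nan), True
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        y = np.where(np.isfinite(x), 100.0, np.nan)
        return y, True
    y = (x - lo) / (hi - lo) * 100.0
    return y, False


def find_branch_point(
    intron_seq: str, bp_pwm: PWM, min_tail: int = 3
) -> Optional[int]:
    """Position (0-based, within the intron) of the best branch adenosine.

    Scans anchors that (a) are adenosines, (b) leave ``min_tail`` nt
    before the 3'SS, and (c) fit the full BP window inside the intron.
    Ties go to the 3'-most site, matching the usual BP->3'SS geometry.
    Returns None when no eligible adenosine exists.
    """
    u, d = WINDOWS["bp"]
    best_pos, best_score = None, -np.inf
    for pos in range(u, len(intron_seq) - max(min_tail, d - 1)):
        if intron_seq[pos].upper() != "A":
            continue
        window = intron_seq[pos - u: pos + d]
        if len(window) != u + d:
            continue
        s = score_sequence(bp_pwm, window)
        if np.isnan(s):
            continue
        if s >= best_score:  # >= keeps the 3'-most of equal scores
            best_score, best_pos = s, pos
    return best_pos


@lru_cache(maxsize=1)
def _kmer_names() -> tuple[str, ...]:
    from itertools import product

    names = []
    for k in (1, 2, 3):
        names.extend("".join(p) for p in product(_ALPHABET, repeat=k))
    return tuple(names)


KMER_NAMES: tuple[str, ...] = _kmer_names()  # 4 + 16 + 64 = 84 entries


def kmer_frequencies(sequence: str) -> np.ndarray:
    """84-vector of 1- to 3-mer frequencies (count / (L - k + 1)).

    Entries for a k with ``L < k`` are NaN (flagged missing).  Windows
    containing non-ACGT characters are skipped in the numerator but the
    denominator keeps all L - k + 1 positions.
    """
    seq = sequence.upper()
    L = len(seq)
    out = np.zeros(84, dtype=float)
    offset = 0
    for k in (1, 2, 3):
        n_windows = L - k + 1
        block = 4 ** k
        if n_windows <= 0:
            out[offset: offset + block] = np.nan
            offset += block
            continue
        counts = {}
        for i in range(n_windows):
            counts[seq[i: i + k]] = counts.get(seq[i: i + k], 0) + 1
        names = _kmer_names()[offset: offset + block]
        for j, name in enumerate(names):
            out[offset + j] = counts.get(name, 0) / n_windows
        offset += block
    return out


_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG", "AT", "TA", "GT", "TG"}

# base codes: A=0, C=1, G=2, T/U=3, other=4 (pairs with nothing)
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PAIR_TABLE = np.zeros((5, 5), dtype=np.bool_)
for _x, _y in (("A", "T"), ("G", "C"), ("G", "T")):
    _PAIR_TABLE[_BASE_CODE[_x], _BASE_CODE[_y]] = True
    _PAIR_TABLE[_BASE_CODE[_y], _BASE_CODE[_x]] = True


def _nussinov_kernel(codes, pair_table, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for t in range(i, j - min_loop):
                if pair_table[codes[t], codes[j]]:
                    left = dp[i, t - 1] if t > i else 0
                    right = dp[t + 1, j - 1] if t + 1 <= j - 1 else 0
                    cand = left + 1 + right
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp[0, n - 1]


try:  # O(n^3) DP; compiled when numba is available (it is in the
    # reference environment), otherwise the pure-Python kernel is used
    from numba import njit

    _nussinov_kernel = njit(cache=False)(_nussinov_kernel)
except ImportError:  # pragma: no cover
    pass


def nussinov_max_pairs(sequence: str, min_loop: int = 3) -> int:
    """Maximum nested base pairs (WC + GU) with a minimum hairpin loop.

    A pair (i, j) requires at least ``min_loop`` unpaired bases between
    i and j.
    """
    s = sequence.upper()
    n = len(s)
    if n == 0:
        return 0
    codes = np.array([_BASE_CODE.get(b, 4) for b in s], dtype=np.int8)
    return int(_nussinov_kernel(codes, _PAIR_TABLE, min_loop))


def fold_energy_proxy(
    sequence: str,
    pair_weight: float = 1.0,
    min_loop: int = 3,
    engine: Optional[Callable[[str], float]] = None,
) -> float:
    """Folding free-energy proxy, normalized per nucleotide (always <= 0).

    Default: ``-(max nested pairs) * pair_weight / length``.  Supplying
    ``engine`` (any callable returning a total delta-G for the sequence,
    e.g. a wrapper around an external folding program) replaces the
    pairing proxy; the result is still divided by the length.
    """
    if len(sequence) == 0:
        return 0.0
    if engine is not None:
        return engine(sequence) / len(sequence)
    pairs = nussinov_max_pairs(sequence, min_loop=min_loop)
    return -pairs * pair_weight / len(sequence)


# ---------------------------------------------------------------------------
# feature matrix assembly

_SCALARS = ("length", "dg_intron_per_nt", "dg_bp3ss_per_nt", "score_5ss",
            "score_3ss", "score_bp")


def feature_registry() -> list[str]:
    """Column order of the default feature matrix.

    6 scalars x {annotated, novel} + 84 k-mers x {annotated, novel}
    = 180 columns.
    """
    cols = []
    for side in ("annot", "novel"):
        cols.extend(f"{side}_{s}" for s in _SCALARS)
    for side in ("annot", "novel"):
        cols.extend(f"{side}_kmer_{m}" for m in KMER_NAMES)
    return cols


def _intron_seq(seqs: dict[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    s = seqs[chrom][start:end]
    return revcomp(s) if strand == "-" else s


@dataclass
class _IntronFeatures:
    length: float = np.nan
    dg_intron: float = np.nan
    dg_bp3ss: float = np.nan
    s5: float = np.nan  # raw log2 scores; rescaled jointly later
    s3: float = np.nan
    sbp: float = np.nan
    kmers: np.ndarray = field(default_factory=lambda: np.full(84, np.nan))


def _one_intron(
    seqs: dict[str, str],
    chrom: str,
    start: int,
    end: int,
    strand: str,
    pwms: dict[str, PWM],
    bp_pos: Optional[int],
    fold=fold_energy_proxy,
) -> _IntronFeatures:
    f = _IntronFeatures()
    iseq = _intron_seq(seqs, chrom, start, end, strand)
    f.length = float(len(iseq))
    f.dg_intron = fold(iseq)
    f.kmers = kmer_frequencies(iseq)

    iv = Intron(chrom, start, end, strand, "", "", 0, bp_pos)
    wins = extract_site_windows(iv, seqs)
    for key, attr in (("5ss", "s5"), ("3ss", "s3")):
        seq, trunc = wins[key]
        if seq is not None and not trunc and len(seq) == pwms[key].k:
            setattr(f, attr, score_sequence(pwms[key], seq))

    if bp_pos is None:
        rel = find_branch_point(iseq, pwms["bp"])
    else:
        rel = (bp_pos - start) if strand == "+" else (end - 1 - bp_pos)
    if rel is not None:
        u, d = WINDOWS["bp"]
        window = iseq[rel - u: rel + d]
        if len(window) == u + d:
            f.sbp = score_sequence(pwms["bp"], window)
        tail = iseq[rel:]
        if len(tail) > 0:
            f.dg_bp3ss = fold(tail)
    return f


def build_feature_matrix(
    events: Sequence[SpliceEvent],
    genome: GenomeModel,
    seqs: dict[str, str],
    pwms: Optional[dict[str, PWM]] = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """One feature row per novel event (index = event_id).

    When ``pwms`` is None they are trained on the windows of all
    annotated introns in the genome.  Raw log2 PWM scores are rescaled to
    [0, 100] per site class over the pooled annotated+novel sequence set,
    so 100 marks the best site seen.  Missing features stay NaN (median
    imputation is deferred to model fitting).
    """
    if pwms is None:
        pwms = train_pwms_from_genome(genome, seqs, pseudocount=pseudocount)

    rows: dict[str, dict[str, _IntronFeatures]] = {}
    for ev in events:
        if not ev.is_novel:
            continue
        novel = _one_intron(
            seqs, ev.chrom, ev.start, ev.end, ev.strand, pwms, None
        )
        if ev.paired_intron is not None:
            iv = ev.paired_intron
            annot = _one_intron(
                seqs, iv.chrom, iv.start, iv.end, iv.strand, pwms, iv.bp_pos
            )
        else:
            annot = _IntronFeatures()
        rows[ev.event_id] = {"annot": annot, "novel": novel}

    # joint rescale per site class over every scored sequence
    for attr in ("s5", "s3", "sbp"):
        raw = [
            getattr(rows[eid][side], attr)
            for eid in rows
            for side in ("annot", "novel")
        ]
        scaled, _ = rescale_scores(raw)
        it = iter(scaled)
        for eid in rows:
            for side in ("annot", "novel"):
                setattr(rows[eid][side], attr, float(next(it)))

    cols = feature_registry()
    data = np.full((len(rows), len(cols)), np.nan)
    for r, eid in enumerate(rows):
        vals = []
        for side in ("annot", "novel"):
            f = rows[eid][side]
            vals.extend([f.length, f.dg_intron, f.dg_bp3ss, f.s5, f.s3, f.sbp])
        for side in ("annot", "novel"):
            vals.extend(rows[eid][side].kmers.tolist())
        data[r] = vals
    return pd.DataFrame(data, index=list(rows), columns=cols)


def train_pwms_from_genome(
    genome: GenomeModel, seqs: dict[str, str], pseudocount: float = 0.5
) -> dict[str, PWM]:
    """Train 5'SS/3'SS/BP PWMs from all annotated introns.

    Branch points: annotated positions when present, else a consensus
    TACTAAC scan (best match, branch A = 6th position of the motif).
    """
    windows: dict[str, list[str]] = {"5ss": [], "3ss": [], "bp": []}
    for iv in genome.introns:
        bp = iv.bp_pos
        if bp is None:
            rel = _scan_consensus_bp(_intron_seq(seqs, iv.chrom, iv.start, iv.end, iv.strand))
            if rel is not None:
                bp = (iv.start + rel) if iv.strand == "+" else (iv.end - 1 - rel)
        wins = extract_site_windows(iv, seqs, bp_pos=bp)
        for key, (u, d) in WINDOWS.items():
            seq, trunc = wins[key]
            if seq is not None and not trunc and len(seq) == u + d:
                windows[key].append(seq)
    return {
        key: train_pwm(ws, site_class=key, pseudocount=pseudocount)
        for key, ws in windows.items()
        if ws
    }


def _scan_consensus_bp(intron_seq: str, motif: str = "TACTAAC") -> Optional[int]:
    """Best TACTAAC match by Hamming distance; returns the branch-A index."""
    L, m = len(intron_seq), len(motif)
    if L < m:
        return None
    best, best_pos = m + 1, None
    for i in range(L - m + 1):
        d = sum(a != b for a, b in zip(intron_seq[i: i + m].upper(), motif))
        if d <= best:  # <= keeps the 3'-most best match
            best, best_pos = d, i
    if best_pos is None:
        return None
    return best_pos + 5  # branch adenosine = 6th base of TACTAAC
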