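"""Supervised sliding-window sequence scorer.

A fixed-order Markov log-likelihood-ratio model: a CRM model and a
background model are trained on k-mer counts (add-pseudocount smoothing),
and each genome window is scored by the mean per-base log-likelihood ratio
CRM vs background. The genome-scanning interface matches the conventions of
supervised CRM discovery tools: 500-bp windows with a 250-bp shift, scanned
within non-coding (exon-masked) segments, with a per-instance *offset*
(leading base pairs ignored at the start of each segment) so that many
instances at staggered offsets can tile the genome at high density.

Ranked score curves are cut at their elbow: the point furthest from the
chord joining the first and last points after min-max normalization of both
axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, sort_merge

__all__ = [
    "MarkovModel",
    "ScoredWindow",
    "ScanConfig",
    "train_markov",
    "score_window",
    "extract_noncoding",
    "scan",
    "prepare_scan",
    "scan_prepared",
    "take_top",
    "elbow_index",
    "default_top_predictions",
]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class MarkovModel:
    """Fixed-order Markov model over {A,C,G,T} with pseudocount smoothing.

    ``log_cond`` has shape (4**order, 4): log P(next base | context).
    """

    order: int
    log_cond: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        rows = np.exp(self.log_cond).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("conditional probabilities do not sum to 1")

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_cond)


@dataclass(frozen=True)
class ScoredWindow:
    """A scored scan window with the offset of the instance that produced it."""

    interval: GenomicInterval
    score: float
    offset: int


@dataclass
class ScanConfig:
    window: int = 500
    shift: int = 250
    offset: int = 0
    top_n: int = 5000

    def __post_init__(self) -> None:
        if self.window <= 0 or self.shift <= 0 or self.shift > self.window:
            raise ValueError("require 0 < shift <= window")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


def _kmer_context_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Context index (base-4) and validity for each position i >= k.

    Returns (ctx, valid) of length len(codes) - k; position i in the return
    arrays describes base ``i + k`` of the input, whose context is
    ``codes[i:i+k]``. Valid means no N within the (k+1)-mer.
    """
    n = len(codes)
    if n < k + 1:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    valid = codes < 4
    ctx = np.zeros(n - k, dtype=np.int64)
    ok = np.ones(n - k, dtype=bool)
    for j in range(k):
        ctx = ctx * 4 + np.where(valid[j : n - k + j], codes[j : n - k + j], 0)
        ok &= valid[j : n - k + j]
    ok &= valid[k:]
    return ctx, ok


def train_markov(
    sequences: list[str],
    order: int,
    pseudocount: float = 1.0,
    include_revcomp: bool = False,
) -> MarkovModel:
    """Train a fixed-order Markov model from (k+1)-mer counts.

    Counts come from the given sequences (optionally pooled with their
    reverse complements); any (k+1)-mer containing N is excluded. Smoothing
    adds ``pseudocount`` to every (context, base) cell. With no usable
    counts at all, every conditional is uniform (pure pseudocount).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    k = order
    counts = np.zeros(4**k * 4, dtype=np.float64)
    total_len = 0
    for seq in sequences:
        codes = encode(seq)
        total_len += len(codes)
        variants = [codes]
        if include_revcomp:
            variants.append(_COMPLEMENT[codes[::-1]])
        for c in variants:
            ctx, ok = _kmer_context_indices(c, k)
            if len(ctx) == 0:
                continue
            idx = ctx[ok] * 4 + c[k:][ok]
            counts += np.bincount(idx, minlength=len(counts))
    if total_len < 4 ** (order + 1):
        warnings.warn(
            f"training length {total_len} bp is below 4^{order + 1}; "
            "conditional probabilities will be dominated by the pseudocount",
            stacklevel=2,
        )
    counts = counts.reshape(4**k, 4) + pseudocount
    log_cond = np.log(counts) - np.log(counts.sum(axis=1, keepdims=True))
    return MarkovModel(order=order, log_cond=log_cond, pseudocount=pseudocount)


def _llr_table(crm_model: MarkovModel, bg_model: MarkovModel) -> np.ndarray:
    if crm_model.order != bg_model.order:
        raise ValueError("CRM and background models must share the same order")
    return crm_model.log_cond - bg_model.log_cond


def score_window(
    seq: str, crm_model: MarkovModel, bg_model: MarkovModel, max_n_frac: float = 0.10
) -> float:
    """Mean per-scored-base log-likelihood ratio of one sequence.

    Returns NaN when more than ``max_n_frac`` of the bases are N (undefined
    k-mer statistics) or when no position has a complete valid context.
    """
    k = crm_model.order
    llr = _llr_table(crm_model, bg_model)
    codes = encode(seq)
    if len(codes) < k + 1:
        raise ValueError(f"sequence length {len(codes)} < order+1 ({k + 1})")
    if (codes == 4).sum() > max_n_frac * len(codes):
        return float("nan")
    ctx, ok = _kmer_context_indices(codes, k)
    if not ok.any():
        return float("nan")
    vals = llr[ctx[ok], codes[k:][ok]]
    return float(vals.mean())


def extract_noncoding(
    genome: dict[str, str], exons: list[GenomicInterval]
) -> list[tuple[GenomicInterval, str]]:
    """Maximal non-exonic segments with their sequences, genomic coordinates."""
    merged: dict[str, list[GenomicInterval]] = {}
    for iv in sort_merge(exons):
        merged.setdefault(iv.chrom, []).append(iv)
    out: list[tuple[GenomicInterval, str]] = []
    for chrom, seq in genome.items():
        pos = 0
        for iv in merged.get(chrom, []):
            if iv.start > pos:
                out.append((GenomicInterval(chrom, pos, iv.start), seq[pos : iv.start]))
            pos = max(pos, iv.end)
        if pos < len(seq):
            out.append((GenomicInterval(chrom, pos, len(seq)), seq[pos:]))
    return out


@dataclass
class _PreparedSegment:
    chrom: str
    start: int  # genomic start of the segment
    length: int
    cum_llr: np.ndarray  # cumulative per-position LLR (invalid positions 0)
    cum_ok: np.ndarray  # cumulative count of scored positions
    cum_n: np.ndarray  # cumulative count of N bases


@dataclass
class ScanPrep:
    """Per-base LLR sums for every non-coding segment, shared across offsets.

    Computing these once makes scanning the same genome at the 25
    high-density offsets no more expensive than a single scan.
    """

    segments: list[_PreparedSegment]
    order: int


def prepare_scan(
    genome: dict[str, str],
    exons: list[GenomicInterval],
    crm_model: MarkovModel,
    bg_model: MarkovModel,
) -> ScanPrep:
    llr = _llr_table(crm_model, bg_model)
    k = crm_model.order
    segments: list[_PreparedSegment] = []
    for iv, seq in extract_noncoding(genome, exons):
        codes = encode(seq)
        n = len(codes)
        per_pos = np.zeros(n, dtype=np.float64)
        okpos = np.zeros(n, dtype=np.float64)
        if n >= k + 1:
            ctx, ok = _kmer_context_indices(codes, k)
            vals = np.where(ok, llr[ctx, np.where(ok, codes[k:], 0)], 0.0)
            per_pos[k:] = vals
            okpos[k:] = ok
        cum_llr = np.concatenate(([0.0], np.cumsum(per_pos)))
        cum_ok = np.concatenate(([0.0], np.cumsum(okpos)))
        cum_n = np.concatenate(([0], np.cumsum(codes == 4)))
        segments.append(_PreparedSegment(iv.chrom, iv.start, n, cum_llr, cum_ok, cum_n))
    return ScanPrep(segments=segments, order=k)


def scan_prepared(
    prep: ScanPrep, cfg: ScanConfig, max_n_frac: float = 0.10
) -> list[ScoredWindow]:
    """Score all windows of one offset instance from prepared segments.

    Window starts within each segment are segment_start + offset + i*shift
    for i = 0, 1, ... while the window fits; windows with more than
    ``max_n_frac`` N bases or no scoreable position are dropped.
    """
    out: list[ScoredWindow] = []
    w = cfg.window
    for seg in prep.segments:
        rel = np.arange(cfg.offset, seg.length - w + 1, cfg.shift, dtype=np.int64)
        if len(rel) == 0:
            continue
        n_counts = seg.cum_n[rel + w] - seg.cum_n[rel]
        ok_counts = seg.cum_ok[rel + w] - seg.cum_ok[rel]
        sums = seg.cum_llr[rel + w] - seg.cum_llr[rel]
        keep = (n_counts <= max_n_frac * w) & (ok_counts > 0)
        for r, s, c in zip(rel[keep], sums[keep], ok_counts[keep]):
            start = seg.start + int(r)
            out.append(
                ScoredWindow(
                    interval=GenomicInterval(seg.chrom, start, start + w),
                    score=float(s / c),
                    offset=cfg.offset,
                )
            )
    return out


def scan(
    genome: dict[str, str],
    exons: list[GenomicInterval],
    crm_model: MarkovModel,
    bg_model: MarkovModel,
    cfg: ScanConfig,
    max_n_frac: float = 0.10,
) -> list[ScoredWindow]:
    """Score every window of one scan instance (one offset) over the genome."""
    return scan_prepared(prepare_scan(genome, exons, crm_model, bg_model), cfg, max_n_frac)


def take_top(windows: list[ScoredWindow], top_n: int = 5000) -> list[ScoredWindow]:
    """Rank descending by score, ties by (chrom, start) ascending; keep top_n."""
    ranked = sorted(
        windows, key=lambda w: (-w.score, w.interval.chrom, w.interval.start)
    )
    return ranked[:top_n]


def elbow_index(values_desc: list[float] | np.ndarray) -> int:
    """Elbow of a descending curve: the point furthest from the chord.

    Both axes are min-max normalized to [0, 1] first (the two axes carry
    different units, so the geometric rule is only scale-invariant after
    normalization). Returns the 0-based index maximizing perpendicular
    distance to the line through the first and last points; ties break to
    the smallest index, and a flat curve returns 0.
    """
    v = np.asarray(values_desc, dtype=np.float64)
    if len(v) < 3:
        raise ValueError("elbow_index requires at least 3 values")
    x = np.arange(len(v)) / (len(v) - 1)
    rng = v.max() - v.min()
    if rng == 0:
        return 0
    y = (v - v.min()) / rng
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    # perpendicular distance; denominator constant, so omitted from argmax
    dist = np.abs(dy * x - dx * y + dx * y[0] - dy * x[0])
    # ties (within float noise) break to the smallest index
    return int(np.nonzero(dist >= dist.max() - 1e-12)[0][0])


def default_top_predictions(windows: list[ScoredWindow]) -> list[GenomicInterval]:
    """Default-protocol cutoff: keep windows scoring >= the elbow-point score.

    Input is ranked (or re-ranked here); the result is always a prefix of
    the ranked list, carrying each window's score.
    """
    ranked = take_top(windows, top_n=len(windows))
    scores = [w.score for w in ranked]
    cut = scores[elbow_index(scores)]
    out: list[GenomicInterval] = []
    for w in ranked:
        if w.score < cut:
            break
        out.append(w.interval.with_score(w.score))
    return out
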