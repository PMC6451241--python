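"""High-density aggregation of staggered scan instances.

Many scan instances, each offset by a multiple of 10 bp (canonically
offsets 0, 10, ..., 240 with a 500/250 window/shift), are pooled and their
per-window scores projected onto a 10-bp bin grid:

1. pool all instances and keep windows scoring at or above the score of the
   5000th-ranked pooled window (theta);
2. split each kept window into 10-bp segments, each retaining the window
   score;
3. sum the segment scores per bin into a bedGraph-like track;
4. call peaks on the track (maximal runs of bins above theta, gap-merged
   and length-filtered with the peak caller's usual defaults);
5. accept peaks passing a two-stage elbow cutoff: first on the descending
   peak-amplitude curve, then on the curve of each surviving peak's maximum
   single-window score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .intervals import BinTrack, GenomicInterval
from .scoring import ScoredWindow, elbow_index

__all__ = [
    "InstanceBundle",
    "Peak",
    "concat_and_threshold",
    "explode_bins",
    "sum_bins",
    "call_peaks",
    "hd_top_predictions",
    "hd_stages",
    "HDStages",
    "CANONICAL_OFFSETS",
]

CANONICAL_OFFSETS = tuple(range(0, 250, 10))


@dataclass
class InstanceBundle:
    """Ranked windows from each offset instance of one high-density run."""

    instances: dict[int, list[ScoredWindow]]
    window: int = 500
    shift: int = 250
    bin: int = 10

    def __post_init__(self) -> None:
        for off in self.instances:
            if off % self.bin:
                raise ValueError(f"offset {off} is not a multiple of bin ({self.bin})")

    def pooled(self) -> list[ScoredWindow]:
        # iterate offsets in sorted order so pooling is order-invariant
        out: list[ScoredWindow] = []
        for off in sorted(self.instances):
            out.extend(self.instances[off])
        return out


@dataclass
class Peak:
    interval: GenomicInterval
    amplitude: float
    max_window_score: float = math.nan


def concat_and_threshold(
    bundle: InstanceBundle, rank_cutoff: int = 5000
) -> tuple[list[ScoredWindow], float]:
    """Pool all instances; drop windows below the rank-cutoff pooled score.

    theta is the score of the ``rank_cutoff``-th ranked window of the pooled
    list (the smallest score if fewer windows exist); ties at theta are
    kept, i.e. the comparison is >=.
    """
    pooled = bundle.pooled()
    if not pooled:
        raise ValueError("empty instance bundle")
    scores = sorted((w.score for w in pooled), reverse=True)
    theta = scores[min(rank_cutoff, len(scores)) - 1]
    kept = [w for w in pooled if w.score >= theta]
    return kept, theta


def explode_bins(
    kept: list[ScoredWindow], bin: int = 10
) -> list[tuple[GenomicInterval, float]]:
    """Split each window into bin-sized segments retaining the window score."""
    out: list[tuple[GenomicInterval, float]] = []
    for w in kept:
        iv = w.interval
        if iv.start % bin:
            raise ValueError(
                f"window start {iv.chrom}:{iv.start} is off the {bin}-bp grid"
            )
        if iv.length % bin:
            raise ValueError(f"window length {iv.length} is not a multiple of {bin}")
        for s in range(iv.start, iv.end, bin):
            out.append((GenomicInterval(iv.chrom, s, s + bin), w.score))
    return out


def sum_bins(
    segments: list[tuple[GenomicInterval, float]], bin: int = 10
) -> BinTrack:
    """Sum segment scores per bin; bins with no segment stay absent."""
    track = BinTrack(bin_width=bin)
    vals = track.values
    for iv, score in segments:
        if iv.start % bin or iv.length != bin:
            raise ValueError(f"segment {iv.chrom}:{iv.start}-{iv.end} off the grid")
        key = (iv.chrom, iv.start)
        vals[key] = vals.get(key, 0.0) + score
    return track


def call_peaks(
    track: BinTrack,
    cutoff: float,
    min_length: int = 200,
    max_gap: int = 30,
) -> list[Peak]:
    """Maximal runs of bins with value strictly above cutoff.

    Runs on the same chromosome separated by at most ``max_gap`` bp of
    sub-cutoff (or absent) signal are merged; merged runs shorter than
    ``min_length`` are discarded. Amplitude is the maximum bin value inside
    the peak. Only present bins are examined, so peaks always lie within
    binned (i.e. scored) territory.
    """
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for (chrom, start), v in track.values.items():
        if v > cutoff:
            by_chrom.setdefault(chrom, []).append((start, v))
    peaks: list[Peak] = []
    bw = track.bin_width
    for chrom in sorted(by_chrom):
        bins = sorted(by_chrom[chrom])
        run_start, run_end, amp = bins[0][0], bins[0][0] + bw, bins[0][1]
        for start, v in bins[1:]:
            if start - run_end <= max_gap:
                run_end = start + bw
                amp = max(amp, v)
            else:
                if run_end - run_start >= min_length:
                    peaks.append(Peak(GenomicInterval(chrom, run_start, run_end), amp))
                run_start, run_end, amp = start, start + bw, v
        if run_end - run_start >= min_length:
            peaks.append(Peak(GenomicInterval(chrom, run_start, run_end), amp))
    return peaks


def _max_window_scores(peaks: list[Peak], kept: list[ScoredWindow]) -> None:
    """Fill each peak's max single-window score (>=1 bp overlap, kept windows)."""
    import bisect

    by_chrom: dict[str, list[ScoredWindow]] = {}
    for w in kept:
        by_chrom.setdefault(w.interval.chrom, []).append(w)
    starts: dict[str, list[int]] = {}
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.interval.start)
        starts[chrom] = [w.interval.start for w in ws]
    max_w = max((w.interval.length for w in kept), default=0)
    for peak in peaks:
        ws = by_chrom.get(peak.interval.chrom, [])
        best = -math.inf
        if ws:
            st = starts[peak.interval.chrom]
            lo = bisect.bisect_left(st, peak.interval.start - max_w)
            hi = bisect.bisect_left(st, peak.interval.end)
            for w in ws[lo:hi]:
                if w.interval.overlap_len(peak.interval) > 0 and w.score > best:
                    best = w.score
        peak.max_window_score = best if best > -math.inf else math.nan


@dataclass
class HDStages:
    """All intermediates of one high-density postprocessing run."""

    kept: list[ScoredWindow]
    theta: float
    track: BinTrack
    raw_peaks: list[Peak]
    top_peaks: list[Peak]


def hd_top_predictions(
    bundle: InstanceBundle,
    rank_cutoff: int = 5000,
    min_length: int = 200,
    max_gap: int = 30,
) -> list[Peak]:
    """Full high-density pipeline: threshold, bin, sum, call, two-stage elbow.

    Stage 1 keeps peaks with amplitude at or above the elbow of the
    descending amplitude curve over all called peaks; stage 2 keeps
    survivors whose maximum single-window score is at or above the elbow of
    the ranked score curve, again constructed over all called peaks (the
    full curve retains the noise tail that anchors the elbow). When fewer
    than 3 peaks exist at a stage, its elbow is undefined and every peak is
    kept (with a warning) rather than silently dropped.
    """
    return hd_stages(bundle, rank_cutoff, min_length, max_gap).top_peaks


def hd_stages(
    bundle: InstanceBundle,
    rank_cutoff: int = 5000,
    min_length: int = 200,
    max_gap: int = 30,
) -> HDStages:
    """As :func:`hd_top_predictions`, but returning every intermediate."""
    kept, theta = concat_and_threshold(bundle, rank_cutoff)
    track = sum_bins(explode_bins(kept, bundle.bin), bundle.bin)
    raw_peaks = call_peaks(track, cutoff=theta, min_length=min_length, max_gap=max_gap)
    peaks = list(raw_peaks)
    _max_window_scores(raw_peaks, kept)

    if len(raw_peaks) >= 3:
        amps = sorted((p.amplitude for p in raw_peaks), reverse=True)
        amp_cut = amps[elbow_index(amps)]
        peaks = [p for p in peaks if p.amplitude >= amp_cut]
        # score curve built over every called peak, cutoff applied to the
        # amplitude survivors
        scores = sorted((p.max_window_score for p in raw_peaks), reverse=True)
        score_cut = scores[elbow_index(scores)]
        peaks = [p for p in peaks if p.max_window_score >= score_cut]
    elif peaks:
        warnings.warn("fewer than 3 peaks: elbow cutoffs skipped, keeping all")

    peaks = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start))
    return HDStages(kept=kept, theta=theta, track=track, raw_peaks=raw_peaks, top_peaks=peaks)
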