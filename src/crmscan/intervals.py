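"""Core genomic types and a native interval engine.

Every coordinate in this package is 0-based half-open (the BED convention).
GFF input is converted on read (:mod:`crmscan.io`); nothing downstream ever
sees 1-based coordinates.

The engine reproduces the overlap semantics of the classic BED toolchain:
``sort_merge`` merges book-ended intervals, ``intersect_fraction`` applies a
minimum-overlap fraction computed against the *query* (A) interval length,
and ``shuffle_intervals`` relocates intervals uniformly over the positions
that avoid an exclusion set, for permutation testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "CrmRecord",
    "BinTrack",
    "GenomeSpace",
    "OverlapResult",
    "sort_merge",
    "intersect_fraction",
    "shuffle_intervals",
    "total_covered_bp",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand is not None and self.strand not in _VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_score(self, score: float) -> "GenomicInterval":
        return replace(self, score=score)


@dataclass(frozen=True)
class CrmRecord:
    """A known CRM with an optional set of expression-term annotations.

    Mirrors a curated-database export: the interval plus zero or more
    tissue/stage terms (e.g. ``{"mesoderm"}``).
    """

    interval: GenomicInterval
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", frozenset(self.terms))
        if any((not t) or (not isinstance(t, str)) for t in self.terms):
            raise ValueError("expression terms must be non-empty strings")


@dataclass
class BinTrack:
    """Genome-wide fixed-width bins with non-negative summed scores.

    ``values`` maps ``(chrom, bin_start)`` to the summed score of that bin;
    bins that carry no signal are simply absent (implicitly zero).
    """

    bin_width: int = 10
    values: dict[tuple[str, int], float] = field(default_factory=dict)

    def validate(self) -> None:
        # Bin values are summed log-likelihood-ratio scores and may be
        # negative when the rank cutoff retains sub-zero windows (small
        # genomes); only the grid is enforced.
        for (chrom, start), _ in self.values.items():
            if start % self.bin_width:
                raise ValueError(f"bin start {chrom}:{start} off the {self.bin_width}-bp grid")


@dataclass
class GenomeSpace:
    """Chromosome sizes plus a merged exclusion set (e.g. exons).

    The exclusion list is sorted and merged on construction and every
    excluded interval is checked to fit within its chromosome.
    """

    chrom_sizes: dict[str, int]
    excluded: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged = sort_merge(self.excluded)
        for iv in merged:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None:
                raise ValueError(f"excluded interval on unknown chromosome {iv.chrom}")
            if iv.end > size:
                raise ValueError(
                    f"excluded interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {size}"
                )
        self.excluded = merged

    def allowed_gaps(self) -> list[GenomicInterval]:
        """Complement of the exclusion set: maximal placeable segments."""
        by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in self.chrom_sizes}
        for iv in self.excluded:
            by_chrom[iv.chrom].append(iv)
        gaps: list[GenomicInterval] = []
        for chrom in self.chrom_sizes:
            pos = 0
            for iv in by_chrom[chrom]:
                if iv.start > pos:
                    gaps.append(GenomicInterval(chrom, pos, iv.start))
                pos = iv.end
            if pos < self.chrom_sizes[chrom]:
                gaps.append(GenomicInterval(chrom, pos, self.chrom_sizes[chrom]))
        return gaps


@dataclass
class OverlapResult:
    """Result of a fractional-overlap intersection between two interval sets."""

    a_hit_indices: set[int]
    b_hit_indices: set[int]
    pair_count: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def sort_merge(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start) and merge overlapping or book-ended intervals.

    Names/scores/strands are dropped on merge (coordinates only), matching
    the behaviour of the standard BED merge step. Idempotent.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ordered:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_covered_bp(intervals: list[GenomicInterval]) -> int:
    return sum(iv.length for iv in sort_merge(intervals))


def intersect_fraction(
    A: list[GenomicInterval],
    B: list[GenomicInterval],
    min_frac_of_A: float,
) -> OverlapResult:
    """Fractional-overlap intersection, fraction computed on A's length.

    Index ``i`` of A is a hit iff some ``b`` in B overlaps ``a_i`` by at
    least ``min_frac_of_A`` of ``a_i``'s own length (comparison is >=, and
    is done in division form ``overlap/len(a) >= f`` to match the float
    semantics of the classic toolkit). The fraction never applies to B.
    """
    if not (0 < min_frac_of_A <= 1):
        raise ValueError(f"min_frac_of_A must be in (0, 1], got {min_frac_of_A}")
    a_hits: set[int] = set()
    b_hits: set[int] = set()
    pairs: list[tuple[int, int]] = []
    if not A or not B:
        return OverlapResult(a_hits, b_hits, 0, pairs)

    a_by_chrom: dict[str, list[int]] = {}
    for i, a in enumerate(A):
        a_by_chrom.setdefault(a.chrom, []).append(i)
    b_by_chrom: dict[str, list[int]] = {}
    for j, b in enumerate(B):
        b_by_chrom.setdefault(b.chrom, []).append(j)

    for chrom, a_idx in a_by_chrom.items():
        b_idx = b_by_chrom.get(chrom)
        if not b_idx:
            continue
        a_start = np.array([A[i].start for i in a_idx])[:, None]
        a_end = np.array([A[i].end for i in a_idx])[:, None]
        b_start = np.array([B[j].start for j in b_idx])[None, :]
        b_end = np.array([B[j].end for j in b_idx])[None, :]
        ov = np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
        a_len = (a_end - a_start).astype(float)
        hit = (ov > 0) & (ov / a_len >= min_frac_of_A)
        for ii, jj in zip(*np.nonzero(hit)):
            i, j = a_idx[ii], b_idx[jj]
            a_hits.add(i)
            b_hits.add(j)
            pairs.append((i, j))
    pairs.sort()
    return OverlapResult(a_hits, b_hits, len(pairs), pairs)


def shuffle_intervals(
    intervals: list[GenomicInterval],
    space: GenomeSpace,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Relocate each interval uniformly over all positions avoiding exclusions.

    Each output interval keeps its input's length (and name/score); its
    placement is drawn uniformly over every valid start position on every
    chromosome (so intervals may change chromosome, in proportion to
    available space, and outputs may overlap one another). Deterministic
    given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gaps = space.allowed_gaps()
    gap_chrom = [g.chrom for g in gaps]
    gap_start = np.array([g.start for g in gaps], dtype=np.int64)
    gap_end = np.array([g.end for g in gaps], dtype=np.int64)

    out: list[GenomicInterval] = []
    for iv in intervals:
        L = iv.length
        capacity = np.maximum(gap_end - gap_start - L + 1, 0)
        total = int(capacity.sum())
        if total == 0:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} (length {L}) cannot be "
                "placed anywhere in the allowed space"
            )
        r = int(rng.integers(total))
        cum = np.cumsum(capacity)
        g = int(np.searchsorted(cum, r, side="right"))
        offset = r - (int(cum[g - 1]) if g else 0)
        start = int(gap_start[g]) + offset
        out.append(
            GenomicInterval(
                gap_chrom[g], start, start + L, name=iv.name, score=iv.score, strand=iv.strand
            )
        )
    return out
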