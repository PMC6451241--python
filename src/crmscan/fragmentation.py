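"""Simulated genome fragmentation and robustness assessment.

Poorly assembled genomes are emulated by cutting each chromosome, from its
start toward its end, into fragments whose lengths mimic an empirical
scaffold-length distribution (draw a quartile uniformly, then a length
uniformly from the observed lengths in that quartile). Each fragment
becomes its own scaffold. Annotations are lifted forward (clipped and
re-based, features spanning cuts split), predictions are lifted back, and
robustness is summarized as true/false-positive percentages against the
native run plus the Pearson correlation of matched window scores.

A reference table of scaffold N50 values for arthropod assemblies ranging
from excellent to poor parameterizes realistic length models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, intersect_fraction

__all__ = [
    "FragmentPlan",
    "LengthModel",
    "RobustnessReport",
    "ASSEMBLY_PRESETS",
    "build_length_model",
    "preset_length_model",
    "plan_fragments",
    "apply_fragmentation",
    "liftover_back",
    "assess_robustness",
]

# Scaffold N50 (bp) of published arthropod assemblies, best to worst; "A" is
# the degenerate best case, splitting each chromosome into two halves.
ASSEMBLY_PRESETS: dict[str, tuple[str, int | None, str]] = {
    "A": ("Drosophila melanogaster (halved chromosomes)", None, "excellent"),
    "B": ("Aedes aegypti", 409_777_670, "excellent"),
    "C": ("Ctenocephalides felis", 71_713_785, "very good"),
    "D": ("Apis mellifera", 13_619_445, "very good"),
    "E": ("Papilio xuthus", 6_198_915, "good"),
    "F": ("Schizaphis graminum", 1_292_312, "good"),
    "G": ("Pogonomyrmex barbatus", 819_605, "medium"),
    "H": ("Bactrocera oleae", 139_566, "medium"),
    "I": ("Lutzomyia longipalpis", 85_093, "poor"),
    "J": ("Drosophila albomicans", 23_589, "poor"),
}

# For an exponential length distribution, the length-weighted median (N50)
# sits at ~1.6783 * mean: the solution of (1 + x) e^{-x} = 1/2.
_N50_OVER_MEAN_EXP = 1.6783469900166605


@dataclass
class LengthModel:
    """An empirical scaffold-length sample with its quartile bounds."""

    sample_lengths: np.ndarray
    quartile_bounds: tuple[float, float, float]


@dataclass
class FragmentPlan:
    """An exact tiling of each native chromosome into named fragments."""

    fragments: list[tuple[str, int, int, str]]  # (native_chrom, start, end, scaffold_id)
    seed: int

    def __post_init__(self) -> None:
        ids = [f[3] for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scaffold ids in fragment plan")

    def by_scaffold(self) -> dict[str, tuple[str, int, int]]:
        return {sid: (c, s, e) for c, s, e, sid in self.fragments}

    def validate_against(self, chrom_sizes: dict[str, int]) -> None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e, _ in self.fragments:
            per_chrom.setdefault(c, []).append((s, e))
        if set(per_chrom) != set(chrom_sizes):
            raise ValueError("fragment plan chromosomes do not match the genome")
        for c, spans in per_chrom.items():
            spans.sort()
            pos = 0
            for s, e in spans:
                if s != pos:
                    raise ValueError(f"plan gap/overlap on {c} at {pos}")
                pos = e
            if pos != chrom_sizes[c]:
                raise ValueError(f"plan does not reach the end of {c}")


@dataclass
class RobustnessReport:
    tp_percent: float
    fp_percent: float
    pearson_r: float
    n_common_windows: int


def build_length_model(scaffold_lengths: list[int] | np.ndarray) -> LengthModel:
    """Quartile bounds (linear interpolation) over an observed length sample."""
    lengths = np.asarray(scaffold_lengths, dtype=np.float64)
    if len(lengths) < 4:
        raise ValueError("need at least 4 scaffold lengths")
    q1, q2, q3 = np.percentile(lengths, [25, 50, 75])
    return LengthModel(sample_lengths=np.sort(lengths), quartile_bounds=(q1, q2, q3))


def preset_length_model(
    preset: str, seed: int = 0, n_samples: int = 200, min_length: int = 500
) -> LengthModel:
    """A length model mimicking a preset assembly's scaffold N50.

    Lengths are drawn from an exponential distribution whose mean is set so
    the length-weighted median matches the preset N50 (floored at
    ``min_length``). Preset "A" has no length distribution (use
    mode="halves" in :func:`plan_fragments` instead).
    """
    if preset not in ASSEMBLY_PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    _, n50, _ = ASSEMBLY_PRESETS[preset]
    if n50 is None:
        raise ValueError("preset 'A' is the halves mode; it has no length model")
    rng = np.random.default_rng(seed)
    lengths = rng.exponential(scale=n50 / _N50_OVER_MEAN_EXP, size=n_samples)
    return build_length_model(np.maximum(lengths, min_length).astype(np.int64))


def plan_fragments(
    chrom_sizes: dict[str, int],
    model: LengthModel | None = None,
    seed: int = 0,
    mode: str = "quartile",
    align: int | None = None,
) -> FragmentPlan:
    """Plan an exact fragment tiling of every chromosome.

    mode="halves" splits each chromosome into two equal (+-1 bp) fragments.
    mode="quartile" cuts iteratively from the chromosome start: pick one of
    the model's four quartiles uniformly, then a length uniformly from the
    sample lengths in that quartile; the final fragment is truncated at the
    chromosome end. Deterministic given the seed.

    ``align`` rounds every cut position down to a multiple of that many bp
    (e.g. 10 to keep cuts on the high-density bin grid); the shift is
    negligible against scaffold lengths.
    """
    rng = np.random.default_rng(seed)
    fragments: list[tuple[str, int, int, str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"scaf{counter:05d}"

    def snap(x: int) -> int:
        return (x // align) * align if align else x

    if mode == "halves":
        for chrom, size in chrom_sizes.items():
            half = snap(size // 2)
            fragments.append((chrom, 0, half, next_id()))
            fragments.append((chrom, half, size, next_id()))
        return FragmentPlan(fragments=fragments, seed=seed)
    if mode != "quartile":
        raise ValueError(f"unknown mode {mode!r}")
    if model is None:
        raise ValueError("quartile mode requires a LengthModel")

    ls = model.sample_lengths
    b1, b2, b3 = model.quartile_bounds
    pools = [
        ls[ls <= b1],
        ls[(ls > b1) & (ls <= b2)],
        ls[(ls > b2) & (ls <= b3)],
        ls[ls > b3],
    ]
    pools = [p if len(p) else ls for p in pools]  # ties can empty a quartile
    for chrom, size in chrom_sizes.items():
        pos = 0
        while pos < size:
            q = int(rng.integers(4))
            length = max(align or 1, snap(max(1, int(rng.choice(pools[q])))))
            end = min(pos + length, size)
            fragments.append((chrom, pos, end, next_id()))
            pos = end
    return FragmentPlan(fragments=fragments, seed=seed)


def apply_fragmentation(
    genome: dict[str, str],
    annotations: list[GenomicInterval],
    plan: FragmentPlan,
) -> tuple[dict[str, str], list[GenomicInterval]]:
    """Extract fragment sequences and re-base annotations onto them.

    Fragment sequences are copied verbatim (concatenating them in plan
    order reconstructs each native chromosome byte-exactly). Features
    intersecting a fragment are clipped to it and shifted to fragment-local
    coordinates; a feature spanning a cut yields one piece per fragment.
    """
    plan.validate_against({c: len(s) for c, s in genome.items()})
    new_genome: dict[str, str] = {}
    per_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c, s, e, sid in plan.fragments:
        new_genome[sid] = genome[c][s:e]
        per_chrom.setdefault(c, []).append((s, e, sid))
    for spans in per_chrom.values():
        spans.sort()
    new_annotations: list[GenomicInterval] = []
    for iv in annotations:
        for s, e, sid in per_chrom.get(iv.chrom, []):
            if iv.start < e and iv.end > s:
                new_annotations.append(
                    GenomicInterval(
                        sid,
                        max(iv.start, s) - s,
                        min(iv.end, e) - s,
                        name=iv.name,
                        score=iv.score,
                        strand=iv.strand,
                    )
                )
    return new_genome, new_annotations


def liftover_back(
    intervals_on_scaffolds: list[GenomicInterval], plan: FragmentPlan
) -> list[GenomicInterval]:
    """Map scaffold-local intervals back to native-genome coordinates."""
    lookup = plan.by_scaffold()
    out: list[GenomicInterval] = []
    for iv in intervals_on_scaffolds:
        if iv.chrom not in lookup:
            raise ValueError(f"unknown scaffold id {iv.chrom!r}")
        chrom, s, e = lookup[iv.chrom]
        if iv.end > e - s:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds scaffold length {e - s}"
            )
        out.append(
            GenomicInterval(
                chrom, s + iv.start, s + iv.end, name=iv.name, score=iv.score, strand=iv.strand
            )
        )
    return out


def assess_robustness(
    native_top: list[GenomicInterval],
    native_all_scored: list[GenomicInterval],
    sim_top_lifted: list[GenomicInterval],
    sim_scored_lifted: list[GenomicInterval] | None = None,
    min_frac: float = 0.50,
) -> RobustnessReport:
    """Compare a fragmented-genome run against the native run.

    Native top predictions are treated as true positives and sub-cutoff
    scored territory as true negatives. tp_percent is the fraction of
    lifted simulated top predictions hitting a native top prediction at
    ``min_frac`` of their own length; fp_percent the fraction hitting only
    sub-cutoff native windows. Pearson r correlates the scores of windows
    present in both runs, matched by exact lifted coordinates (windows
    truncated or lost on short scaffolds simply do not match).
    """
    n_sim = len(sim_top_lifted)
    if n_sim:
        tp_hits = intersect_fraction(sim_top_lifted, native_top, min_frac).a_hit_indices
        tp_percent = 100.0 * len(tp_hits) / n_sim
        misses = [iv for i, iv in enumerate(sim_top_lifted) if i not in tp_hits]
        top_keys = {(iv.chrom, iv.start, iv.end) for iv in native_top}
        sub = [
            iv
            for iv in native_all_scored
            if (iv.chrom, iv.start, iv.end) not in top_keys
        ]
        fp_hits = intersect_fraction(misses, sub, min_frac).a_hit_indices
        fp_percent = 100.0 * len(fp_hits) / n_sim
    else:
        tp_percent = fp_percent = math.nan

    sim_scores = sim_scored_lifted if sim_scored_lifted is not None else sim_top_lifted
    native_by_coord = {
        (iv.chrom, iv.start, iv.end): iv.score
        for iv in native_all_scored
        if iv.score is not None
    }
    xs, ys = [], []
    for iv in sim_scores:
        key = (iv.chrom, iv.start, iv.end)
        if iv.score is not None and key in native_by_coord:
            xs.append(native_by_coord[key])
            ys.append(iv.score)
    n_common = len(xs)
    if n_common >= 2 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(np.corrcoef(xs, ys)[0, 1])
    else:
        r = math.nan
    return RobustnessReport(
        tp_percent=tp_percent, fp_percent=fp_percent, pearson_r=r, n_common_windows=n_common
    )


def write_fragment_plan(plan: FragmentPlan, path, header: list[str] | None = None) -> None:
    """Write a plan as TSV: native_chrom, native_start, native_end, scaffold."""
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(f"# {h}\n")
        fh.write(f"# seed={plan.seed}\n")
        for chrom, s, e, sid in plan.fragments:
            fh.write(f"{chrom}\t{s}\t{e}\t{sid}\n")


def read_fragment_plan(path) -> FragmentPlan:
    seed = 0
    fragments: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("# seed="):
                seed = int(s.split("=", 1)[1])
                continue
            if not s or s.startswith("#"):
                continue
            chrom, start, end, sid = s.split("\t")
            fragments.append((chrom, int(start), int(end), sid))
    return FragmentPlan(fragments=fragments, seed=seed)
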