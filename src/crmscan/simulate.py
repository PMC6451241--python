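"""Seeded synthetic genomes with planted, class-labelled CRMs.

The generator emulates the inputs of a supervised CRM-discovery study on a
compact insect-like genome, with no downloads:

- background sequence from an order-2 Markov chain with mildly non-uniform
  transition probabilities;
- planted CRMs in several "expression classes", each class enriched for
  its own small set of k-mers (emitted at elevated odds during CRM
  synthesis) — the k-mer statistical signal a supervised scorer detects;
- a partially complete, partially annotated known-CRM database: a sampled
  subset of the planted CRMs with jittered coordinates (modelling
  reporter-construct imprecision), terms kept at a configurable rate, plus
  unannotated decoy entries;
- per-class training sets drawn from the planted CRMs, leaving held-out
  planted CRMs so recovery and recall are non-trivial;
- an exon annotation covering a configurable fraction of the genome,
  avoiding planted CRMs.

Exons (and hence non-coding segment boundaries) are placed on the 10-bp
analysis grid so that high-density binning applies cleanly, mirroring
whole-scaffold scanning where the grid is anchored at position zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .intervals import CrmRecord, GenomicInterval, sort_merge

__all__ = [
    "FixtureConfig",
    "TruthSet",
    "generate_fixture",
    "generate_random_training_set",
    "write_fixture",
    "CLASS_TERMS",
]

CLASS_TERMS = (
    "mesoderm",
    "nervous_system",
    "ectoderm",
    "midgut",
    "epidermis",
    "tracheal_system",
)

# Scale between the enrichment-odds multiplier and the per-position k-mer
# emission probability. Chosen once so that the default configuration
# yields a clearly separable planted signal for a fixed-order Markov
# scorer (see the power check in the tests); not a tuning knob.
_ODDS_SCALE = 4.0

_BASES = "ACGT"
_GRID = 10


@dataclass
class FixtureConfig:
    genome_length: int = 2_000_000
    n_chromosomes: int = 4
    n_classes: int = 3
    crms_per_class: int = 60
    crm_length_range: tuple[int, int] = (300, 1500)
    enrichment_kmers_per_class: int = 8
    kmer_length: int = 6
    enrichment_strength: float = 4.0
    db_annotation_rate: float = 0.7
    db_term_rate: float = 0.8
    decoy_count: int = 40
    exon_fraction: float = 0.25
    training_per_class: int = 30
    db_jitter: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.db_annotation_rate, self.db_term_rate, self.exon_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.crm_length_range
        if not (0 < lo <= hi < 2000):
            raise ValueError("crm_length_range must lie within (0, 2000)")
        if self.n_classes > len(CLASS_TERMS):
            raise ValueError(f"at most {len(CLASS_TERMS)} classes supported")
        if self.training_per_class > self.crms_per_class:
            raise ValueError("cannot train on more CRMs than are planted")
        if self.enrichment_strength < 1.0:
            raise ValueError("enrichment_strength must be >= 1")

    @property
    def class_names(self) -> tuple[str, ...]:
        return CLASS_TERMS[: self.n_classes]

    @property
    def insertion_prob(self) -> float:
        """Per-position probability of emitting a class k-mer inside a CRM.

        Proportional to (strength - 1), so strength 1.0 plants nothing and
        CRMs are drawn purely from the background chain.
        """
        base = self.enrichment_kmers_per_class / 4**self.kmer_length
        return min(0.30, (self.enrichment_strength - 1.0) * base * _ODDS_SCALE)


@dataclass
class TruthSet:
    planted: list[CrmRecord]
    training_sets: dict[str, list[GenomicInterval]]
    database: list[CrmRecord]
    exons: list[GenomicInterval]
    class_kmers: dict[str, list[str]]

    @property
    def class_names(self) -> list[str]:
        return list(self.training_sets)


def _grid(x: int) -> int:
    return (x // _GRID) * _GRID


def _place_regions(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    lengths: list[int],
    avoid: dict[str, np.ndarray],
    mark: dict[str, np.ndarray],
    margin: int,
    what: str,
    max_tries: int = 2000,
) -> list[GenomicInterval]:
    """Place non-overlapping grid-aligned regions by rejection sampling."""
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    probs = sizes / sizes.sum()
    out: list[GenomicInterval] = []
    for length in lengths:
        for _ in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            size = chrom_sizes[chrom]
            if size <= length:
                continue
            start = _grid(int(rng.integers(0, size - length)))
            end = start + length
            lo, hi = max(0, start - margin), min(size, end + margin)
            if avoid[chrom][lo:hi].any():
                continue
            mark[chrom][lo:hi] = True
            out.append(GenomicInterval(chrom, start, end))
            break
        else:
            raise ValueError(
                f"could not place a {what} of {length} bp after {max_tries} tries; "
                "the genome is too densely packed for this configuration"
            )
    return out


def _emit_chromosome(
    length: int,
    regions: list[tuple[int, int, int]],
    trans_cum: list[tuple[float, float, float]],
    class_kmers_codes: list[list[tuple[int, ...]]],
    p_insert: float,
    rng: np.random.Generator,
) -> str:
    """Emit one chromosome: background chain with k-mer-enriched CRM spans.

    ``regions`` lists (start, end, class_index) CRM spans, sorted; class
    index -1 denotes background. The chain context carries across region
    boundaries.
    """
    u = rng.random(2 * length + 64)
    seq = bytearray(length)
    ui = 0
    ctx = 0
    spans: list[tuple[int, int, int]] = []
    pos = 0
    for s, e, cls in regions:
        if s > pos:
            spans.append((pos, s, -1))
        spans.append((s, e, cls))
        pos = e
    if pos < length:
        spans.append((pos, length, -1))

    for s, e, cls in spans:
        pos = s
        if cls < 0 or p_insert <= 0:
            while pos < e:
                r = u[ui]
                ui += 1
                row = trans_cum[ctx]
                b = 0 if r < row[0] else 1 if r < row[1] else 2 if r < row[2] else 3
                seq[pos] = b
                ctx = ((ctx << 2) & 15) | b
                pos += 1
        else:
            kmers = class_kmers_codes[cls]
            nk = len(kmers)
            while pos < e:
                r = u[ui]
                ui += 1
                if r < p_insert and pos + len(kmers[0]) <= e:
                    km = kmers[int(u[ui] * nk)]
                    ui += 1
                    for b in km:
                        seq[pos] = b
                        ctx = ((ctx << 2) & 15) | b
                        pos += 1
                else:
                    rr = u[ui]
                    ui += 1
                    row = trans_cum[ctx]
                    b = 0 if rr < row[0] else 1 if rr < row[1] else 2 if rr < row[2] else 3
                    seq[pos] = b
                    ctx = ((ctx << 2) & 15) | b
                    pos += 1
    table = bytes.maketrans(bytes(range(4)), b"ACGT")
    return bytes(seq).translate(table).decode("ascii")


def generate_fixture(cfg: FixtureConfig) -> tuple[dict[str, str], TruthSet]:
    """Generate the genome and full truth set, deterministically from the seed."""
    rng = np.random.default_rng(cfg.seed)
    per_chrom = _grid(cfg.genome_length // cfg.n_chromosomes)
    chrom_sizes = {f"chr{i + 1}": per_chrom for i in range(cfg.n_chromosomes)}
    class_names = cfg.class_names

    # distinct enrichment k-mers across all classes
    n_kmers_total = cfg.n_classes * cfg.enrichment_kmers_per_class
    kmer_ids = rng.choice(4**cfg.kmer_length, size=n_kmers_total, replace=False)

    def kmer_str(idx: int) -> str:
        s = []
        for _ in range(cfg.kmer_length):
            s.append(_BASES[idx % 4])
            idx //= 4
        return "".join(reversed(s))

    class_kmers = {
        cls: [kmer_str(int(k)) for k in kmer_ids[i * cfg.enrichment_kmers_per_class : (i + 1) * cfg.enrichment_kmers_per_class]]
        for i, cls in enumerate(class_names)
    }
    class_kmers_codes = [
        [tuple("ACGT".index(b) for b in km) for km in class_kmers[cls]]
        for cls in class_names
    ]

    # background order-2 transition probabilities, mildly non-uniform
    trans = rng.dirichlet([8.0, 8.0, 8.0, 8.0], size=16)
    trans_cum = [tuple(float(x) for x in np.cumsum(row)[:3]) for row in trans]

    # region placement
    crm_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    exon_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    lo, hi = cfg.crm_length_range
    crm_lengths = [
        _grid(int(rng.integers(lo, hi + 1))) or _GRID
        for _ in range(cfg.n_classes * cfg.crms_per_class)
    ]
    crm_ivs = _place_regions(
        rng, chrom_sizes, crm_lengths, avoid=crm_mask, mark=crm_mask, margin=200, what="CRM"
    )
    planted: list[CrmRecord] = []
    for i, iv in enumerate(crm_ivs):
        cls = class_names[i // cfg.crms_per_class]
        planted.append(
            CrmRecord(replace(iv, name=f"crm_{cls}_{i % cfg.crms_per_class:03d}"), frozenset({cls}))
        )

    # exons: fill the target fraction, avoiding CRMs
    exon_target = int(cfg.exon_fraction * cfg.genome_length)
    exon_lengths: list[int] = []
    total = 0
    while total < exon_target:
        L = _grid(int(rng.integers(200, 1501))) or _GRID
        exon_lengths.append(L)
        total += L
    # exons must avoid CRMs (and their margins); they may overlap each other
    # and are merged afterwards
    exons = _place_regions(
        rng, chrom_sizes, exon_lengths, avoid=crm_mask,
        mark=exon_mask, margin=0, what="exon",
    )
    exons = sort_merge(exons)

    # decoys: background positions, overlapping neither CRMs nor exons
    decoy_mask = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    decoy_lengths = [_grid(int(rng.integers(lo, hi + 1))) or _GRID for _ in range(cfg.decoy_count)]
    decoys = _place_regions(
        rng, chrom_sizes, decoy_lengths,
        avoid={c: crm_mask[c] | exon_mask[c] | decoy_mask[c] for c in chrom_sizes},
        mark=decoy_mask, margin=0, what="decoy",
    )

    # emit sequence
    regions_by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_sizes}
    for i, rec in enumerate(planted):
        iv = rec.interval
        regions_by_chrom[iv.chrom].append((iv.start, iv.end, i // cfg.crms_per_class))
    genome: dict[str, str] = {}
    for chrom, size in chrom_sizes.items():
        regions = sorted(regions_by_chrom[chrom])
        genome[chrom] = _emit_chromosome(
            size, regions, trans_cum, class_kmers_codes, cfg.insertion_prob, rng
        )

    # database: noisy view of the planted CRMs plus decoys
    database: list[CrmRecord] = []
    for rec in planted:
        if rng.random() >= cfg.db_annotation_rate:
            continue
        iv = rec.interval
        size = chrom_sizes[iv.chrom]
        j1 = int(rng.integers(-cfg.db_jitter, cfg.db_jitter + 1))
        j2 = int(rng.integers(-cfg.db_jitter, cfg.db_jitter + 1))
        start = max(0, iv.start + j1)
        end = min(size, iv.end + j2)
        if end <= start:
            start, end = iv.start, iv.end
        terms = rec.terms if rng.random() < cfg.db_term_rate else frozenset()
        database.append(CrmRecord(GenomicInterval(iv.chrom, start, end, name=iv.name), terms))
    for i, iv in enumerate(decoys):
        database.append(CrmRecord(replace(iv, name=f"decoy_{i:03d}"), frozenset()))
    database.sort(key=lambda r: (r.interval.chrom, r.interval.start))

    # training sets: a disjoint random subset of each class's planted CRMs
    training_sets: dict[str, list[GenomicInterval]] = {}
    for ci, cls in enumerate(class_names):
        members = [r.interval for r in planted[ci * cfg.crms_per_class : (ci + 1) * cfg.crms_per_class]]
        chosen = rng.choice(len(members), size=cfg.training_per_class, replace=False)
        training_sets[cls] = [members[int(j)] for j in sorted(chosen)]

    truth = TruthSet(
        planted=planted,
        training_sets=training_sets,
        database=database,
        exons=exons,
        class_kmers=class_kmers,
    )
    return genome, truth


def _lognormal_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    # median 745 bp with 1st/3rd quartiles near 360/1200 bp
    return np.maximum(50, rng.lognormal(mean=np.log(745.0), sigma=0.71, size=n)).astype(int)


def generate_random_training_set(
    genome: dict[str, str],
    exons: list[GenomicInterval],
    n: int = 30,
    length_sample: list[int] | np.ndarray | None = None,
    gc_tolerance: float = 0.02,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Random non-coding training sequences, GC-matched to the genome.

    Lengths come from ``length_sample`` (or, by default, a log-normal
    profile with median 745 bp and quartiles near 360/1200 bp). Each
    candidate placement must avoid exons entirely and have a GC fraction
    within ``gc_tolerance`` of the genome-wide non-coding GC fraction;
    placement fails with an error after 10 000 attempts for any interval.
    """
    rng = np.random.default_rng(seed)
    merged = sort_merge(exons)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    gaps: list[GenomicInterval] = []
    gc_count = at_count = 0
    for chrom, seq in genome.items():
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                gaps.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < len(seq):
            gaps.append(GenomicInterval(chrom, pos, len(seq)))
    for gap in gaps:
        s = genome[gap.chrom][gap.start : gap.end]
        gc_count += s.count("G") + s.count("C")
        at_count += s.count("A") + s.count("T")
    target_gc = gc_count / max(1, gc_count + at_count)

    if length_sample is None:
        lengths = _lognormal_lengths(rng, n)
    else:
        sample = np.asarray(length_sample, dtype=int)
        if len(sample) == 0:
            raise ValueError("length_sample must be non-empty")
        lengths = sample[rng.integers(0, len(sample), size=n)]

    cap = np.array([g.length for g in gaps], dtype=np.float64)
    out: list[GenomicInterval] = []
    for L in lengths:
        L = int(L)
        ok_gaps = cap >= L
        if not ok_gaps.any():
            raise ValueError(f"no non-coding gap can hold a {L}-bp interval")
        probs = np.where(ok_gaps, cap, 0.0)
        probs /= probs.sum()
        for attempt in range(10_000):
            g = gaps[int(rng.choice(len(gaps), p=probs))]
            start = g.start + int(rng.integers(0, g.length - L + 1))
            s = genome[g.chrom][start : start + L]
            gc = (s.count("G") + s.count("C")) / L
            if abs(gc - target_gc) <= gc_tolerance:
                out.append(GenomicInterval(g.chrom, start, start + L))
                break
        else:
            raise ValueError(
                f"could not find a {L}-bp non-coding interval within "
                f"{gc_tolerance:.3f} of GC {target_gc:.3f} after 10000 attempts"
            )
    return out


def write_fixture(
    genome: dict[str, str],
    truth: TruthSet,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the fixture to disk: FASTA, exon GFF, database, training BEDs."""
    from . import __version__
    from .io import write_bed, write_expression_table, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"crmscan v{__version__} seed={seed}"] if seed is not None else None

    paths = {"genome": out / "genome.fasta", "exons": out / "exons.gff"}
    write_fasta(genome, paths["genome"])
    with open(paths["exons"], "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"# {header[0]}\n")
        for i, iv in enumerate(truth.exons):
            fh.write(
                f"{iv.chrom}\tcrmscan\texon\t{iv.start + 1}\t{iv.end}\t.\t+\t.\tID=exon{i:05d}\n"
            )
    paths["database_tsv"] = out / "database.tsv"
    write_expression_table(truth.database, paths["database_tsv"], header=header)
    paths["database_bed"] = out / "database.bed"
    write_bed([r.interval for r in truth.database], paths["database_bed"], header=header)
    paths["truth"] = out / "truth.bed"
    write_bed([r.interval for r in truth.planted], paths["truth"], header=header)
    manifest_lines = []
    for cls, ivs in truth.training_sets.items():
        p = out / f"training_{cls}.bed"
        write_bed(ivs, p, header=header)
        paths[f"training_{cls}"] = p
        manifest_lines.append(f"training_{cls}.bed\t{cls}")
    paths["manifest"] = out / "manifest.txt"
    paths["manifest"].write_text("\n".join(manifest_lines) + "\n")
    return paths
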