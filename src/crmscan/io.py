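"""Readers and writers for the standard formats the pipeline touches.

FASTA, BED3/BED6, bedGraph, GFF3 exons, the 5-column expression-annotated
CRM table (``chrom  start  end  name  terms``; terms semicolon-separated),
and the training-set manifest. Strict about coordinates: BED/bedGraph are
0-based half-open and preserved verbatim; GFF is 1-based inclusive and is
converted to 0-based half-open here, the only place 1-based data enters.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .intervals import BinTrack, CrmRecord, GenomicInterval

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_gff_exons",
    "read_expression_table",
    "write_expression_table",
    "read_manifest",
    "write_windows_bed",
    "read_windows_bed",
]

_FASTA_ALPHABET = frozenset("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {chrom: sequence}, upper-cased, ACGTN only."""
    entries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in entries:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"illegal character {sorted(bad)[0]!r} in sequence {rec.id!r}"
            )
        entries[rec.id] = seq
    return entries


def write_fasta(entries: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return (not s) or s.startswith("#") or s.startswith("track") or s.startswith("browser")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; '.' placeholders map to None; errors carry line numbers."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from e
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                score = float(cols[4])
            strand = cols[5] if len(cols) > 5 and cols[5] != "." else None
            out.append(GenomicInterval(cols[0], start, end, name, score, strand))
    return out


def _fmt_score(x: float) -> str:
    # repr() keeps round-trips bit-stable
    return repr(float(x))


def write_bed(
    intervals: list[GenomicInterval],
    path: str | Path,
    header: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(f"# {h}\n")
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            extras = [
                iv.name if iv.name is not None else ".",
                _fmt_score(iv.score) if iv.score is not None else ".",
                iv.strand if iv.strand is not None else ".",
            ]
            # trim trailing placeholder columns
            while extras and extras[-1] == ".":
                extras.pop()
            fh.write("\t".join(cols + extras) + "\n")


def write_bedgraph(
    track: BinTrack, path: str | Path, header: list[str] | None = None
) -> None:
    """One line per bin (no merging of equal-valued neighbours), bit-stable."""
    track.validate()
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(f"# {h}\n")
        for (chrom, start), v in sorted(track.values.items()):
            fh.write(f"{chrom}\t{start}\t{start + track.bin_width}\t{_fmt_score(v)}\n")


def read_bedgraph(path: str | Path, bin_width: int = 10) -> BinTrack:
    track = BinTrack(bin_width=bin_width)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = cols[0], int(cols[1]), int(cols[2]), float(cols[3])
            if end - start != bin_width:
                raise ValueError(
                    f"{path}:{lineno}: bin width {end - start} != expected {bin_width}"
                )
            track.values[(chrom, start)] = value
    track.validate()
    return track


def read_gff_exons(
    path: str | Path, feature_type: str = "exon"
) -> list[GenomicInterval]:
    """Extract features of one type from GFF3, converting to 0-based half-open.

    GFF columns are 1-based inclusive; an exon annotated 1..100 becomes the
    interval [0, 100).
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF line (<8 columns)")
            if cols[2] != feature_type:
                continue
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer GFF coordinate") from e
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start > end in GFF feature")
            strand = cols[6] if len(cols) > 6 and cols[6] in {"+", "-"} else None
            out.append(GenomicInterval(cols[0], start1 - 1, end1, strand=strand))
    return out


def read_expression_table(path: str | Path) -> list[CrmRecord]:
    """Read the 5-column TSV of expression-annotated CRMs.

    Columns: chrom, start, end, name, terms (semicolon-separated; may be
    empty). Terms are trimmed and deduplicated.
    """
    out: list[CrmRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if _is_skippable(line):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 columns, got {len(cols)}"
                )
            chrom, start, end, name, terms_col = cols
            terms = frozenset(t.strip() for t in terms_col.split(";") if t.strip())
            out.append(
                CrmRecord(GenomicInterval(chrom, int(start), int(end), name or None), terms)
            )
    return out


def write_expression_table(
    records: list[CrmRecord], path: str | Path, header: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for h in header or []:
            fh.write(f"# {h}\n")
        for rec in records:
            iv = rec.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        ";".join(sorted(rec.terms)),
                    ]
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """Read a training-set manifest: one 'bed_path<TAB>set_name' line each.

    A line with only a path derives the set name from the file stem.
    """
    base = Path(path).parent
    out: list[tuple[str, Path]] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t") if "\t" in s else s.split()
            bed = Path(parts[0])
            if not bed.is_absolute():
                bed = base / bed
            name = parts[1] if len(parts) > 1 else bed.stem
            out.append((name, bed))
    return out


def write_windows_bed(windows, path, header: list[str] | None = None) -> None:
    """Write scored scan windows as BED6: name 'w<i>_off<o>', score column 5.

    The producing offset is encoded in the name suffix so instance files
    can be pooled later without relying on file naming.
    """
    intervals = [
        GenomicInterval(
            w.interval.chrom,
            w.interval.start,
            w.interval.end,
            name=f"w{i:06d}_off{w.offset}",
            score=w.score,
            strand=".",
        )
        for i, w in enumerate(windows)
    ]
    write_bed(intervals, path, header=header)


def read_windows_bed(path: str | Path):
    """Read scored windows written by :func:`write_windows_bed`."""
    from .scoring import ScoredWindow

    out = []
    for iv in read_bed(path):
        if iv.score is None or iv.name is None or "_off" not in iv.name:
            raise ValueError(f"{path}: not a scored-window BED (need name/_off and score)")
        offset = int(iv.name.rsplit("_off", 1)[1])
        out.append(
            ScoredWindow(
                interval=GenomicInterval(iv.chrom, iv.start, iv.end),
                score=iv.score,
                offset=offset,
            )
        )
    return out
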