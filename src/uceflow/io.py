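"""Readers and writers for the on-disk artifacts the pipeline exchanges.

Coordinate conventions: 0-based half-open everywhere in memory and in BED
output; FASTA headers that carry coordinates report them 1-based inclusive.
The gap character is ``-``; ambiguity codes are IUPAC; ``N`` never counts as
a match anywhere in the toolkit.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastaError(ValueError):
    pass


class AlignmentParseError(ValueError):
    pass


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""


@dataclass
class AlignmentBlock:
    """One pairwise alignment block (MAF ``a``/``s`` pair or 2-row format).

    ``ref_start`` / ``query_start`` are 0-based positions on the forward
    strand of the source sequence; ``strand`` is the query strand.
    """

    ref_name: str
    ref_start: int
    ref_seq: str
    query_name: str
    query_start: int
    query_seq: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.query_seq):
            raise AlignmentParseError(
                f"rows of block {self.ref_name}/{self.query_name} differ in "
                f"length ({len(self.ref_seq)} vs {len(self.query_seq)})"
            )
        if self.ref_start < 0 or self.query_start < 0:
            raise AlignmentParseError("negative alignment start coordinate")
        if self.strand not in "+-":
            raise AlignmentParseError(f"bad strand {self.strand!r}")

    @property
    def ncols(self) -> int:
        return len(self.ref_seq)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file, rejecting duplicate or malformed ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[FastaRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise FastaError(f"{path}: record with empty header")
            if rec.id in seen:
                raise FastaError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = (rec.description[len(rec.id):].strip()
                    if rec.description else "")
            records.append(FastaRecord(rec.id, str(rec.seq), desc))
    except FastaError:
        raise
    except ValueError as exc:
        raise FastaError(f"{path}: malformed header ({exc})") from exc
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path,
                wrap: int | None = 70) -> None:
    records = list(records)
    if not records:
        raise FastaError("refusing to write an empty FASTA file")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            if wrap:
                for i in range(0, len(rec.seq), wrap):
                    fh.write(rec.seq[i:i + wrap] + "\n")
            else:
                fh.write(rec.seq + "\n")


def as_seqrecords(records: Iterable[FastaRecord]) -> list[SeqRecord]:
    return [SeqRecord(Seq(r.seq), id=r.id, description=r.description)
            for r in records]


# ---------------------------------------------------------------------------
# Alignment blocks (MAF subset: a/s lines; or the 2-row TSV block format)


def read_alignment_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Parse pairwise alignment blocks from MAF (a/s lines) or 2-row format.

    The 2-row format is one block per paragraph::

        block <ref_name> <ref_start> <query_name> <query_start> <strand>
        <ref_row>
        <query_row>
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    if not stripped:
        return []
    if stripped.startswith(("a", "#")):
        return _read_maf(text, path)
    if stripped.startswith("block"):
        return _read_two_row(text, path)
    raise AlignmentParseError(f"{path}: unrecognized alignment format")


def _read_maf(text: str, path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    current: list[tuple[str, int, str, str]] = []
    index = 0

    def flush() -> None:
        nonlocal index
        if not current:
            return
        if len(current) != 2:
            raise AlignmentParseError(
                f"{path}: block {index} has {len(current)} 's' rows (need 2)")
        (rn, rs, _, rseq), (qn, qs, qstrand, qseq) = current
        try:
            blocks.append(AlignmentBlock(rn, rs, rseq, qn, qs, qseq, qstrand))
        except AlignmentParseError as exc:
            raise AlignmentParseError(f"{path}: block {index}: {exc}") from exc
        index += 1
        current.clear()

    for line in text.splitlines():
        line = line.rstrip()
        if line.startswith("a"):
            flush()
        elif line.startswith("s"):
            fields = line.split()
            if len(fields) != 7:
                raise AlignmentParseError(
                    f"{path}: block {index}: bad 's' line: {line!r}")
            _, name, start, _size, strand, _srclen, seq = fields
            current.append((name, int(start), strand, seq))
        elif not line or line.startswith(("#", "q", "i", "e")):
            continue
        else:
            raise AlignmentParseError(f"{path}: unexpected line: {line!r}")
    flush()
    return blocks


def _read_two_row(text: str, path) -> list[AlignmentBlock]:
    blocks: list[AlignmentBlock] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) % 3:
        raise AlignmentParseError(f"{path}: truncated 2-row block file")
    for index in range(len(lines) // 3):
        head, ref_row, query_row = lines[3 * index:3 * index + 3]
        fields = head.split()
        if len(fields) != 6 or fields[0] != "block":
            raise AlignmentParseError(
                f"{path}: block {index}: bad header {head!r}")
        _, rn, rs, qn, qs, strand = fields
        try:
            blocks.append(AlignmentBlock(rn, int(rs), ref_row.strip(),
                                         qn, int(qs), query_row.strip(), strand))
        except AlignmentParseError as exc:
            raise AlignmentParseError(f"{path}: block {index}: {exc}") from exc
    return blocks


def write_alignment_blocks(blocks: Iterable[AlignmentBlock],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            ref_len = sum(c != "-" for c in b.ref_seq)
            query_len = sum(c != "-" for c in b.query_seq)
            fh.write("a\n")
            fh.write(f"s {b.ref_name} {b.ref_start} {ref_len} + 0 {b.ref_seq}\n")
            fh.write(f"s {b.query_name} {b.query_start} {query_len} "
                     f"{b.strand} 0 {b.query_seq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(intervals: Iterable[tuple[str, int, int, str]],
              path: str | Path) -> None:
    """Write (chrom, start, end, name) tuples as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        name = fields[3] if len(fields) > 3 else ""
        out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


def write_tsv(rows: Iterable[dict], path: str | Path,
              columns: list[str] | None = None) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0]) if rows else []
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# Packaged per-taxon enrichment statistics fixture

_TABLE1_INT_COLS = ("trimmed_reads", "contigs_assembled", "reads_in_contigs",
                    "uce_contigs", "reads_in_uce_contigs")
_TABLE1_FLOAT_COLS = ("avg_size", "avg_coverage")


def load_table1_fixture() -> list[dict]:
    """Load the packaged 17-taxon read/assembly statistics table.

    Per-taxon sequencing and assembly counts for the fish enrichment
    experiment: trimmed read counts, assembled contig counts, reads placed in
    contigs, contigs matching UCE loci, reads in those contigs, and average
    UCE-contig size (bp) and coverage (fold).
    """
    ref = resources.files("uceflow").joinpath("data/table1.tsv")
    rows: list[dict] = []
    with ref.open() as fh:
        for raw in csv.DictReader(fh, delimiter="\t"):
            row: dict = {"taxon": raw["taxon"]}
            for col in _TABLE1_INT_COLS:
                row[col] = int(raw[col])
            for col in _TABLE1_FLOAT_COLS:
                row[col] = float(raw[col])
            rows.append(row)
    return rows
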