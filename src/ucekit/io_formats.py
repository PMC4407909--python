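"""Readers and writers for the on-disk formats the toolkit touches.

Conventions
-----------
* Coordinates are 0-based half-open everywhere internally and in BED output;
  1-based inclusive ranges appear only in charset/partition files, per
  phylogenetics convention.
* Lowercase residues denote soft-masked repeats and are preserved on
  round-trip.
* The missing-data character in supermatrices is ``?`` (distinct from the
  alignment gap ``-``).
* Minus-strand MAF rows are convertible to plus-strand coordinates via
  ``start' = src_size - start - size``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGTNacgtn")


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """A named DNA sequence; lowercase marks soft-masked repeat residues."""

    seq_id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> "GenomeSequence":
        if len(self.residues) < 1:
            raise FormatError(f"empty sequence body for record {self.seq_id!r}")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.seq_id!r} contains invalid residues: {sorted(bad)}"
            )
        return self

    def normalized(self) -> "GenomeSequence":
        """Replace residues outside A/C/G/T/N (either case) with ``N``."""
        res = "".join(
            c if c in VALID_RESIDUES else ("n" if c.islower() else "N")
            for c in self.residues
        )
        return GenomeSequence(self.seq_id, res)


def _as_handle(source: str | Path | IO[str]) -> IO[str]:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return open(source)
    if isinstance(source, str):
        return io.StringIO(source)
    return source  # already a handle


def read_fasta(
    source: str | Path | IO[str], on_invalid: str = "raise"
) -> list[GenomeSequence]:
    """Read FASTA records as :class:`GenomeSequence`.

    ``on_invalid`` is ``"raise"`` (reject residues outside A/C/G/T/N) or
    ``"normalize"`` (replace them with N, preserving case).
    """
    if on_invalid not in ("raise", "normalize"):
        raise ValueError(f"on_invalid must be 'raise' or 'normalize', got {on_invalid!r}")
    handle = _as_handle(source)
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        gs = GenomeSequence(rec.id, str(rec.seq))
        if len(gs.residues) == 0:
            raise FormatError(f"empty sequence body for record {rec.id!r}")
        records.append(gs.validate() if on_invalid == "raise" else gs.normalized())
    return records


def write_fasta(records: Iterable[GenomeSequence], wrap: int = 60) -> str:
    """Render records as FASTA text with line wrapping (default 60)."""
    out = []
    for rec in records:
        out.append(f">{rec.seq_id}")
        for i in range(0, len(rec.residues), wrap):
            out.append(rec.residues[i : i + wrap])
    return "\n".join(out) + "\n"


def save_fasta(records: Iterable[GenomeSequence], path: str | Path, wrap: int = 60) -> None:
    Path(path).write_text(write_fasta(records, wrap=wrap))


def fasta_index(records: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    idx: dict[str, GenomeSequence] = {}
    for rec in records:
        if rec.seq_id in idx:
            raise FormatError(f"duplicate sequence id {rec.seq_id!r}")
        idx[rec.seq_id] = rec
    return idx


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


@dataclass
class MafRow:
    source: str
    start: int
    size: int
    strand: str
    src_size: int
    text: str

    def non_gap_length(self) -> int:
        return len(self.text) - self.text.count("-")

    def plus_strand_interval(self) -> tuple[int, int]:
        """The row's aligned interval in plus-strand coordinates."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start


@dataclass
class MafBlock:
    rows: list[MafRow]
    score: float | None = None

    def validate(self) -> "MafBlock":
        if not self.rows:
            raise FormatError("MAF block has no sequence rows")
        width = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != width:
                raise FormatError(
                    f"inconsistent row lengths in MAF block "
                    f"({row.source}: {len(row.text)} != {width})"
                )
            if row.non_gap_length() != row.size:
                raise FormatError(
                    f"MAF row {row.source!r}: size field {row.size} does not match "
                    f"{row.non_gap_length()} non-gap characters"
                )
            if row.start + row.size > row.src_size:
                raise FormatError(
                    f"MAF row {row.source!r}: start+size exceeds source size"
                )
        return self

    @property
    def width(self) -> int:
        return len(self.rows[0].text)


def read_maf(
    source: str | Path | IO[str], taxon_map: Mapping[str, str] | None = None
) -> Iterator[MafBlock]:
    """Parse MAF blocks in file order.

    ``taxon_map`` optionally renames each row source ``src`` to
    ``"<taxon>.<src>"`` (the conventional taxon-annotation step applied
    before scanning for conserved regions).
    """
    handle = _as_handle(source)
    rows: list[MafRow] = []
    score: float | None = None

    def flush() -> Iterator[MafBlock]:
        nonlocal rows, score
        if rows:
            yield MafBlock(rows, score).validate()
        rows, score = [], None

    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if line.startswith("#") or not line.strip():
            yield from flush()
            continue
        if line.startswith("a"):
            yield from flush()
            m = re.search(r"score=([-\d.eE+]+)", line)
            score = float(m.group(1)) if m else None
            continue
        if line.startswith("s"):
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(f"malformed 's' line at line {lineno}: {line!r}")
            _, src, start, size, strand, src_size, text = parts
            try:
                row = MafRow(src, int(start), int(size), strand, int(src_size), text)
            except ValueError as exc:
                raise FormatError(f"malformed 's' line at line {lineno}: {exc}") from exc
            if strand not in "+-":
                raise FormatError(f"bad strand {strand!r} at line {lineno}")
            if taxon_map is not None:
                label = taxon_map.get(src) or taxon_map.get(src.split(".")[0])
                if label:
                    row.source = f"{label}.{src}"
            rows.append(row)
            continue
        # i/e/q lines and track lines are ignored
    yield from flush()


def write_maf(blocks: Iterable[MafBlock]) -> str:
    out = ["##maf version=1 scoring=none", ""]
    for block in blocks:
        score = block.score if block.score is not None else 0
        out.append(f"a score={score}")
        width = max(len(r.source) for r in block.rows)
        for r in block.rows:
            out.append(
                f"s {r.source:<{width}} {r.start} {r.size} {r.strand} {r.src_size} {r.text}"
            )
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass
class BedInterval:
    """0-based half-open genomic interval (BED4)."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid BED interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def read_bed(source: str | Path | IO[str]) -> list[BedInterval]:
    handle = _as_handle(source)
    intervals = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"malformed BED line {lineno}: {line!r}")
        name = parts[3] if len(parts) > 3 else "."
        intervals.append(BedInterval(parts[0], int(parts[1]), int(parts[2]), name))
    return intervals


def write_bed(intervals: Iterable[BedInterval]) -> str:
    return (
        "\n".join(f"{b.chrom}\t{b.start}\t{b.end}\t{b.name}" for b in intervals) + "\n"
    )


def extract_interval(genome: Mapping[str, GenomeSequence], interval: BedInterval) -> str:
    """Slice a genome with a BED interval, reproducing the region's residues."""
    try:
        seq = genome[interval.chrom]
    except KeyError:
        raise FormatError(f"BED chrom {interval.chrom!r} not in genome") from None
    if interval.end > len(seq):
        raise FormatError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} "
            f"beyond sequence end ({len(seq)})"
        )
    return seq.residues[interval.start : interval.end]


# ---------------------------------------------------------------------------
# PHYLIP / charsets / NEXUS (supermatrix output)
# ---------------------------------------------------------------------------


def write_phylip(supermatrix) -> str:
    """Relaxed PHYLIP: header ``ntaxa nchar``, one taxon per line."""
    taxa = list(supermatrix.taxa)
    rows = supermatrix.rows
    lengths = {len(rows[t]) for t in taxa}
    if len(lengths) > 1:
        raise FormatError(f"ragged supermatrix rows: lengths {sorted(lengths)}")
    nchar = lengths.pop() if lengths else 0
    width = max((len(t) for t in taxa), default=0)
    out = [f"{len(taxa)} {nchar}"]
    for t in taxa:
        out.append(f"{t:<{width}}  {rows[t]}")
    return "\n".join(out) + "\n"


def read_phylip(source: str | Path | IO[str]) -> dict[str, str]:
    handle = _as_handle(source)
    header = handle.readline().split()
    if len(header) != 2:
        raise FormatError("missing PHYLIP header")
    ntax, nchar = int(header[0]), int(header[1])
    rows: dict[str, str] = {}
    for line in handle:
        if not line.strip():
            continue
        name, seq = line.split(None, 1)
        rows[name] = seq.strip()
    if len(rows) != ntax or any(len(s) != nchar for s in rows.values()):
        raise FormatError("PHYLIP body does not match header dimensions")
    return rows


def write_charsets(supermatrix) -> str:
    """One ``charset`` line per locus, 1-based inclusive, concatenation order."""
    return (
        "\n".join(
            f"charset {locus} = {start}-{end};"
            for locus, (start, end) in supermatrix.charsets
        )
        + "\n"
    )


def write_raxml_partitions(supermatrix) -> str:
    """RAxML-style partition file: ``DNA, uce-N = a-b``."""
    return (
        "\n".join(
            f"DNA, {locus} = {start}-{end}"
            for locus, (start, end) in supermatrix.charsets
        )
        + "\n"
    )


def write_nexus(rows: Mapping[str, str], charsets: Sequence[tuple[str, tuple[int, int]]] | None = None) -> str:
    """Minimal NEXUS DATA block (plus an optional SETS block of charsets)."""
    taxa = list(rows)
    nchar = len(next(iter(rows.values()))) if rows else 0
    if any(len(rows[t]) != nchar for t in taxa):
        raise FormatError("ragged alignment rows")
    width = max((len(t) for t in taxa), default=0)
    out = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={len(taxa)} NCHAR={nchar};",
        "  FORMAT DATATYPE=DNA GAP=- MISSING=?;",
        "  MATRIX",
    ]
    for t in taxa:
        out.append(f"    {t:<{width}}  {rows[t]}")
    out += ["  ;", "END;"]
    if charsets:
        out.append("BEGIN SETS;")
        for locus, (start, end) in charsets:
            out.append(f"  CHARSET {locus} = {start}-{end};")
        out.append("END;")
    return "\n".join(out) + "\n"


def read_nexus(source: str | Path | IO[str]) -> dict[str, str]:
    """Parse the toolkit's own minimal NEXUS output back to rows."""
    handle = _as_handle(source)
    text = handle.read()
    if not text.lstrip().upper().startswith("#NEXUS"):
        raise FormatError("not a NEXUS file")
    m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not m:
        raise FormatError("no MATRIX block found")
    rows: dict[str, str] = {}
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        name, seq = line.split(None, 1)
        rows[name] = seq.strip()
    return rows
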