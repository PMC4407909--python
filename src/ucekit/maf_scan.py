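"""Detect perfectly conserved regions in MAF alignment blocks.

A conserved region is a maximal run of alignment columns in which every row
carries the identical nucleotide (case-insensitive).  Gap columns and
columns containing ``N`` or any ambiguity code break runs: perfect
conservation cannot be asserted through gaps or unknown bases.  Runs are
kept when strictly longer than ``min_len`` (the conventional cutoff of
"longer than 40 bp"), and reported in plus-strand coordinates on the first
row's source sequence.

Soft-mask case is ignored for the identity comparison, but regions whose
residues are more than 25% lowercase in the first row are flagged
(``repeat_flag``) so the bait-design stage can apply its repeat filter;
they are not discarded here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import BedInterval, MafBlock

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclass
class ConservedRegion:
    """A 100%-conserved interval on a named source sequence (plus strand)."""

    source_taxon: str
    chrom: str
    start: int
    end: int
    residues: str
    origin_block: int = 0
    repeat_flag: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def to_bed(self) -> BedInterval:
        return BedInterval(self.chrom, self.start, self.end, self.name)


def _split_source(source: str) -> tuple[str, str]:
    """Split ``taxon.chrom`` annotation; sources without a dot have no taxon."""
    if "." in source:
        taxon, chrom = source.split(".", 1)
        return taxon, chrom
    return "", source


def find_conserved(
    block: MafBlock, min_len: int = 40, origin_block: int = 0
) -> list[ConservedRegion]:
    """Maximal fully conserved column runs of length > ``min_len`` in a block.

    Coordinates are reported on the first row's source, converted to the
    plus strand.  Raises ``ValueError`` for single-row blocks, which offer
    nothing to compare.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    if len(block.rows) < 2:
        raise ValueError("nothing to compare: MAF block has fewer than 2 rows")

    texts = [np.frombuffer(r.text.upper().encode("ascii"), dtype=np.uint8) for r in block.rows]
    first = texts[0]
    ok = np.isin(first, np.frombuffer(b"ACGT", dtype=np.uint8))
    for other in texts[1:]:
        ok &= other == first
        ok &= np.isin(other, np.frombuffer(b"ACGT", dtype=np.uint8))

    row0 = block.rows[0]
    raw0 = row0.text
    # strand-space position of each column on row 0 (gap columns never
    # enter a run, so their positions are irrelevant)
    non_gap = np.frombuffer(raw0.encode("ascii"), dtype=np.uint8) != ord("-")
    pos = np.cumsum(non_gap) - 1 + row0.start

    taxon, chrom = _split_source(row0.source)
    regions: list[ConservedRegion] = []
    # maximal runs of True in ok
    padded = np.concatenate(([False], ok, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for c0, c1 in zip(edges[::2], edges[1::2]):  # half-open column spans
        if c1 - c0 <= min_len:
            continue
        s, e = int(pos[c0]), int(pos[c1 - 1]) + 1
        if row0.strand == "-":
            s, e = row0.src_size - e, row0.src_size - s
        run_raw = raw0[c0:c1]
        lower = sum(c.islower() for c in run_raw)
        regions.append(
            ConservedRegion(
                source_taxon=taxon,
                chrom=chrom,
                start=s,
                end=e,
                residues=run_raw.upper(),
                origin_block=origin_block,
                repeat_flag=lower / (c1 - c0) > 0.25,
            )
        )
    return regions


def scan_alignment(
    blocks: Iterable[MafBlock], min_len: int = 40
) -> list[ConservedRegion]:
    """Scan blocks in order, collapsing regions with identical coordinates."""
    seen: dict[tuple[str, str, int, int], ConservedRegion] = {}
    n_blocks = 0
    for i, block in enumerate(blocks):
        n_blocks += 1
        for region in find_conserved(block, min_len=min_len, origin_block=i):
            key = (region.source_taxon, region.chrom, region.start, region.end)
            seen.setdefault(key, region)
    regions = sorted(seen.values(), key=lambda r: (r.source_taxon, r.chrom, r.start))
    logger.info("stage=scan in=%d out=%d", n_blocks, len(regions))
    return regions


def regions_to_bed(regions: Sequence[ConservedRegion]) -> list[BedInterval]:
    return [r.to_bed() for r in regions]
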