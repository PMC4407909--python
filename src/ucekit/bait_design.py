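"""Buffer conserved regions, tile enrichment baits, filter, and dedupe.

The design pipeline takes the deduplicated conserved regions and the
soft-masked design genome and produces the final bait set:

1. **buffer** — regions shorter than the target length (default 180 bp) are
   padded with equal 5' and 3' flanking genome sequence (odd remainder goes
   3'), clamped at sequence ends with the deficit shifted to the other side
   where possible;
2. **tile** — 120-nt baits at 2X tiling density (60-bp stride); when a locus
   length is not exactly tileable, one extra bait is placed flush with the
   3' end so the whole locus is covered;
3. **filter** — baits containing ambiguous bases, more than 25% soft-masked
   (lowercase) sequence, or more than 70% GC are dropped (strict
   inequalities);
4. **dedupe** — byte-identical baits are collapsed (keeping the lowest locus
   number, then lowest bait index) and cross-locus near-duplicate baits are
   removed pairwise; neighbouring baits of the same locus are exempt, since
   2X tiling guarantees they overlap by half their length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import seqmatch
from ._util import gc_fraction, lowercase_fraction
from .io_formats import BedInterval, GenomeSequence
from .maf_scan import ConservedRegion

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = frozenset("ACGTacgt")
_LOCUS_ID_RE = re.compile(r"^(?P<stem>.*?)(?P<num>\d+)$")


@dataclass
class Locus:
    """A buffered target region on the design genome."""

    locus_id: str  # "uce-N"
    chrom: str
    start: int
    end: int
    residues: str  # case-preserving slice of the design genome
    clamped: bool = False  # buffering hit a sequence end and fell short

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Bait:
    """A fixed-length probe tied to a locus, with design-genome coordinates."""

    bait_id: str  # "uce-N_pK"
    locus_id: str
    index: int  # K >= 1
    residues: str  # case-preserving; uppercase on FASTA output
    chrom: str
    start: int
    end: int


def locus_number(locus_id: str) -> int:
    """Trailing integer of a locus id ("uce-17" -> 17), for ordering."""
    m = _LOCUS_ID_RE.match(locus_id)
    if not m:
        raise ValueError(f"cannot parse a locus number from {locus_id!r}")
    return int(m.group("num"))


def buffer_region(
    region: ConservedRegion | BedInterval,
    genome: GenomeSequence,
    target_len: int = 180,
    locus_id: str | None = None,
) -> Locus:
    """Pad a region to ``target_len`` with flanking genome sequence.

    Regions already at or above the target length pass through unchanged.
    The pad is split equally 5'/3'; an odd remainder's extra base goes 3'.
    At sequence ends the deficit shifts to the other side when possible;
    a locus that still cannot reach the target is flagged ``clamped``.
    """
    chrom = region.chrom
    start, end = region.start, region.end
    if end > len(genome):
        raise ValueError(
            f"region {chrom}:{start}-{end} lies outside genome ({len(genome)} bp)"
        )
    if locus_id is None:
        locus_id = getattr(region, "name", f"{chrom}:{start}-{end}")
    length = end - start
    if length < target_len:
        deficit = target_len - length
        pad5 = deficit // 2
        pad3 = deficit - pad5  # odd remainder's extra base goes 3'
        new_start = start - pad5
        new_end = end + pad3
        if new_start < 0:  # shift the unmet 5' deficit to the 3' side
            new_end += -new_start
            new_start = 0
        if new_end > len(genome):  # and vice versa
            new_start -= new_end - len(genome)
            new_end = len(genome)
        new_start = max(new_start, 0)
        start, end = new_start, new_end
    clamped = end - start < target_len
    return Locus(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=end,
        residues=genome.residues[start:end],
        clamped=clamped,
    )


def tile(locus: Locus, bait_len: int = 120, stride: int = 60) -> list[Bait]:
    """Tile baits across a locus at fixed stride (2X density by default).

    Offsets run 0, stride, 2*stride, ... while a full bait fits; if the last
    tiled bait stops short of the locus 3' end, one additional bait is placed
    flush with that end.  Loci shorter than ``bait_len`` yield no baits.
    """
    L = locus.length
    if L < bait_len:
        logger.info("stage=tile locus=%s dropped: length %d < bait %d", locus.locus_id, L, bait_len)
        return []
    offsets = list(range(0, L - bait_len + 1, stride))
    if offsets[-1] + bait_len < L:
        offsets.append(L - bait_len)  # flush with the 3' end
    baits = []
    for k, off in enumerate(offsets, start=1):
        baits.append(
            Bait(
                bait_id=f"{locus.locus_id}_p{k}",
                locus_id=locus.locus_id,
                index=k,
                residues=locus.residues[off : off + bait_len],
                chrom=locus.chrom,
                start=locus.start + off,
                end=locus.start + off + bait_len,
            )
        )
    return baits


def filter_bait(
    bait: Bait, max_gc: float = 0.70, max_repeat: float = 0.25
) -> tuple[bool, set[str]]:
    """Apply the three bait-level filters; reasons name every violated rule.

    * ``ambiguity`` — any residue outside A/C/G/T (either case);
    * ``repeat`` — soft-masked (lowercase) fraction strictly above
      ``max_repeat``;
    * ``gc`` — case-insensitive GC fraction strictly above ``max_gc``.
    """
    reasons: set[str] = set()
    if any(c not in _UNAMBIGUOUS for c in bait.residues):
        reasons.add("ambiguity")
    if lowercase_fraction(bait.residues) > max_repeat:
        reasons.add("repeat")
    if gc_fraction(bait.residues) > max_gc:
        reasons.add("gc")
    return (not reasons, reasons)


def dedupe_baits(
    baits: Sequence[Bait],
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
) -> tuple[list[Bait], list[Bait]]:
    """Collapse identical baits; remove cross-locus near-duplicate pairs.

    Exact sequence duplicates (case-insensitive) keep the copy with the
    lowest locus number, then lowest index.  Near-duplicates (identity and
    bait coverage strictly above the thresholds, either strand) from
    *different* loci are both removed; pairs from the same locus are exempt
    — 2X tiling makes neighbours overlap by exactly half their length.
    """
    ids = [b.bait_id for b in baits]
    if len(set(ids)) != len(ids):
        raise ValueError("bait ids are not unique")

    def rank(b: Bait) -> tuple[int, int]:
        return (locus_number(b.locus_id), b.index)

    # 1. exact duplicate collapse
    by_seq: dict[str, Bait] = {}
    removed: list[Bait] = []
    for b in sorted(baits, key=rank):
        key = b.residues.upper()
        if key in by_seq:
            removed.append(b)
        else:
            by_seq[key] = b
    survivors = [b for b in baits if b not in removed]

    # 2. cross-locus near-duplicate screen (both members removed)
    near_removed: set[str] = set()
    ordered = sorted(survivors, key=rank)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a.locus_id == b.locus_id:
                continue  # same-locus exemption
            if seqmatch._pair_is_duplicate(
                a.residues, b.residues, min_identity, min_coverage, basis="shorter"
            ):
                near_removed.add(a.bait_id)
                near_removed.add(b.bait_id)
    kept = [b for b in survivors if b.bait_id not in near_removed]
    removed += [b for b in survivors if b.bait_id in near_removed]
    return kept, removed


def assign_locus_ids(
    regions: Sequence[ConservedRegion], prefix: str = "uce-"
) -> list[tuple[str, ConservedRegion]]:
    """Number regions "uce-1", "uce-2", ... in genome order."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    return [(f"{prefix}{i}", r) for i, r in enumerate(ordered, start=1)]


def design_pipeline(
    regions: Sequence[ConservedRegion],
    genome: Mapping[str, GenomeSequence],
    target_len: int = 180,
    bait_len: int = 120,
    stride: int = 60,
    max_gc: float = 0.70,
    max_repeat: float = 0.25,
    dedupe_identity: float = 0.80,
    dedupe_coverage: float = 0.50,
    locus_prefix: str = "uce-",
) -> tuple[list[Locus], list[Bait], dict]:
    """Run buffer -> tile -> filter -> dedupe and report stage counts.

    Loci with zero surviving baits are dropped from the returned locus list
    and recorded in the report.  An empty conserved set yields an empty bait
    set (with a warning), not an error.
    """
    report: dict = {"n_regions": len(regions)}
    if not regions:
        logger.warning("stage=design in=0 out=0 (empty conserved set)")
        report.update(n_loci=0, n_baits_tiled=0, n_baits_filtered=0, n_baits_final=0, dropped_loci=[])
        return [], [], report

    loci: list[Locus] = []
    for locus_id, region in assign_locus_ids(regions, prefix=locus_prefix):
        if region.chrom not in genome:
            raise ValueError(f"region chrom {region.chrom!r} not in design genome")
        loci.append(buffer_region(region, genome[region.chrom], target_len, locus_id=locus_id))
    report["n_loci"] = len(loci)
    report["n_clamped"] = sum(l.clamped for l in loci)

    tiled: list[Bait] = []
    for locus in loci:
        tiled.extend(tile(locus, bait_len=bait_len, stride=stride))
    report["n_baits_tiled"] = len(tiled)

    passed: list[Bait] = []
    fail_reasons: dict[str, int] = {}
    for bait in tiled:
        ok, reasons = filter_bait(bait, max_gc=max_gc, max_repeat=max_repeat)
        if ok:
            passed.append(bait)
        else:
            for r in reasons:
                fail_reasons[r] = fail_reasons.get(r, 0) + 1
    report["n_baits_filtered"] = len(passed)
    report["filter_failures"] = fail_reasons

    final, dropped = dedupe_baits(passed, min_identity=dedupe_identity, min_coverage=dedupe_coverage)
    report["n_baits_final"] = len(final)

    surviving_loci = {b.locus_id for b in final}
    kept_loci = [l for l in loci if l.locus_id in surviving_loci]
    report["dropped_loci"] = sorted(
        (l.locus_id for l in loci if l.locus_id not in surviving_loci),
        key=locus_number,
    )
    logger.info(
        "stage=design in=%d out=%d (loci %d -> %d)",
        len(regions), len(final), len(loci), len(kept_loci),
    )
    return kept_loci, final, report


def baits_to_fasta_records(baits: Iterable[Bait]) -> list[GenomeSequence]:
    """Bait records for FASTA output: uppercase, coordinate-annotated ids."""
    return [
        GenomeSequence(
            f"{b.bait_id} |{b.chrom}:{b.start}-{b.end}", b.residues.upper()
        )
        for b in baits
    ]


def loci_to_bed(loci: Iterable[Locus]) -> list[BedInterval]:
    return [BedInterval(l.chrom, l.start, l.end, l.locus_id) for l in loci]
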