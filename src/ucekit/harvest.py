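"""Match contigs or genome slices to the bait set and track locus status.

Orthology enforcement follows the standard capture bookkeeping rules,
applied per taxon:

1. a contig hit by baits targeting two or more distinct loci is removed
   entirely (``multi-locus``: likely chimeric or repetitive);
2. a locus hit by two or more surviving contigs is marked absent for that
   taxon (``duplicate-contig``: ambiguous orthology);
3. survivors populate a relational match database with two tables — locus
   presence/absence per taxon, and the contig name backing each credited
   (locus, taxon) pair.

Coverage is measured on the bait: contigs legitimately extend far beyond
the 120-nt probes that pull them down.
"""

from __future__ import annotations

import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import seqmatch
from ._util import completeness_threshold, revcomp
from .io_formats import GenomeSequence

logger = logging.getLogger(__name__)

_BAIT_ID_RE = re.compile(r"^(?P<locus>.+)_p(?P<index>\d+)$")


def bait_locus(bait_id: str) -> str:
    """Locus id encoded in a bait id ("uce-3_p2" -> "uce-3")."""
    m = _BAIT_ID_RE.match(bait_id)
    if not m:
        raise ValueError(f"bait id {bait_id!r} does not encode a locus (expected '<locus>_pK')")
    return m.group("locus")


@dataclass
class MatchRecord:
    taxon: str
    contig_id: str
    locus_id: str
    identity: float
    coverage: float  # on the bait
    strand: str


@dataclass
class MatchDatabase:
    """Locus x taxon presence plus contig-name mapping and a removal log.

    Invariants: at most one contig per (locus, taxon); a contig appears
    under at most one locus within a taxon.
    """

    presence: dict[str, set[str]] = field(default_factory=dict)  # locus -> taxa
    name_map: dict[tuple[str, str], str] = field(default_factory=dict)
    removal_log: list[tuple[str, str, str]] = field(default_factory=list)
    taxa: set[str] = field(default_factory=set)

    def add(self, taxon: str, locus: str, contig_id: str) -> None:
        if (locus, taxon) in self.name_map:
            raise ValueError(f"(locus={locus}, taxon={taxon}) already has a contig")
        for (l, t), c in self.name_map.items():
            if t == taxon and c == contig_id and l != locus:
                raise ValueError(
                    f"contig {contig_id!r} already mapped to {l} in taxon {taxon}"
                )
        self.presence.setdefault(locus, set()).add(taxon)
        self.name_map[(locus, taxon)] = contig_id
        self.taxa.add(taxon)

    def log_removal(self, taxon: str, name: str, reason: str) -> None:
        self.removal_log.append((taxon, name, reason))
        self.taxa.add(taxon)

    def is_present(self, locus: str, taxon: str) -> bool:
        return taxon in self.presence.get(locus, set())

    def loci(self) -> list[str]:
        return sorted(self.presence)

    # -- persistence (two-table relational file) ---------------------------

    def to_sqlite(self, path: str | Path) -> None:
        con = sqlite3.connect(str(path))
        try:
            con.executescript(
                """
                DROP TABLE IF EXISTS match_status;
                DROP TABLE IF EXISTS match_map;
                DROP TABLE IF EXISTS removal_log;
                CREATE TABLE match_status (locus TEXT, taxon TEXT, present INTEGER,
                                           PRIMARY KEY (locus, taxon));
                CREATE TABLE match_map (locus TEXT, taxon TEXT, contig TEXT,
                                        PRIMARY KEY (locus, taxon));
                CREATE TABLE removal_log (taxon TEXT, name TEXT, reason TEXT);
                """
            )
            loci = sorted(set(self.presence))
            for locus in loci:
                for taxon in sorted(self.taxa):
                    con.execute(
                        "INSERT INTO match_status VALUES (?, ?, ?)",
                        (locus, taxon, int(self.is_present(locus, taxon))),
                    )
            for (locus, taxon), contig in sorted(self.name_map.items()):
                con.execute("INSERT INTO match_map VALUES (?, ?, ?)", (locus, taxon, contig))
            for row in self.removal_log:
                con.execute("INSERT INTO removal_log VALUES (?, ?, ?)", row)
            con.commit()
        finally:
            con.close()

    @classmethod
    def from_sqlite(cls, path: str | Path) -> "MatchDatabase":
        con = sqlite3.connect(str(path))
        try:
            db = cls()
            for locus, taxon, present in con.execute("SELECT * FROM match_status"):
                db.taxa.add(taxon)
                if present:
                    db.presence.setdefault(locus, set()).add(taxon)
            for locus, taxon, contig in con.execute("SELECT * FROM match_map"):
                db.name_map[(locus, taxon)] = contig
            for row in con.execute("SELECT * FROM removal_log"):
                db.removal_log.append(tuple(row))
            return db
        finally:
            con.close()


def _bait_pairs(baits) -> list[tuple[str, str]]:
    """Normalize a bait collection to (bait_id, residues) pairs."""
    pairs = []
    for b in baits:
        if isinstance(b, tuple):
            bait_id, seq = b
        else:
            bait_id = getattr(b, "bait_id", None) or getattr(b, "seq_id")
            seq = getattr(b, "residues")
        bait_id = str(bait_id).split()[0]
        bait_locus(bait_id)  # raises if unparseable
        pairs.append((bait_id, str(seq)))
    return pairs


def match_contigs_to_loci(
    contigs_by_taxon: Mapping[str, Sequence[GenomeSequence]],
    baits,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    seed_k: int | None = 12,
) -> tuple[MatchDatabase, list[MatchRecord]]:
    """Screen per-taxon contigs against the bait set and build the database.

    Matching requires the bait's best local alignment on the contig to be at
    least ``min_identity`` identical over at least ``min_coverage`` of the
    bait length (either strand).  Multiple baits of one locus hitting one
    contig count as a single locus-level match with the best identity
    retained.
    """
    bait_pairs = _bait_pairs(baits)
    db = MatchDatabase()
    records: list[MatchRecord] = []

    for taxon in sorted(contigs_by_taxon):
        db.taxa.add(taxon)
        # contig -> locus -> best MatchRecord
        hits: dict[str, dict[str, MatchRecord]] = {}
        contigs = list(contigs_by_taxon[taxon])
        for contig in contigs:
            for bait_id, bait_seq in bait_pairs:
                found = seqmatch.local_matches(
                    bait_id,
                    bait_seq,
                    [(contig.seq_id, contig.residues)],
                    min_identity=min_identity,
                    min_coverage=min_coverage,
                    coverage_basis="query",
                    seed_k=seed_k,
                )
                for m in found:
                    locus = bait_locus(bait_id)
                    rec = MatchRecord(
                        taxon, contig.seq_id, locus, m.identity,
                        (m.query_span[1] - m.query_span[0]) / len(bait_seq), m.strand,
                    )
                    best = hits.setdefault(contig.seq_id, {})
                    if locus not in best or rec.identity > best[locus].identity:
                        best[locus] = rec

        # rule 1: contigs hit by baits of >= 2 distinct loci are removed
        surviving: dict[str, list[MatchRecord]] = {}
        for contig_id in sorted(hits):
            per_locus = hits[contig_id]
            if len(per_locus) >= 2:
                db.log_removal(taxon, contig_id, "multi-locus")
                continue
            ((locus, rec),) = per_locus.items()
            records.append(rec)
            surviving.setdefault(locus, []).append(rec)

        # rule 2: loci matched by >= 2 surviving contigs are absent
        for locus in sorted(surviving):
            recs = surviving[locus]
            if len(recs) >= 2:
                for r in sorted(recs, key=lambda r: r.contig_id):
                    db.log_removal(taxon, r.contig_id, "duplicate-contig")
            else:
                db.add(taxon, locus, recs[0].contig_id)

        n_present = sum(1 for l, taxa in db.presence.items() if taxon in taxa)
        logger.info("stage=harvest taxon=%s in=%d out=%d", taxon, len(contigs), n_present)
    return db, records


def slice_from_genome(
    genome: Sequence[GenomeSequence],
    baits,
    flank: int = 1000,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    seed_k: int | None = 12,
    cluster_gap: int = 100,
    on_multiple_sites: str = "drop",
) -> tuple[list[GenomeSequence], list[tuple[str, str]]]:
    """Slice each locus (+- ``flank``) from a genome assembly.

    Bait hits of one locus are clustered by (sequence, strand) with hits
    closer than ``cluster_gap`` merged into one genomic site.  A locus
    matching two or more distinct sites is dropped and logged (first-pass
    duplicate removal); ``on_multiple_sites="best"`` instead keeps the
    site with the highest best-bait identity.  Minus-strand slices are
    reverse-complemented into bait orientation.  Slices are clamped at
    sequence ends.

    Returns (slices, dropped_log) where dropped_log holds
    ``(locus, reason)`` tuples.
    """
    if on_multiple_sites not in ("drop", "best"):
        raise ValueError("on_multiple_sites must be 'drop' or 'best'")
    bait_pairs = _bait_pairs(baits)
    targets = [(g.seq_id, g.residues) for g in genome]
    genome_idx = {g.seq_id: g for g in genome}

    # locus -> list of (chrom, strand, start, end, identity); every disjoint
    # genomic site counts, not just the best per sequence
    locus_hits: dict[str, list[tuple[str, str, int, int, float]]] = {}
    for bait_id, bait_seq in bait_pairs:
        locus = bait_locus(bait_id)
        if seed_k:
            seeds = seqmatch._kmers(bait_seq, seed_k) | seqmatch._kmers(
                revcomp(bait_seq), seed_k
            )
        for target_id, target_seq in targets:
            if seed_k and not (seeds & seqmatch._kmers(target_seq, seed_k)):
                continue
            for m in seqmatch.site_matches(
                bait_id, bait_seq, target_id, target_seq,
                min_identity=min_identity, min_coverage=min_coverage,
                coverage_basis="query",
            ):
                locus_hits.setdefault(locus, []).append(
                    (m.target_id, m.strand, m.target_span[0], m.target_span[1], m.identity)
                )

    slices: list[GenomeSequence] = []
    dropped: list[tuple[str, str]] = []
    for locus in sorted(locus_hits):
        # cluster hits into genomic sites
        clusters: list[dict] = []
        for chrom, strand, s, e, ident in sorted(locus_hits[locus]):
            placed = False
            for cl in clusters:
                if (
                    cl["chrom"] == chrom
                    and cl["strand"] == strand
                    and s <= cl["end"] + cluster_gap
                    and e >= cl["start"] - cluster_gap
                ):
                    cl["start"] = min(cl["start"], s)
                    cl["end"] = max(cl["end"], e)
                    cl["identity"] = max(cl["identity"], ident)
                    placed = True
                    break
            if not placed:
                clusters.append(
                    {"chrom": chrom, "strand": strand, "start": s, "end": e, "identity": ident}
                )
        if len(clusters) > 1:
            if on_multiple_sites == "drop":
                dropped.append((locus, f"multiple-genomic-sites({len(clusters)})"))
                logger.info("stage=slice locus=%s dropped: %d sites", locus, len(clusters))
                continue
            clusters = [max(clusters, key=lambda c: c["identity"])]
        cl = clusters[0]
        seq = genome_idx[cl["chrom"]]
        s = max(cl["start"] - flank, 0)
        e = min(cl["end"] + flank, len(seq))
        residues = seq.residues[s:e]
        if cl["strand"] == "-":
            residues = revcomp(residues)
        slices.append(GenomeSequence(locus, residues))
    logger.info("stage=slice in=%d out=%d", len(locus_hits), len(slices))
    return slices, dropped


def get_match_counts(
    db: MatchDatabase, taxa: Sequence[str], min_fraction: float
) -> list[str]:
    """Loci present in at least ``ceil(min_fraction * |taxa|)`` listed taxa."""
    unknown = [t for t in taxa if t not in db.taxa]
    if unknown:
        raise ValueError(f"unknown taxa: {unknown}")
    threshold = completeness_threshold(min_fraction, len(taxa))
    out = [
        locus
        for locus in db.loci()
        if sum(db.is_present(locus, t) for t in taxa) >= threshold
    ]
    logger.info(
        "stage=counts in=%d out=%d (threshold %d of %d)",
        len(db.loci()), len(out), threshold, len(taxa),
    )
    return sorted(out)


def get_fastas(
    db: MatchDatabase,
    sequences: Mapping[str, Mapping[str, str]],
    loci: Sequence[str],
) -> list[GenomeSequence]:
    """Monolithic FASTA records "<locus>_<taxon>", locus-major then taxon.

    ``sequences`` maps taxon -> contig_id -> residues; each credited
    (locus, taxon) pair must be retrievable through the database name map.
    """
    records: list[GenomeSequence] = []
    for locus in loci:
        for taxon in sorted(db.taxa):
            if not db.is_present(locus, taxon):
                continue
            contig_id = db.name_map.get((locus, taxon))
            if contig_id is None or contig_id not in sequences.get(taxon, {}):
                raise ValueError(
                    f"no sequence retrievable for credited pair ({locus}, {taxon})"
                )
            records.append(GenomeSequence(f"{locus}_{taxon}", sequences[taxon][contig_id]))
    return records
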