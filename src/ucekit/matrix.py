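"""Per-locus alignment bookkeeping and supermatrix concatenation.

Completeness filtering keeps loci present in at least ``ceil(fraction * N)``
of the N taxa under study (e.g. a 70% complete matrix over 14 taxa keeps
loci with at least 10 taxa; 75% over 44 requires 33).  Parsimony-informative
sites are counted with gaps, ``?`` and IUPAC ambiguity codes treated as
missing data — a column is informative when at least two distinct
unambiguous states are each carried by at least two taxa.

Multiple sequence alignment itself, and production-grade alignment
trimming, are external steps: this module consumes per-locus aligned FASTA.
``edge_trim`` is a simple sliding-window fallback for untrimmed input and
is not equivalent to dedicated trimming tools.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._util import completeness_threshold

logger = logging.getLogger(__name__)

MISSING_CHAR = "?"
_STATES = b"ACGT"


@dataclass
class LocusAlignment:
    """One locus's multiple alignment: taxon -> aligned residues."""

    locus_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"alignment {self.locus_id}: fewer than 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"alignment {self.locus_id}: ragged rows {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_taxa(self) -> int:
        return len(self.rows)


@dataclass
class Supermatrix:
    """Concatenated loci with 1-based inclusive charset bookkeeping."""

    taxa: list[str]
    rows: dict[str, str]
    charsets: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def extract(self, locus_id: str) -> dict[str, str]:
        """Rows of one charset, omitting taxa that are entirely missing."""
        for locus, (start, end) in self.charsets:
            if locus == locus_id:
                out = {}
                for taxon in self.taxa:
                    piece = self.rows[taxon][start - 1 : end]
                    if set(piece) != {MISSING_CHAR}:
                        out[taxon] = piece
                return out
        raise KeyError(f"no charset named {locus_id!r}")


def min_taxa_filter(
    alignments: Sequence[LocusAlignment], n_taxa_total: int, fraction: float
) -> list[LocusAlignment]:
    """Keep alignments with at least ``ceil(fraction * n_taxa_total)`` taxa."""
    threshold = completeness_threshold(fraction, n_taxa_total)
    kept = [a for a in alignments if a.n_taxa >= threshold]
    logger.info(
        "stage=min_taxa_filter in=%d out=%d (threshold %d of %d)",
        len(alignments), len(kept), threshold, n_taxa_total,
    )
    return kept


def _state_matrix(rows: Iterable[str]) -> np.ndarray:
    return np.array([np.frombuffer(r.upper().encode("ascii"), dtype=np.uint8) for r in rows])


def informative_sites(alignment: LocusAlignment | Mapping[str, str]) -> int:
    """Count parsimony-informative columns.

    A column is informative when at least two distinct unambiguous states
    (A/C/G/T) each occur in at least two rows.  Everything else — gaps,
    ``?``, N and other ambiguity codes — is missing data, never a state.
    """
    rows = alignment.rows if isinstance(alignment, LocusAlignment) else alignment
    mat = _state_matrix(rows.values())
    counts = np.stack([(mat == s).sum(axis=0) for s in _STATES])  # 4 x ncols
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def summary_stats(alignments: Sequence[LocusAlignment]):
    """Per-locus table plus overall mean length with a 95% CI half-width.

    The half-width is ``1.96 * sd / sqrt(n)`` with the sample (n-1) standard
    deviation; a single alignment reports 0 with ``ci_flag`` set.
    """
    import pandas as pd

    if not alignments:
        raise ValueError("no alignments to summarize")
    per_locus = pd.DataFrame(
        {
            "locus": [a.locus_id for a in alignments],
            "length": [a.length for a in alignments],
            "n_taxa": [a.n_taxa for a in alignments],
            "informative_sites": [informative_sites(a) for a in alignments],
        }
    )
    n = len(alignments)
    lengths = per_locus["length"].to_numpy(dtype=float)
    ci_flag = n == 1
    half_width = 0.0 if ci_flag else 1.96 * lengths.std(ddof=1) / np.sqrt(n)
    overall = {
        "n_alignments": n,
        "mean_length": float(lengths.mean()),
        "ci95_half_width": float(half_width),
        "ci_flag": ci_flag,
        "mean_taxa": float(per_locus["n_taxa"].mean()),
        "total_informative_sites": int(per_locus["informative_sites"].sum()),
    }
    return per_locus, overall


def concat(
    alignments: Sequence[LocusAlignment], taxa_universe: Sequence[str]
) -> Supermatrix:
    """Concatenate loci (lexicographic id order) over a fixed taxon set.

    Taxa absent from a locus are filled with ``?`` across that charset.
    """
    taxa = list(taxa_universe)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels in taxa_universe")
    ordered = sorted(alignments, key=lambda a: a.locus_id)
    ids = [a.locus_id for a in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus ids")
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    charsets: list[tuple[str, tuple[int, int]]] = []
    offset = 0
    for aln in ordered:
        extra = set(aln.rows) - set(taxa)
        if extra:
            raise ValueError(
                f"alignment {aln.locus_id} has taxa outside the universe: {sorted(extra)}"
            )
        L = aln.length
        for t in taxa:
            pieces[t].append(aln.rows.get(t, MISSING_CHAR * L))
        charsets.append((aln.locus_id, (offset + 1, offset + L)))
        offset += L
    sm = Supermatrix(taxa=taxa, rows={t: "".join(pieces[t]) for t in taxa}, charsets=charsets)
    logger.info("stage=concat in=%d out=%d sites", len(alignments), sm.length)
    return sm


def _window_identity(mat: np.ndarray, col0: int, col1: int) -> float:
    """Mean per-column pairwise identity over a column window.

    Per column: fraction of row pairs (both with unambiguous data) that
    agree; columns with fewer than two data rows contribute 0.
    """
    total = 0.0
    for c in range(col0, col1):
        col = mat[:, c]
        counts = np.array([(col == s).sum() for s in _STATES])
        m = counts.sum()
        if m < 2:
            continue
        agree = (counts * (counts - 1) // 2).sum()
        total += agree / (m * (m - 1) / 2)
    return total / (col1 - col0)


def edge_trim(
    alignment: LocusAlignment, window: int = 20, min_identity: float = 0.5
) -> LocusAlignment | None:
    """Sliding-window edge trimmer (fallback; interior is never trimmed).

    From each end, columns are trimmed until a ``window``-column window
    reaches ``min_identity`` mean pairwise identity.  This is a simple
    stand-in for dedicated alignment-trimming tools and is not equivalent
    to them; pre-trimmed alignments can (and should) be supplied instead.
    Returns ``None`` with a warning when nothing survives.
    """
    if alignment.length < window:
        raise ValueError(f"alignment shorter than window ({alignment.length} < {window})")
    mat = _state_matrix(alignment.rows.values())
    ncols = mat.shape[1]
    left = None
    for c in range(0, ncols - window + 1):
        if _window_identity(mat, c, c + window) >= min_identity:
            left = c
            break
    if left is None:
        warnings.warn(f"edge_trim: alignment {alignment.locus_id} trimmed to empty")
        return None
    right = None
    for c in range(ncols, window - 1, -1):
        if _window_identity(mat, c - window, c) >= min_identity:
            right = c
            break
    if right is None or right <= left:
        warnings.warn(f"edge_trim: alignment {alignment.locus_id} trimmed to empty")
        return None
    # strip boundary columns with fewer than two data rows (e.g. all-gap)
    data = np.isin(mat, np.frombuffer(_STATES, dtype=np.uint8)).sum(axis=0) >= 2
    while left < right and not data[left]:
        left += 1
    while right > left and not data[right - 1]:
        right -= 1
    if right <= left:
        warnings.warn(f"edge_trim: alignment {alignment.locus_id} trimmed to empty")
        return None
    return LocusAlignment(
        alignment.locus_id, {t: s[left:right] for t, s in alignment.rows.items()}
    )
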