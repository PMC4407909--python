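"""Local-similarity engine for duplicate screening and bait/contig matching.

All match decisions in the toolkit reduce to one criterion: a local
alignment whose identity (matching columns / aligned columns) and coverage
(aligned span on a basis sequence / its full length) clear configurable
thresholds — e.g. "more than 80% identical over 50% of their length" for
the paralog screen of candidate conserved regions, and "80% identical over
80% of the bait length" for crediting a contig with a locus.

Alignment is optimal Smith-Waterman (match +1, mismatch -1, linear gap -2)
via scikit-bio's pair aligner; input sizes in this workflow (regions of a
few hundred bp, 120-nt baits, kb-scale contigs) do not require heuristic
seeding for the alignment itself, but an exact k-mer prescreen is available
to skip hopeless bait/contig pairs in bulk matching.  Reverse-complement
matches count: paralogy and capture are strand-agnostic.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from skbio.alignment import pair_align

from ._util import revcomp

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_COST = 2.0


@dataclass
class LocalMatch:
    """Best local alignment between a query and a target sequence."""

    query_id: str
    target_id: str
    query_span: tuple[int, int]  # half-open, on the query's + strand
    target_span: tuple[int, int]  # half-open, on the target's + strand
    identity: float
    strand: str  # strand of the query relative to the target
    score: float = 0.0
    n_columns: int = 0


def align_local(query: str, target: str):
    """Optimal local alignment; returns (score, q_span, t_span, identity, ncols).

    Returns ``None`` when the best local score is not positive (no similarity
    segment at all).  Case is ignored.
    """
    q, t = query.upper(), target.upper()
    res = pair_align(
        q,
        t,
        mode="local",
        sub_score=(MATCH_SCORE, MISMATCH_SCORE),
        gap_cost=GAP_COST,
        max_paths=1,
    )
    if res.score <= 0 or not res.paths:
        return None
    path = res.paths[0]
    (q0, q1), (t0, t1) = path.ranges
    # walk the path segments to count matches and aligned columns
    qi, ti = int(q0), int(t0)
    matches = ncols = 0
    for state, length in zip(path.states[0], path.lengths):
        length = int(length)
        ncols += length
        if state == 0:  # both sequences advance
            for k in range(length):
                if q[qi + k] == t[ti + k]:
                    matches += 1
            qi += length
            ti += length
        elif state == 1:  # gap in query
            ti += length
        else:  # gap in target
            qi += length
    identity = matches / ncols if ncols else 0.0
    return res.score, (int(q0), int(q1)), (int(t0), int(t1)), identity, ncols


def _kmers(seq: str, k: int) -> set[str]:
    s = seq.upper()
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def _coverage(
    match_spans: tuple[tuple[int, int], tuple[int, int]],
    qlen: int,
    tlen: int,
    basis: str,
) -> float:
    (q0, q1), (t0, t1) = match_spans
    if basis == "query":
        return (q1 - q0) / qlen
    if basis == "target":
        return (t1 - t0) / tlen
    if basis == "shorter":
        if qlen <= tlen:
            return (q1 - q0) / qlen
        return (t1 - t0) / tlen
    raise ValueError(f"coverage_basis must be query/target/shorter, got {basis!r}")


def local_matches(
    query_id: str,
    query: str,
    targets: Mapping[str, str] | Iterable[tuple[str, str]],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    coverage_basis: str = "query",
    strict: bool = False,
    seed_k: int | None = None,
) -> list[LocalMatch]:
    """All targets whose best local alignment clears both thresholds.

    Both strands are searched.  ``strict=True`` switches the comparisons
    from >= to > (for criteria phrased "more than").  ``seed_k`` enables an
    exact shared-k-mer prescreen (either strand) that skips targets with no
    seed in common with the query.  A trivial self-match (same id, full-span
    identity on the + strand) is excluded.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must lie in (0, 1]")
    if not query:
        raise ValueError("empty query sequence")
    cmp = operator.gt if strict else operator.ge
    items = targets.items() if isinstance(targets, Mapping) else targets
    qlen = len(query)
    rc_query = revcomp(query)
    if seed_k:
        seeds = _kmers(query, seed_k) | _kmers(rc_query, seed_k)

    out: list[LocalMatch] = []
    for target_id, target in items:
        if not target:
            continue
        if seed_k and not (seeds & _kmers(target, seed_k)):
            continue
        best: LocalMatch | None = None
        for strand, q in (("+", query), ("-", rc_query)):
            hit = align_local(q, target)
            if hit is None:
                continue
            score, qspan, tspan, identity, ncols = hit
            if strand == "-":  # report span on the query's own + strand
                qspan = (qlen - qspan[1], qlen - qspan[0])
            cov = _coverage((qspan, tspan), qlen, len(target), coverage_basis)
            if not (cmp(identity, min_identity) and cmp(cov, min_coverage)):
                continue
            cand = LocalMatch(
                query_id, target_id, qspan, tspan, identity, strand, score, ncols
            )
            if best is None or cand.score > best.score:
                best = cand
        if best is None:
            continue
        if (
            best.query_id == best.target_id
            and best.strand == "+"
            and best.query_span == best.target_span
            and best.identity == 1.0
        ):
            continue  # trivial self-match
        out.append(best)
    return out


def site_matches(
    query_id: str,
    query: str,
    target_id: str,
    target: str,
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    coverage_basis: str = "query",
    max_sites: int = 20,
) -> list[LocalMatch]:
    """All disjoint target sites matching the query above the thresholds.

    Unlike :func:`local_matches` (one best match per target), this finds
    multiple occurrences by iteratively masking each accepted site and
    re-aligning, on both strands, until no further site qualifies.  Used to
    detect loci present at several genomic locations.
    """
    qlen = len(query)
    out: list[LocalMatch] = []
    for strand, q in (("+", query.upper()), ("-", revcomp(query).upper())):
        work = list(target.upper())
        for _ in range(max_sites):
            hit = align_local(q, "".join(work))
            if hit is None:
                break
            score, qspan, tspan, identity, _ = hit
            rep_qspan = (qlen - qspan[1], qlen - qspan[0]) if strand == "-" else qspan
            cov = _coverage((rep_qspan, tspan), qlen, len(target), coverage_basis)
            if identity < min_identity or cov < min_coverage:
                break
            out.append(
                LocalMatch(query_id, target_id, rep_qspan, tspan, identity, strand, score)
            )
            for p in range(tspan[0], tspan[1]):  # mask the site and re-align
                work[p] = "#"
    return out


def _pair_is_duplicate(
    seq_a: str, seq_b: str, min_identity: float, min_coverage: float, basis: str
) -> bool:
    """Strict (>) duplicate decision for one pair, searching both strands."""
    for b in (seq_b, revcomp(seq_b)):
        hit = align_local(seq_a, b)
        if hit is None:
            continue
        _, qspan, tspan, identity, _ = hit
        cov = _coverage((qspan, tspan), len(seq_a), len(seq_b), basis)
        if identity > min_identity and cov > min_coverage:
            return True
    return False


def screen_duplicates(
    regions: Mapping[str, str] | Sequence,
    min_identity: float = 0.80,
    min_coverage: float = 0.50,
    coverage_basis: str = "shorter",
) -> tuple[list[str], list[str]]:
    """All-against-all paralog screen; BOTH members of a duplicate pair go.

    ``regions`` maps unique ids to residues (a mapping, ``(id, seq)`` pairs,
    or objects with ``name``/``residues``).  A pair counts as duplicate when
    its best local alignment is *more than* ``min_identity`` identical over
    *more than* ``min_coverage`` of the basis sequence (default: the shorter
    member).  Returns ``(kept_ids, removed_ids)`` in input order; the
    partition is invariant under input permutation.
    """
    pairs = _as_id_seq_pairs(regions)
    ids = [i for i, _ in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate region ids: {dupes}")
    seqs = dict(pairs)
    removed: set[str] = set()
    ordered = sorted(ids)
    for i, id_a in enumerate(ordered):
        for id_b in ordered[i + 1 :]:
            if _pair_is_duplicate(
                seqs[id_a], seqs[id_b], min_identity, min_coverage, coverage_basis
            ):
                removed.add(id_a)
                removed.add(id_b)
    kept = [i for i in ids if i not in removed]
    return kept, [i for i in ids if i in removed]


def _as_id_seq_pairs(regions) -> list[tuple[str, str]]:
    if isinstance(regions, Mapping):
        return [(str(k), str(v)) for k, v in regions.items()]
    pairs = []
    for item in regions:
        if isinstance(item, tuple):
            pairs.append((str(item[0]), str(item[1])))
        else:
            name = getattr(item, "name", None) or getattr(item, "locus_id", None)
            pairs.append((str(name), item.residues))
    return pairs
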