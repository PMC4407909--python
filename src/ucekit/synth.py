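"""Deterministic synthetic fixtures with planted ground truth.

The generator emulates the data regimes the toolkit consumes:

* a pair of genomes sharing planted, perfectly conserved elements on a
  divergent background, with an accompanying per-element MAF file and a
  truth BED of element coordinates;
* optional duplicated elements (a second, ~90%-identical copy planted in
  both genomes) to exercise the paralog screen, and soft-masked repeat
  tracts to exercise the bait repeat filter;
* per-taxon contig sets diverged from the design genome, with optional
  chimeric contigs (two loci fused), duplicated-locus contigs, and
  off-target decoys;
* qPCR crossing-point (Cp) tables with known per-library delta-Cp and
  closed-form truth folds.

Planted elements are *exactly* recoverable by construction: the generator
forces a cross-genome mismatch at the column immediately flanking each
element and breaks any accidental background run of matching bases longer
than ``max_background_run``, so a conserved-region scan returns precisely
the planted coordinates.  Background divergence is therefore approximately,
not exactly, the nominal substitution rate.

All outputs are pure functions of the spec (which carries the seed):
identical specs yield byte-identical files.  Indel evolution is not
modeled.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import BedInterval, GenomeSequence, MafBlock, MafRow

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthSpec:
    """Parameters of the synthetic study system (all rates in [0, 1])."""

    seed: int = 7
    genome_length: int = 100_000
    chrom_name: str = "chr1"
    taxon_a: str = "taxA"
    taxon_b: str = "taxB"
    n_elements: int = 50
    element_length_range: tuple[int, int] = (60, 200)
    n_duplicated_elements: int = 0
    duplicate_identity: float = 0.90
    background_substitution_rate: float = 0.15
    indel_rate: float = 0.0
    element_spacing: int = 500
    maf_context: int = 100
    max_background_run: int = 25
    repeat_tract_count: int = 4
    repeat_tract_length: int = 1500
    n_masked_elements: int = 0
    # contig generation
    contig_divergence: float = 0.05
    contig_flank_range: tuple[int, int] = (50, 400)
    n_decoy_contigs: int = 10
    decoy_length_range: tuple[int, int] = (300, 1500)
    n_chimeric_contigs: int = 0
    n_split_loci: int = 0
    # qPCR table
    cp_libraries: int = 3
    cp_amplicons: int = 7
    cp_replicates: int = 2
    cp_noise_sd: float = 0.0
    cp_blockers: tuple[str, ...] = ("chicken", "hymenoptera")
    cp_delta_means: dict = field(default_factory=lambda: {"chicken": 11.5, "hymenoptera": 9.0})
    cp_delta_sd: float = 1.0
    cp_efficiency: float = 1.78

    def __post_init__(self) -> None:
        for name in ("background_substitution_rate", "indel_rate", "contig_divergence", "duplicate_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.indel_rate != 0:
            raise ValueError("indel evolution is not modeled; indel_rate must be 0")

    def to_yaml(self) -> str:
        d = asdict(self)
        for key in ("element_length_range", "contig_flank_range", "decoy_length_range", "cp_blockers"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SynthSpec":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and "\n" not in source and Path(source).exists():
            text = Path(source).read_text()
        d = yaml.safe_load(text)
        for key in ("element_length_range", "contig_flank_range", "decoy_length_range", "cp_blockers"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GenomePair:
    """Two genomes with planted conserved elements and their truth files."""

    genome_a: GenomeSequence
    genome_b: GenomeSequence
    truth_bed: list[BedInterval]
    duplicate_pairs: list[tuple[str, str]]
    maf_blocks: list[MafBlock]
    masked_elements: list[str]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position to a *different* base with probability rate."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in hit:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _mutate_exact(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly ``n_sub`` distinct positions to different bases."""
    out = seq.copy()
    for p in rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False):
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_genome_pair(spec: SynthSpec) -> GenomePair:
    """Plant conserved elements in a divergent genome pair, with truth files.

    The first ``n_duplicated_elements`` elements also receive a second,
    ``duplicate_identity``-identical copy planted (verbatim in both genomes)
    further along the sequence, so the total planted element count is
    ``n_elements + n_duplicated_elements``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.element_length_range
    n_total = spec.n_elements + spec.n_duplicated_elements
    lengths = rng.integers(lo, hi + 1, size=spec.n_elements)
    # duplicate copies reuse the parent length
    lengths = np.concatenate([lengths, lengths[: spec.n_duplicated_elements]])

    # sequential packing with >= element_spacing between elements
    starts = []
    cursor = spec.element_spacing + int(rng.integers(0, 200))
    for L in lengths:
        starts.append(cursor)
        cursor += int(L) + spec.element_spacing + int(rng.integers(0, 250))
    if cursor + spec.element_spacing > spec.genome_length:
        raise ValueError(
            f"genome_length {spec.genome_length} cannot pack {n_total} elements; "
            f"needs at least {cursor + spec.element_spacing}"
        )

    G = spec.genome_length
    ancestral = rng.choice(_BASES, size=G)
    mask = np.zeros(G, dtype=bool)
    names = [f"elem-{i + 1:04d}" for i in range(n_total)]
    duplicate_pairs = []
    for i in range(n_total):
        s, L = starts[i], int(lengths[i])
        if i >= spec.n_elements:  # planted copy of element (i - n_elements)
            parent = i - spec.n_elements
            ps, pL = starts[parent], int(lengths[parent])
            n_sub = int(round((1 - spec.duplicate_identity) * pL))
            copy_seq = _mutate_exact(ancestral[ps : ps + pL], n_sub, rng)
            ancestral[s : s + L] = copy_seq
            duplicate_pairs.append((names[parent], names[i]))
        mask[s : s + L] = True

    bg = ~mask
    genome_a = ancestral.copy()
    genome_b = ancestral.copy()
    for genome in (genome_a, genome_b):
        hit = np.flatnonzero(bg & (rng.random(G) < spec.background_substitution_rate))
        for p in hit:
            choices = _BASES[_BASES != genome[p]]
            genome[p] = rng.choice(choices)

    def force_mismatch(p: int) -> None:
        if genome_a[p] == genome_b[p]:
            choices = _BASES[_BASES != genome_a[p]]
            genome_b[p] = rng.choice(choices)

    # Guard element boundaries and break accidental background runs so the
    # planted coordinates are exactly recoverable.  A zero background rate is
    # the degenerate identical-genome case and is left untouched.
    if spec.background_substitution_rate > 0:
        for i in range(n_total):
            s, e = starts[i], starts[i] + int(lengths[i])
            if s > 0:
                force_mismatch(s - 1)
            if e < G:
                force_mismatch(e)
        run = 0
        for p in range(G):
            if mask[p]:
                run = 0
                continue
            if genome_a[p] == genome_b[p]:
                run += 1
                if run >= spec.max_background_run:
                    force_mismatch(p)
                    run = 0
            else:
                run = 0

    # soft-masked repeat tracts in the background (both genomes)
    a_text = _to_str(genome_a)
    b_text = _to_str(genome_b)
    a_chars = list(a_text)
    b_chars = list(b_text)
    tracts = []
    tries = 0
    while len(tracts) < spec.repeat_tract_count and tries < 1000:
        tries += 1
        s = int(rng.integers(0, max(G - spec.repeat_tract_length, 1)))
        e = s + spec.repeat_tract_length
        if mask[s:e].any():
            continue
        if any(not (e <= ts or s >= te) for ts, te in tracts):
            continue
        tracts.append((s, e))
        for p in range(s, e):
            a_chars[p] = a_chars[p].lower()
            b_chars[p] = b_chars[p].lower()

    masked_elements = []
    for i in range(min(spec.n_masked_elements, n_total)):
        s, e = starts[i], starts[i] + int(lengths[i])
        for p in range(s, e):
            a_chars[p] = a_chars[p].lower()
        masked_elements.append(names[i])

    a_text = "".join(a_chars)
    b_text = "".join(b_chars)

    truth_bed = [
        BedInterval(spec.chrom_name, starts[i], starts[i] + int(lengths[i]), names[i])
        for i in range(n_total)
    ]

    blocks = []
    src_a = f"{spec.taxon_a}.{spec.chrom_name}"
    src_b = f"{spec.taxon_b}.{spec.chrom_name}"
    for i in range(n_total):
        s, e = starts[i], starts[i] + int(lengths[i])
        c0 = max(s - spec.maf_context, 0)
        c1 = min(e + spec.maf_context, G)
        blocks.append(
            MafBlock(
                rows=[
                    MafRow(src_a, c0, c1 - c0, "+", G, a_text[c0:c1]),
                    MafRow(src_b, c0, c1 - c0, "+", G, b_text[c0:c1]),
                ],
                score=0.0,
            ).validate()
        )

    return GenomePair(
        genome_a=GenomeSequence(spec.chrom_name, a_text),
        genome_b=GenomeSequence(spec.chrom_name, b_text),
        truth_bed=truth_bed,
        duplicate_pairs=duplicate_pairs,
        maf_blocks=blocks,
        masked_elements=masked_elements,
    )


def make_contigs(
    genome: GenomeSequence,
    loci: Sequence[BedInterval],
    spec: SynthSpec,
    taxon: str = "taxon1",
    divergence: float | None = None,
) -> tuple[list[GenomeSequence], pd.DataFrame]:
    """Per-taxon contigs diverged from the design genome, plus a truth table.

    One contig per locus (locus plus random flanks), mutated at the
    divergence rate.  The first ``n_split_loci`` loci receive a *second*
    contig (to trigger duplicate-contig removal); ``n_chimeric_contigs``
    contigs fuse the last locus pairs (to trigger multi-locus removal);
    ``n_decoy_contigs`` off-target background slices carry no locus.
    """
    if divergence is None:
        divergence = spec.contig_divergence
    rng = np.random.default_rng([spec.seed, zlib.crc32(taxon.encode()) & 0x7FFFFFFF])
    arr = np.frombuffer(genome.residues.upper().encode("ascii"), dtype=np.uint8)
    G = len(arr)
    flo, fhi = spec.contig_flank_range
    contigs: list[GenomeSequence] = []
    truth_rows = []
    counter = 0

    def add(seq: np.ndarray, kind: str, locus: str) -> None:
        nonlocal counter
        counter += 1
        name = f"{taxon}_node_{counter:04d}"
        contigs.append(GenomeSequence(name, _to_str(seq)))
        truth_rows.append({"contig": name, "kind": kind, "locus": locus})

    def locus_slice(iv: BedInterval) -> np.ndarray:
        fl = int(rng.integers(flo, fhi + 1))
        fr = int(rng.integers(flo, fhi + 1))
        s, e = max(iv.start - fl, 0), min(iv.end + fr, G)
        return _mutate(arr[s:e], divergence, rng)

    for iv in loci:
        add(locus_slice(iv), "normal", iv.name)
    for iv in loci[: spec.n_split_loci]:
        add(locus_slice(iv), "split-extra", iv.name)
    for j in range(spec.n_chimeric_contigs):
        a, b = loci[-(2 * j + 1)], loci[-(2 * j + 2)]
        fused = np.concatenate([locus_slice(a), locus_slice(b)])
        add(fused, "chimera", f"{a.name}+{b.name}")

    occupied = [(iv.start, iv.end) for iv in loci]
    placed = tries = 0
    while placed < spec.n_decoy_contigs and tries < 1000:
        tries += 1
        L = int(rng.integers(*spec.decoy_length_range))
        s = int(rng.integers(0, max(G - L, 1)))
        if any(not (s + L <= ts or s >= te) for ts, te in occupied):
            continue
        add(_mutate(arr[s : s + L], divergence, rng), "decoy", "")
        placed += 1

    order = rng.permutation(len(contigs))
    contigs = [contigs[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return contigs, truth


def make_cp_table(spec: SynthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic qPCR Cp table plus closed-form truth folds.

    Per (library, blocker, amplicon): an unenriched baseline Cp is drawn
    uniformly on [20, 30]; the enriched baseline sits ``delta`` cycles lower
    with ``delta ~ Normal(cp_delta_means[blocker], cp_delta_sd)`` truncated
    at 0; replicates add Normal(0, cp_noise_sd) noise.  Truth folds are
    ``cp_efficiency ** |delta|`` of the noiseless baselines, so with zero
    replicate noise the computed folds reproduce the truth exactly.
    """
    rng = np.random.default_rng([spec.seed, 0x5C9])
    rows, truth_rows = [], []
    reps = [f"rep{i + 1}" for i in range(spec.cp_replicates)]
    for li in range(spec.cp_libraries):
        library = f"pool{li + 1}"
        for blocker in spec.cp_blockers:
            for ai in range(spec.cp_amplicons):
                amplicon = f"amp{ai + 1}"
                unenr = float(rng.uniform(20, 30))
                delta = max(float(rng.normal(spec.cp_delta_means[blocker], spec.cp_delta_sd)), 0.0)
                enr = unenr - delta
                for treatment, base in (("enriched", enr), ("unenriched", unenr)):
                    noise = rng.normal(0, spec.cp_noise_sd, size=spec.cp_replicates) if spec.cp_noise_sd else np.zeros(spec.cp_replicates)
                    row = {"library": library, "amplicon": amplicon,
                           "treatment": treatment, "blocker": blocker}
                    row.update({r: base + n for r, n in zip(reps, noise)})
                    rows.append(row)
                truth_rows.append(
                    {
                        "library": library,
                        "amplicon": amplicon,
                        "blocker": blocker,
                        "delta_cp": enr - unenr,
                        "fold": spec.cp_efficiency ** abs(enr - unenr),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
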