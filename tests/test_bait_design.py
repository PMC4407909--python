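import numpy as np
import pytest

from ucekit import bait_design, synth
from ucekit.io_formats import GenomeSequence
from ucekit.maf_scan import ConservedRegion


def region(start, end, genome, chrom="chr1"):
    return ConservedRegion("", chrom, start, end, genome.residues[start:end].upper())


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(5)
    return GenomeSequence("chr1", "".join(rng.choice(list("ACGT"), size=5000)))


class TestBufferRegion:
    def test_short_region_padded_equally(self, genome):
        locus = bait_design.buffer_region(region(1000, 1060, genome), genome)
        assert (locus.start, locus.end) == (940, 1120)
        assert locus.length == 180 and not locus.clamped

    def test_long_region_unchanged(self, genome):
        locus = bait_design.buffer_region(region(1000, 1200, genome), genome)
        assert (locus.start, locus.end) == (1000, 1200)

    def test_odd_remainder_goes_three_prime(self, genome):
        locus = bait_design.buffer_region(region(1000, 1061, genome), genome)
        assert (1000 - locus.start, locus.end - 1061) == (59, 60)

    def test_clamp_at_five_prime_shifts_deficit(self, genome):
        locus = bait_design.buffer_region(region(10, 70, genome), genome)
        assert (locus.start, locus.end) == (0, 180)
        assert not locus.clamped

    def test_genome_shorter_than_target_is_flagged_not_error(self):
        tiny = GenomeSequence("c", "ACGT" * 30)  # 120 bp
        locus = bait_design.buffer_region(region(10, 70, tiny), tiny)
        assert locus.clamped and (locus.start, locus.end) == (0, 120)

    def test_residues_match_genome_slice(self, genome):
        locus = bait_design.buffer_region(region(2000, 2060, genome), genome)
        assert locus.residues == genome.residues[locus.start : locus.end]


class TestTile:
    @pytest.mark.parametrize("L", list(range(120, 1021, 60)))
    def test_closed_form_bait_count(self, L):
        locus = bait_design.Locus("uce-1", "c", 0, L, "A" * L)
        baits = bait_design.tile(locus)
        assert len(baits) == (L - 120) // 60 + 1

    @pytest.mark.parametrize("L", [121, 150, 179, 197, 239, 301])
    def test_flush_final_bait_covers_three_prime_end(self, L):
        locus = bait_design.Locus("uce-1", "c", 0, L, "A" * L)
        baits = bait_design.tile(locus)
        covered = set()
        for b in baits:
            assert b.end - b.start == 120
            covered.update(range(b.start, b.end))
        assert covered == set(range(0, L))
        assert baits[-1].end == L

    def test_exact_bait_length_yields_one(self):
        locus = bait_design.Locus("uce-1", "c", 0, 120, "A" * 120)
        assert len(bait_design.tile(locus)) == 1

    def test_short_locus_yields_empty(self):
        locus = bait_design.Locus("uce-1", "c", 0, 119, "A" * 119)
        assert bait_design.tile(locus) == []

    def test_bait_ids_and_coordinates(self):
        locus = bait_design.Locus("uce-7", "c", 50, 230, "A" * 180)
        baits = bait_design.tile(locus)
        assert [b.bait_id for b in baits] == ["uce-7_p1", "uce-7_p2"]
        assert [(b.start, b.end) for b in baits] == [(50, 170), (110, 230)]


def make_bait(seq, bait_id="uce-1_p1"):
    locus = bait_id.rsplit("_p", 1)[0]
    idx = int(bait_id.rsplit("_p", 1)[1])
    return bait_design.Bait(bait_id, locus, idx, seq, "c", 0, len(seq))


class TestFilterBait:
    def test_single_ambiguous_base_fails(self):
        ok, reasons = bait_design.filter_bait(make_bait("A" * 119 + "N"))
        assert not ok and reasons == {"ambiguity"}

    def test_gc_boundary_strict(self):
        at_boundary = "G" * 84 + "A" * 36  # 84/120 = 0.70 exactly
        ok, reasons = bait_design.filter_bait(make_bait(at_boundary))
        assert ok
        over = "G" * 85 + "A" * 35  # 85/120 > 0.70
        ok, reasons = bait_design.filter_bait(make_bait(over))
        assert not ok and reasons == {"gc"}

    def test_repeat_boundary_strict(self):
        exactly_quarter = "a" * 30 + "A" * 90  # 0.25 is not > 0.25
        ok, _ = bait_design.filter_bait(make_bait(exactly_quarter))
        assert ok
        ok, reasons = bait_design.filter_bait(make_bait("a" * 31 + "A" * 89))
        assert not ok and reasons == {"repeat"}

    def test_multiple_reasons_enumerated(self):
        seq = "g" * 85 + "N" + "a" * 34
        ok, reasons = bait_design.filter_bait(make_bait(seq))
        assert reasons == {"ambiguity", "repeat", "gc"}


class TestDedupeBaits:
    def test_exact_duplicate_keeps_lower_locus(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        b1 = make_bait(seq, "uce-2_p1")
        b2 = make_bait(seq, "uce-10_p1")
        kept, removed = bait_design.dedupe_baits([b2, b1])
        assert [b.bait_id for b in kept] == ["uce-2_p1"]
        assert [b.bait_id for b in removed] == ["uce-10_p1"]

    def test_same_locus_neighbours_exempt(self, rng):
        locus_seq = "".join(rng.choice(list("ACGT"), size=180))
        locus = bait_design.Locus("uce-1", "c", 0, 180, locus_seq)
        baits = bait_design.tile(locus)  # overlap 60/120 = 0.50, same locus
        kept, removed = bait_design.dedupe_baits(baits)
        assert len(kept) == 2 and removed == []

    def test_cross_locus_near_duplicates_both_removed(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        mutated = list(seq)
        for p in rng.choice(120, size=12, replace=False):  # 90% identity
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        b1 = make_bait(seq, "uce-1_p1")
        b2 = make_bait("".join(mutated), "uce-2_p1")
        kept, removed = bait_design.dedupe_baits([b1, b2])
        assert kept == [] and len(removed) == 2

    def test_duplicate_ids_error(self):
        b = make_bait("A" * 120)
        with pytest.raises(ValueError):
            bait_design.dedupe_baits([b, b])


class TestDesignPipeline:
    def test_singleton_loci_yield_two_baits_each(self):
        spec = synth.SynthSpec(seed=3, n_elements=45, element_length_range=(60, 60))
        pair = synth.make_genome_pair(spec)
        from ucekit import maf_scan

        regions = maf_scan.scan_alignment(pair.maf_blocks, min_len=40)
        genome = {pair.genome_a.seq_id: pair.genome_a}
        loci, baits, report = bait_design.design_pipeline(regions, genome)
        assert report["n_baits_tiled"] == 90  # 2 per 180-bp buffered locus

    def test_masked_locus_dropped(self):
        spec = synth.SynthSpec(seed=3, n_elements=20, n_masked_elements=1,
                               element_length_range=(60, 60))
        pair = synth.make_genome_pair(spec)
        from ucekit import maf_scan

        regions = maf_scan.scan_alignment(pair.maf_blocks, min_len=40)
        genome = {pair.genome_a.seq_id: pair.genome_a}
        loci, baits, report = bait_design.design_pipeline(regions, genome)
        # the fully soft-masked element is the lowest-coordinate locus
        masked_start = pair.truth_bed[0].start
        (masked_id,) = [
            lid for lid, r in bait_design.assign_locus_ids(regions) if r.start == masked_start
        ]
        assert report["dropped_loci"] == [masked_id]
        assert len(loci) == 19

    def test_empty_conserved_set_is_success(self):
        loci, baits, report = bait_design.design_pipeline([], {})
        assert loci == [] and baits == [] and report["n_baits_final"] == 0

    def test_bait_residues_equal_design_genome_slice(self, genome_pair_50):
        from ucekit import maf_scan

        regions = maf_scan.scan_alignment(genome_pair_50.maf_blocks, min_len=40)
        genome = {genome_pair_50.genome_a.seq_id: genome_pair_50.genome_a}
        loci, baits, _ = bait_design.design_pipeline(regions, genome)
        g = genome_pair_50.genome_a.residues
        for b in baits:
            assert b.residues.upper() == g[b.start : b.end].upper()

    def test_filter_dedupe_order_independent_for_exact_collapse(self, rng):
        baits = []
        for i in range(1, 6):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            baits.append(make_bait(seq, f"uce-{i}_p1"))
        baits.append(make_bait(baits[0].residues, "uce-9_p1"))  # exact dup
        passed_first = [b for b in baits if bait_design.filter_bait(b)[0]]
        a = {b.bait_id for b in bait_design.dedupe_baits(passed_first)[0]}
        deduped_first = bait_design.dedupe_baits(baits)[0]
        b_ids = {b.bait_id for b in deduped_first if bait_design.filter_bait(b)[0]}
        assert a == b_ids
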