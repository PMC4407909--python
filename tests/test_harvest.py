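import numpy as np
import pytest

from ucekit import bait_design, harvest, maf_scan, synth
from ucekit._util import revcomp
from ucekit.io_formats import GenomeSequence


def rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def toy_baits(rng_mod):
    return [(f"uce-{i}_p1", rand(rng_mod, 120)) for i in (1, 2, 3)]


@pytest.fixture(scope="module")
def rng_mod():
    return np.random.default_rng(99)


class TestBaitLocusParsing:
    def test_parse(self):
        assert harvest.bait_locus("uce-31_p2") == "uce-31"

    def test_unparseable_is_error(self):
        with pytest.raises(ValueError):
            harvest.bait_locus("probe31")


class TestMatchRules:
    def test_verbatim_bait_credits_locus(self, rng_mod, toy_baits):
        contig = GenomeSequence("c1", rand(rng_mod, 200) + toy_baits[0][1] + rand(rng_mod, 200))
        db, _ = harvest.match_contigs_to_loci({"tax1": [contig]}, toy_baits)
        assert db.is_present("uce-1", "tax1")
        assert db.name_map[("uce-1", "tax1")] == "c1"

    def test_chimeric_contig_removed(self, rng_mod, toy_baits):
        chimera = GenomeSequence("chi", toy_baits[0][1] + rand(rng_mod, 50) + toy_baits[1][1])
        db, _ = harvest.match_contigs_to_loci({"tax1": [chimera]}, toy_baits)
        assert db.loci() == []
        assert ("tax1", "chi", "multi-locus") in db.removal_log

    def test_two_contigs_one_locus_marks_absent(self, rng_mod, toy_baits):
        c1 = GenomeSequence("c1", rand(rng_mod, 100) + toy_baits[2][1])
        c2 = GenomeSequence("c2", toy_baits[2][1] + rand(rng_mod, 100))
        db, _ = harvest.match_contigs_to_loci({"tax1": [c1, c2]}, toy_baits)
        assert not db.is_present("uce-3", "tax1")
        reasons = {(t, n, r) for t, n, r in db.removal_log}
        assert ("tax1", "c1", "duplicate-contig") in reasons
        assert ("tax1", "c2", "duplicate-contig") in reasons

    def test_reverse_complement_contig_matches(self, rng_mod, toy_baits):
        contig = GenomeSequence("c1", revcomp(toy_baits[0][1]))
        db, recs = harvest.match_contigs_to_loci({"tax1": [contig]}, toy_baits)
        assert db.is_present("uce-1", "tax1")
        assert recs[0].strand == "-"

    def test_order_invariance(self, rng_mod, toy_baits):
        contigs = [
            GenomeSequence("c1", rand(rng_mod, 80) + toy_baits[0][1]),
            GenomeSequence("c2", toy_baits[1][1]),
            GenomeSequence("c3", rand(rng_mod, 500)),
        ]
        db1, _ = harvest.match_contigs_to_loci({"tax1": contigs}, toy_baits)
        db2, _ = harvest.match_contigs_to_loci({"tax1": contigs[::-1]}, toy_baits)
        assert db1.presence == db2.presence and db1.name_map == db2.name_map


class TestPlantedRecovery:
    def _design(self, pair):
        regions = maf_scan.scan_alignment(pair.maf_blocks, min_len=40)
        genome = {pair.genome_a.seq_id: pair.genome_a}
        return bait_design.design_pipeline(regions, genome)

    def test_recovery_at_five_percent_divergence(self, harvest_system):
        spec, pair, contigs, truth = harvest_system
        loci, baits, _ = self._design(pair)
        db, _ = harvest.match_contigs_to_loci({"taxon1": contigs}, baits)
        credited = [l for l in db.loci() if db.is_present(l, "taxon1")]
        assert len(credited) >= 38
        # zero false credits: every credited contig is a planted locus contig
        truth_by_contig = dict(zip(truth["contig"], truth["kind"]))
        for locus in credited:
            contig = db.name_map[(locus, "taxon1")]
            assert truth_by_contig[contig] in ("normal", "split-extra")
        # the chimera is removed as multi-locus
        (chimera,) = truth.loc[truth["kind"] == "chimera", "contig"]
        assert ("taxon1", chimera, "multi-locus") in db.removal_log
        # the duplicated-contig locus is marked absent
        dup_locus_contigs = truth.loc[truth["kind"] == "split-extra", "contig"]
        for c in dup_locus_contigs:
            assert ("taxon1", c, "duplicate-contig") in db.removal_log

    def test_recovery_collapses_with_divergence(self, harvest_system):
        """The 0.8 identity threshold brackets recovery as divergence grows.

        At 25% divergence the expected per-bait identity (0.75) sits below
        the cutoff, so recovery collapses to a minority of loci (chance
        fluctuations above 0.8 remain possible for single 120-nt windows);
        at 35% it reaches zero.
        """
        spec, pair, _, _ = harvest_system
        loci, baits, _ = self._design(pair)
        n_loci = len(pair.truth_bed)
        for divergence, bound in ((0.25, n_loci // 2), (0.35, 0)):
            contigs, _ = synth.make_contigs(
                pair.genome_a, pair.truth_bed, spec, taxon="far", divergence=divergence
            )
            db, _ = harvest.match_contigs_to_loci({"far": contigs}, baits)
            credited = [l for l in db.loci() if db.is_present(l, "far")]
            assert len(credited) <= bound

    def test_every_bait_hit_contig_accounted_for(self, harvest_system):
        spec, pair, contigs, truth = harvest_system
        loci, baits, _ = self._design(pair)
        db, recs = harvest.match_contigs_to_loci({"taxon1": contigs}, baits)
        hit_contigs = {r.contig_id for r in recs} | {
            n for t, n, r in db.removal_log if n.startswith("taxon1_")
        }
        credited_contigs = set(db.name_map.values())
        logged = {n for _, n, _ in db.removal_log}
        assert hit_contigs <= credited_contigs | logged


class TestSliceFromGenome:
    def test_flank_arithmetic_and_clamping(self, rng_mod):
        bait = rand(rng_mod, 120)
        locus_seq = bait + rand(rng_mod, 60)  # 180-bp locus
        genome_mid = GenomeSequence("g1", rand(rng_mod, 1500) + locus_seq + rand(rng_mod, 1500))
        (sl,), dropped = harvest.slice_from_genome([genome_mid], [("uce-1_p1", bait)])
        # bait span 120 + 2x1000 flank
        assert len(sl.residues) == 120 + 2000 and dropped == []
        genome_edge = GenomeSequence("g2", rand(rng_mod, 300) + locus_seq + rand(rng_mod, 1500))
        (sl2,), _ = harvest.slice_from_genome([genome_edge], [("uce-1_p1", bait)])
        assert len(sl2.residues) == 300 + 120 + 1000

    def test_two_genomic_sites_dropped(self, rng_mod):
        bait = rand(rng_mod, 120)
        genome = GenomeSequence(
            "g", rand(rng_mod, 500) + bait + rand(rng_mod, 2000) + bait + rand(rng_mod, 500)
        )
        slices, dropped = harvest.slice_from_genome([genome], [("uce-1_p1", bait)])
        assert slices == []
        assert dropped and dropped[0][0] == "uce-1"

    def test_best_site_mode_keeps_one(self, rng_mod):
        bait = rand(rng_mod, 120)
        genome = GenomeSequence(
            "g", rand(rng_mod, 500) + bait + rand(rng_mod, 2000) + bait + rand(rng_mod, 500)
        )
        slices, dropped = harvest.slice_from_genome(
            [genome], [("uce-1_p1", bait)], on_multiple_sites="best"
        )
        assert len(slices) == 1

    def test_minus_strand_slice_in_bait_orientation(self, rng_mod):
        bait = rand(rng_mod, 120)
        genome = GenomeSequence("g", rand(rng_mod, 200) + revcomp(bait) + rand(rng_mod, 200))
        (sl,), _ = harvest.slice_from_genome([genome], [("uce-1_p1", bait)], flank=10)
        assert bait in sl.residues


class TestCountsAndFastas:
    def make_db(self):
        db = harvest.MatchDatabase()
        taxa = [f"t{i}" for i in range(1, 15)]
        for t in taxa:
            db.taxa.add(t)
        for t in taxa[:10]:
            db.add(t, "uce-1", f"{t}_c1")
        for t in taxa[:9]:
            db.add(t, "uce-2", f"{t}_c2")
        return db, taxa

    def test_seventy_percent_of_fourteen_is_ten(self):
        db, taxa = self.make_db()
        assert harvest.get_match_counts(db, taxa, 0.70) == ["uce-1"]

    def test_full_completeness(self):
        db, taxa = self.make_db()
        assert harvest.get_match_counts(db, taxa, 1.0) == []

    def test_unknown_taxon_listed_in_error(self):
        db, taxa = self.make_db()
        with pytest.raises(ValueError, match="ghost"):
            harvest.get_match_counts(db, taxa + ["ghost"], 0.5)

    def test_get_fastas_order_and_missing_pair(self):
        db = harvest.MatchDatabase()
        seqs = {}
        for t in ("ta", "tb", "tc"):
            seqs[t] = {}
            for l in ("uce-1", "uce-2"):
                if (t, l) == ("tc", "uce-2"):
                    continue
                db.add(t, l, f"{t}_{l}_contig")
                seqs[t][f"{t}_{l}_contig"] = "ACGT"
        records = harvest.get_fastas(db, seqs, ["uce-1", "uce-2"])
        assert [r.seq_id for r in records] == [
            "uce-1_ta", "uce-1_tb", "uce-1_tc", "uce-2_ta", "uce-2_tb",
        ]

    def test_get_fastas_missing_sequence_error(self):
        db = harvest.MatchDatabase()
        db.add("ta", "uce-1", "c1")
        db.add("tb", "uce-1", "c9")
        with pytest.raises(ValueError, match="retrievable"):
            harvest.get_fastas(db, {"ta": {"c1": "ACGT"}}, ["uce-1"])


class TestDatabase:
    def test_uniqueness_invariants(self):
        db = harvest.MatchDatabase()
        db.add("t1", "uce-1", "c1")
        with pytest.raises(ValueError):
            db.add("t1", "uce-1", "c2")  # second contig for same (locus, taxon)
        with pytest.raises(ValueError):
            db.add("t1", "uce-2", "c1")  # same contig under another locus

    def test_sqlite_round_trip(self, tmp_path):
        db = harvest.MatchDatabase()
        db.add("t1", "uce-1", "c1")
        db.add("t2", "uce-1", "c9")
        db.add("t1", "uce-2", "c2")
        db.log_removal("t2", "cX", "multi-locus")
        path = tmp_path / "m.sqlite"
        db.to_sqlite(path)
        back = harvest.MatchDatabase.from_sqlite(path)
        assert back.presence == db.presence
        assert back.name_map == db.name_map
        assert back.removal_log == db.removal_log
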