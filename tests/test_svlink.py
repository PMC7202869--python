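"""Clip clustering, junction linking and the tandem-duplication call."""

import numpy as np
import pytest

from hostshift import simgen, svlink
from hostshift.formats_io import AlignmentRecord, GenomicInterval, ScaffoldSet
from hostshift.simgen import TruthConfig, build_truth_genome, simulate_dna_reads


def clipped_read(pos, m, clip_seq, side, rid="r", scaffold="s"):
    if side == "right":
        cigar = (("M", m), ("S", len(clip_seq)))
        seq = "A" * m + clip_seq
    else:
        cigar = (("S", len(clip_seq)), ("M", m))
        seq = clip_seq + "A" * m
    return AlignmentRecord(rid, "x", "DNA", scaffold, pos, cigar, seq)


class TestClustering:
    def test_identical_clips_form_one_cluster(self):
        reads = [
            clipped_read(975, 25, "C" * 25, "right", rid=f"r{i}") for i in range(20)
        ]
        clusters = svlink.collect_clip_clusters(reads)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.position == 1_000 and cl.side == "right"
        assert cl.n_clipped == 20
        assert cl.consensus == "C" * 25

    def test_cluster_tolerance_rule(self):
        reads = [
            clipped_read(900, 100, "G" * 20, "right", rid="a"),
            clipped_read(900, 102, "G" * 20, "right", rid="b"),
        ]
        assert len(svlink.collect_clip_clusters(reads, cluster_tol=3)) == 1
        assert len(svlink.collect_clip_clusters(reads, cluster_tol=1)) == 2

    def test_consensus_majority_with_tie_as_n(self):
        reads = [
            clipped_read(10, 10, "AAAAA", "right", rid="a"),
            clipped_read(10, 10, "AAAAC", "right", rid="b"),
            clipped_read(10, 10, "AAACC", "right", rid="c"),
            clipped_read(10, 10, "AACCC", "right", rid="d"),
        ]
        (cl,) = svlink.collect_clip_clusters(reads, min_clip=5)
        # last three columns: A=3,C=1 -> A; A=2,C=2 tie -> N; A=1,C=3 -> C
        assert cl.consensus == "AAANC"

    def test_empty_input_gives_empty_set(self):
        assert svlink.collect_clip_clusters([]) == []


class TestLinking:
    def test_right_cluster_matching_unit_start_is_tandem_dup(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        ref = ScaffoldSet({"s": seq})
        s, e = 1_000, 4_000
        cl = svlink.ClipCluster("s", e, "right", 20, 30, seq[s : s + 30])
        j = svlink.link_junction(cl, ref)
        assert j.classification == "tandem_dup"
        assert j.partner_position == s
        assert j.identity == 1.0

    def test_left_cluster_matching_unit_end_suffix_is_tandem_dup(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        ref = ScaffoldSet({"s": seq})
        s, e = 1_000, 4_000
        cl = svlink.ClipCluster("s", s, "left", 20, 30, seq[e - 30 : e])
        j = svlink.link_junction(cl, ref)
        assert j.classification == "tandem_dup"
        assert j.partner_position == e

    def test_partner_on_other_scaffold_is_interscaffold_insertion(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=2_000))
        b = "".join(rng.choice(list("ACGT"), size=2_000))
        ref = ScaffoldSet({"16": a, "15": b})
        cl = svlink.ClipCluster("16", 500, "right", 5, 10, b[700:730])
        j = svlink.link_junction(cl, ref)
        assert j.classification == "interscaffold_insertion"
        assert j.partner_scaffold == "15"

    def test_random_consensus_is_unresolved(self):
        # expected seed-hit rate ~ len * 4**-15 ~ 1e-4 per scaffold base
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        ref = ScaffoldSet({"s": seq})
        misses = 0
        for i in range(20):
            cons = "".join(rng.choice(list("ACGT"), size=25))
            j = svlink.link_junction(
                svlink.ClipCluster("s", 50_000, "right", 5, 10, cons), ref
            )
            misses += j.classification == "unresolved"
        assert misses == 20

    def test_no_junction_below_min_identity(self):
        # hard guarantee: identity < min_identity never yields a linked class
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        ref = ScaffoldSet({"s": seq})
        true = seq[2_000:2_060]
        corrupted = true[:20] + "".join(
            "A" if c != "A" else "C" for c in true[20:]
        )
        cl = svlink.ClipCluster("s", 5_000, "right", 5, 10, corrupted)
        j = svlink.link_junction(cl, ref, min_identity=0.9)
        assert j.classification == "unresolved"


class TestTandemCall:
    def test_printed_breakpoint_arithmetic(self):
        junctions = svlink.junction_pair_from_breakpoints("16", 445_716, 770_265)
        call = svlink.call_tandem_duplication(junctions)
        assert call.unit_length == 324_549
        assert call.printed_breakpoints == (445_716, 770_265)
        assert not call.depth_supported

    def test_adjacent_breakpoints_have_length_one(self):
        junctions = svlink.junction_pair_from_breakpoints("s", 10, 11)
        assert svlink.call_tandem_duplication(junctions).unit_length == 1

    def test_no_tandem_junction_raises(self):
        with pytest.raises(ValueError):
            svlink.call_tandem_duplication([])


def simulated_readset(copies=4, depth=60, seed=11):
    cfg = TruthConfig(
        seed=seed,
        scaffold_lengths={"16": 40_000},
        genes={},
        dup_unit=GenomicInterval("16", 12_000, 20_000),
        copies_per_genome=copies,
        read_len=100,
        depth=depth,
    )
    reference, genome = build_truth_genome(cfg)
    reads = simulate_dna_reads(genome, seed=seed)
    return cfg, reference, reads


class TestSimulatedRecovery:
    @pytest.mark.parametrize("copies,depth", [(4, 40), (8, 60)])
    def test_breakpoints_recovered_exactly(self, copies, depth):
        cfg, reference, reads = simulated_readset(copies, depth)
        clusters = svlink.collect_clip_clusters(reads)
        junctions = [svlink.link_junction(c, reference) for c in clusters]
        call = svlink.call_tandem_duplication(junctions)
        assert call.unit.start == cfg.dup_unit.start
        assert call.unit.end == cfg.dup_unit.end
        assert call.unit_length == cfg.dup_unit.length
        for j in call.supporting:
            assert j.classification == "tandem_dup"

    def test_cluster_counts_match_truth_geometry_oracle(self):
        """Each junction read soft-clips at the breakpoint holding the
        minority of its bases; the oracle recomputes, from the truth config
        and the read start encoded in each read id, how many reads must
        clip at the unit-end (right) and unit-start (left) clusters."""
        cfg, reference, reads = simulated_readset(copies=6, depth=60, seed=13)
        s, e = cfg.dup_unit.start, cfg.dup_unit.end
        L, rl = cfg.dup_unit.length, cfg.read_len
        min_clip = 10
        junction_pos = [s + j * L for j in range(1, cfg.copies_per_genome - 1)]
        exp_right = exp_left = 0
        for rec in reads:
            _, _, hap, start, _ = rec.read_id.split(":")
            if hap != "16|hapA":
                continue
            x = int(start)
            for jpos in junction_pos:
                b = jpos - x          # bases before the junction
                if 0 < b < rl:
                    if b >= rl - b and rl - b >= min_clip:
                        exp_right += 1
                    elif b < rl - b and b >= min_clip:
                        exp_left += 1
        clusters = svlink.collect_clip_clusters(reads, min_clip=min_clip)
        right = [c for c in clusters if c.side == "right" and c.position == e]
        left = [c for c in clusters if c.side == "left" and c.position == s]
        assert len(right) == 1 and len(left) == 1
        assert right[0].n_clipped == exp_right
        assert left[0].n_clipped == exp_left
        assert 0 < right[0].clip_fraction < 1
        assert 0 < left[0].clip_fraction < 1


@pytest.fixture(scope="module")
def transloc_reads():
    cfg = TruthConfig(
        seed=21,
        scaffold_lengths={"16": 50_000, "15": 30_000},
        genes={},
        dup_unit=GenomicInterval("16", 20_000, 26_000),
        copies_per_genome=5,
        translocation=simgen.TranslocationPlan(
            target_scaffold="15",
            target_offset=10_000,
            amplicon_offset=1_000,
            amplicon_length=2_000,
        ),
        read_len=100,
        depth=80.0,
    )
    reference, genome = build_truth_genome(cfg)
    reads = simulate_dna_reads(genome, seed=21)
    return cfg, reference, reads


class TestMinorityScan:
    def test_minority_cluster_found_at_planned_offset(self, transloc_reads):
        cfg, reference, reads = transloc_reads
        gene = GenomicInterval("16", 22_000, 23_000)  # inside the amplicon image
        hits = svlink.minority_breakpoint_scan(
            reads, gene, reference, flank=2_000, min_fraction=0.03
        )
        positions = {(c.position, j.classification) for c, j, _ in hits}
        assert (21_000, "interscaffold_insertion") in positions
        for c, j, off in hits:
            if c.position == 21_000:
                # 5 native copies + 1 translocated cross this locus; only the
                # translocated one clips, and only when the amplicon side
                # anchors the read, so the fraction is well below majority
                assert 0.01 < c.clip_fraction < 0.5
                assert j.partner_scaffold == "15"
                assert off == 1_000

    def test_no_translocation_gives_empty_scan(self):
        cfg, reference, reads = simulated_readset(copies=4, depth=40, seed=31)
        gene = GenomicInterval("16", 14_000, 15_000)
        hits = svlink.minority_breakpoint_scan(
            reads, gene, reference, flank=1_000, min_fraction=0.03
        )
        assert hits == []

    def test_threshold_above_simulated_fraction_gives_empty(self, transloc_reads):
        cfg, reference, reads = transloc_reads
        gene = GenomicInterval("16", 22_000, 23_000)
        hits = svlink.minority_breakpoint_scan(
            reads, gene, reference, flank=2_000, min_fraction=0.6
        )
        assert hits == []
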