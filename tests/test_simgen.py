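"""Truth-genome construction, read projection and the evidence simulators."""

import numpy as np
import pytest

from hostshift import simgen
from hostshift.formats_io import GeneModel, GenomicInterval
from hostshift.genefate import ddct_fold
from hostshift.simgen import (
    TEInsertion,
    TranslocationPlan,
    TruthConfig,
    TruthConfigError,
    VariantPlan,
    build_truth_genome,
    simulate_bioassay,
    simulate_ct_table,
    simulate_de_tables,
    simulate_dna_reads,
)


def small_config(seed=0, **kw):
    defaults = dict(
        seed=seed,
        scaffold_lengths={"16": 50_000},
        genes={},
        dup_unit=GenomicInterval("16", 20_000, 26_000),
        copies_per_genome=6,
        read_len=100,
        depth=60.0,
    )
    defaults.update(kw)
    return TruthConfig(**defaults)


class TestGenomeConstruction:
    def test_baseline_two_copies_is_identity(self):
        cfg = small_config(copies_per_genome=2)
        reference, genome = build_truth_genome(cfg)
        for scaf in reference:
            assert genome.scaffolds[f"{scaf}|hapA"] == reference[scaf]
            assert genome.scaffolds[f"{scaf}|hapB"] == reference[scaf]

    def test_haplotype_gains_unit_length_times_extra_copies(self):
        # direct string-construction oracle: the expanded haplotype carries
        # all extra copies head-to-tail, so 8 copies on that haplotype
        # (9 per diploid genome, baseline 2) add 7,000 nt of a 1,000-nt unit
        cfg = TruthConfig(
            seed=1,
            scaffold_lengths={"16": 10_000},
            genes={},
            dup_unit=GenomicInterval("16", 4_000, 5_000),
            copies_per_genome=9,
        )
        reference, genome = build_truth_genome(cfg)
        ref = reference["16"]
        unit = ref[4_000:5_000]
        expected = ref[:4_000] + unit * 8 + ref[5_000:]
        assert genome.scaffolds["16|hapA"] == expected
        assert len(genome.scaffolds["16|hapA"]) == 10_000 + 7_000
        assert genome.scaffolds["16|hapB"] == ref

    def test_every_tandem_junction_reads_unit_end_then_unit_start(self):
        cfg = small_config(copies_per_genome=4)
        reference, genome = build_truth_genome(cfg)
        ref = reference["16"]
        s, e = cfg.dup_unit.start, cfg.dup_unit.end
        L = cfg.dup_unit.length
        hap = genome.scaffolds["16|hapA"]
        for j in range(1, cfg.copies_per_genome - 1):
            junction = s + j * L
            assert hap[junction - 5 : junction] == ref[e - 5 : e]
            assert hap[junction : junction + 5] == ref[s : s + 5]

    def test_liftover_tiles_sample_exactly(self):
        cfg = small_config(
            te_plan=(
                TEInsertion("hAT", offset=3_000, length=200, copies=frozenset(range(6))),
            ),
            variant_plan=(
                VariantPlan("v", offset=1_000, kind="del", length=6, copies=frozenset({1})),
            ),
        )
        _, genome = build_truth_genome(cfg)
        assert genome.liftover.tiles_exactly(genome.scaffolds)

    def test_te_offset_outside_unit_rejected(self):
        with pytest.raises(TruthConfigError, match="outside unit"):
            small_config(
                te_plan=(
                    TEInsertion("hAT", offset=7_000, length=10, copies=frozenset({0})),
                )
            )

    def test_overlapping_insertions_rejected(self):
        with pytest.raises(TruthConfigError, match="overlapping"):
            small_config(
                te_plan=(
                    TEInsertion("a", offset=100, length=10, copies=frozenset({0})),
                    TEInsertion("b", offset=100, length=20, copies=frozenset({0})),
                )
            )

    def test_same_seed_gives_identical_output(self):
        cfg = small_config(seed=7)
        ref1, g1 = build_truth_genome(cfg)
        ref2, g2 = build_truth_genome(small_config(seed=7))
        assert g1.scaffolds == g2.scaffolds
        r1 = simulate_dna_reads(g1, depth=5, seed=7)
        r2 = simulate_dna_reads(g2, depth=5, seed=7)
        assert [(a.read_id, a.pos, a.cigar, a.seq) for a in r1] == [
            (a.read_id, a.pos, a.cigar, a.seq) for a in r2
        ]


@pytest.fixture(scope="module")
def genome():
    cfg = small_config(seed=3)
    reference, genome = build_truth_genome(cfg)
    reads = simulate_dna_reads(genome, seed=3)
    return cfg, reference, genome, reads


class TestReadProjection:
    def test_reads_inside_unit_are_m_only_at_unit_interval(self, genome):
        cfg, reference, g, reads = genome
        s, e = cfg.dup_unit.start, cfg.dup_unit.end
        inside = [
            r
            for r in reads
            if s <= r.pos and r.reference_end <= e and len(r.cigar) == 1
        ]
        assert inside, "expected M-only reads within the unit"
        for r in inside[:50]:
            assert r.cigar[0][0] == "M"
            assert r.seq == reference["16"][r.pos : r.reference_end]

    def test_junction_reads_clip_with_partner_sequence(self, genome):
        cfg, reference, g, reads = genome
        s, e = cfg.dup_unit.start, cfg.dup_unit.end
        ref = reference["16"]
        right = [r for r in reads if r.right_clip >= 10 and r.reference_end == e]
        left = [r for r in reads if r.left_clip >= 10 and r.pos == s]
        assert right and left
        for r in right:
            clip = r.right_clipped_seq
            assert clip == ref[s : s + len(clip)]
        for r in left:
            clip = r.left_clipped_seq
            assert clip == ref[e - len(clip) : e]

    def test_depth_ratio_inside_unit_approaches_copy_fold(self, genome):
        # oracle: direct binning of read starts on the generated read set
        cfg, reference, g, reads = genome
        s, e = cfg.dup_unit.start, cfg.dup_unit.end
        starts = np.array([r.pos for r in reads if r.scaffold == "16"])
        inner = ((starts >= s + 500) & (starts < e - 500)).sum()
        inner_len = (e - 500) - (s + 500)
        out = ((starts >= 2_000) & (starts < 18_000)).sum()
        out_len = 16_000
        ratio = (inner / inner_len) / (out / out_len)
        expect = cfg.copies_per_genome / 2
        sd = expect * np.sqrt(1 / inner + 1 / out)
        assert abs(ratio - expect) < 3 * max(sd, 0.01) + 0.15 * expect

    def test_per_copy_deletion_appears_as_d_op(self):
        cfg = small_config(
            seed=5,
            variant_plan=(
                VariantPlan(
                    "d6", offset=2_000, kind="del", length=6, copies=frozenset({0})
                ),
            ),
        )
        _, genome = build_truth_genome(cfg)
        reads = simulate_dna_reads(genome, seed=5)
        pos = cfg.dup_unit.start + 2_000
        with_del = [
            r
            for r in reads
            if any(op == "D" and n == 6 for op, n in r.cigar)
            and r.pos < pos < r.reference_end
        ]
        assert with_del, "no reads carrying the planned 6-bp deletion"

    def test_missing_depth_is_error(self):
        cfg = small_config(depth=60.0)
        _, genome = build_truth_genome(cfg)
        with pytest.raises(TruthConfigError):
            simulate_dna_reads(genome, depth=0)


class TestCtSimulation:
    def test_noiseless_fold_recovered_exactly(self):
        levels = {("test", "g"): 4.0, ("cal", "g"): 1.0}
        ct = simulate_ct_table(levels, ("hk1", "hk2"), replicates=3, seed=0, sd=0.0)
        fe = ddct_fold(ct, "g", ("hk1", "hk2"), "test", "cal")
        assert fe.fold == pytest.approx(4.0, abs=1e-9)

    def test_level_one_everywhere_gives_fold_one(self):
        levels = {("a", "g"): 1.0, ("b", "g"): 1.0}
        ct = simulate_ct_table(levels, ("hk",), replicates=4, seed=0, sd=0.0)
        fe = ddct_fold(ct, "g", ("hk",), "a", "b")
        assert fe.fold == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(TruthConfigError):
            simulate_ct_table({("a", "g"): 0.0}, ("hk",), 3, 0)

    def test_single_replicate_rejected(self):
        with pytest.raises(TruthConfigError):
            simulate_ct_table({("a", "g"): 1.0}, ("hk",), 1, 0)


class TestBioassaySimulation:
    def test_mortality_at_lc50_is_half(self):
        df = simulate_bioassay(
            lc50=10, slope=2, doses=[10.0], n_per_dose=4_000, seed=0
        )
        row = df[df["dose"] == 10.0].iloc[0]
        assert row["dead"] / row["n"] == pytest.approx(0.5, abs=0.03)

    def test_steep_slope_approaches_step_function(self):
        df = simulate_bioassay(
            lc50=10, slope=200, doses=[9.0, 11.0], n_per_dose=2_000, seed=0
        )
        below = df[df["dose"] == 9.0].iloc[0]
        above = df[df["dose"] == 11.0].iloc[0]
        assert below["dead"] / below["n"] < 0.01
        assert above["dead"] / above["n"] > 0.99

    def test_invalid_parameters_rejected(self):
        with pytest.raises(TruthConfigError):
            simulate_bioassay(lc50=-1, slope=2, doses=[1.0], n_per_dose=10)
        with pytest.raises(TruthConfigError):
            simulate_bioassay(lc50=1, slope=2, doses=[0.0], n_per_dose=10)


class TestDESimulation:
    def test_six_by_six_design_emits_36_tables(self):
        tables = simulate_de_tables(
            {"a": 1, "b": -1}, n_test=6, n_ref=6, n_background=50, seed=0
        )
        assert len(tables) == 36

    def test_background_never_survives_36_way_intersection(self):
        # expected survivors ~ 1000 * 0.3**36 < 1e-15; observed must be 0
        from hostshift.phenostats import core_de_intersect

        tables = simulate_de_tables(
            {}, n_test=6, n_ref=6, n_background=1_000, seed=1, sig_rate=0.3
        )
        res = core_de_intersect(tables)
        assert res.core == {}

    def test_planned_core_significant_with_sign_in_every_pair(self):
        tables = simulate_de_tables(
            {"up1": 1, "dn1": -1}, n_test=3, n_ref=3, n_background=10, seed=2
        )
        for df in tables.values():
            up = df[df["gene"] == "up1"].iloc[0]
            dn = df[df["gene"] == "dn1"].iloc[0]
            assert up["q"] <= 0.05 and up["log2fc"] > 0
            assert dn["q"] <= 0.05 and dn["log2fc"] < 0


class TestTranslocation:
    def test_translocated_amplicon_present_on_target_scaffold(self):
        cfg = small_config(
            scaffold_lengths={"16": 50_000, "15": 20_000},
            translocation=TranslocationPlan(
                target_scaffold="15",
                target_offset=10_000,
                amplicon_offset=1_000,
                amplicon_length=2_000,
            ),
        )
        reference, genome = build_truth_genome(cfg)
        hap = genome.scaffolds["15|hapA"]
        amp = reference["16"][21_000:23_000]
        assert hap[10_000:12_000] == amp
        assert len(hap) == 22_000
        assert genome.scaffolds["15|hapB"] == reference["15"]
        assert genome.liftover.tiles_exactly(genome.scaffolds)
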