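"""The canonical synthetic study: one truth configuration, end to end.

This module wires the simulator to every inference stage for a scaled-down
version of the host-shift amplification scenario: a 1-Mb focal scaffold in
which a 30-kb unit (a stand-in for the ~325-kb amplicon, scaled for speed)
is tandemly duplicated to 8 copies per diploid genome, with a gene
straddling each breakpoint (so tandem junctions create a chimeric fusion
gene), a nest of transposable elements downstream of the focal P450, a
6-bp start-codon deletion in a minority of kinase-gene copies, and one
copy of the P450 amplicon translocated into a second scaffold.

``run_end_to_end(seed)`` executes the full chain - read simulation, CNV
scan, breakpoint linking, tandem-dup call, fusion tally, ddCt folds, fate
classification, variant fractions, NMD test, TE ordering, DE intersection,
titer ANOVA and probit bioassay - and returns every intermediate, so tests
and reporting scripts measure recovery against the configured truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cnvscan, fusion, genefate, phenostats, simgen, svlink, teorder
from .formats_io import GeneModel, GenomicInterval

FOCAL = "16"
OTHER = "15"
UNIT = GenomicInterval(FOCAL, 300_000, 330_000)

# expression folds of the amplicon genes in the adapted lineage relative to
# the donor lineage (copy fold is 4 for all of them): the kinase, calcium
# channel and CYP6CY23 under-express their dosage, the two active P450s and
# the fusion over-express it
EXPRESSION_FOLD = {
    "Src42A": 2.7,
    "CaCh": 3.2,
    "CYP6CY23": 2.4,
    "CYP6CY4": 14.7,
    "CYP6CY3": 19.9,
    "fusion": 36.8,
}
COPY_FOLD_DEFAULT = 4.0
COPY_FOLD_CYP6CY3 = 4.5          # 8 native copies + 1 translocated, over 2

# minority-variant truth: a 6-bp deletion removing the start codon of the
# kinase gene, carried by 2 of the 8 copies; its transcripts are further
# depleted by nonsense-mediated decay
SRC_VARIANT_POS = 307_200        # 0-based reference position
SRC_VARIANT_COPIES = frozenset({1, 3})
SRC_VARIANT_RNA_LEVEL = 0.30     # vs 2.4 wild-type: RNA fraction ~ 0.11

TITER_TRUTH = {
    ("Mp", "control"): 1.0,
    ("Mp", "nicotine"): 0.4,     # symbiont crashes without detox cover
    ("Mn", "control"): 1.0,
    ("Mn", "nicotine"): 0.95,
}

BIOASSAY_LC50 = 10.0
BIOASSAY_SLOPE = 2.0
BIOASSAY_DOSES = [2.0, 5.0, 10.0, 20.0, 50.0]

DE_CORE_PLAN = {
    "Src42A": 1,
    "CYP6CY3": 1,
    "CYP6CY4": 1,
    "ADAMTS9": 1,
    "CaCh": 1,
    "CYP6CY23": 1,
    "GST_sigma": -1,
}


def standard_genes() -> dict[str, GeneModel]:
    """Gene models of the scaled amplicon (all on the minus strand, so the
    head-to-tail junction is transcription-compatible for the fusion)."""
    iv = lambda s, e: GenomicInterval(FOCAL, s, e)
    genes = {
        # promoter donor: promoter + two leading exons inside the unit,
        # third exon outside below the start breakpoint
        "RPS11": GeneModel(
            "RPS11",
            FOCAL,
            "-",
            exons=(iv(300_400, 300_550), iv(300_000, 300_150), iv(299_500, 299_700)),
            promoter=iv(300_600, 300_900),
        ),
        # body donor: promoter and first exon outside above the end
        # breakpoint, second exon straddling it, 23 trailing exons inside
        "ADAMTS9": GeneModel(
            "ADAMTS9",
            FOCAL,
            "-",
            exons=(iv(330_800, 331_000), iv(329_900, 330_200))
            + tuple(
                iv(329_900 - 250 * i, 329_900 - 250 * i + 150) for i in range(1, 24)
            ),
            promoter=iv(331_200, 331_500),
        ),
        "Src42A": GeneModel(
            "Src42A",
            FOCAL,
            "-",
            exons=(iv(307_000, 307_500), iv(305_000, 306_200)),
            promoter=iv(307_600, 307_900),
        ),
        "CYP6CY3": GeneModel(
            "CYP6CY3",
            FOCAL,
            "-",
            exons=(iv(311_500, 312_000), iv(310_000, 311_200)),
            promoter=iv(312_100, 312_400),
        ),
        "CYP6CY4": GeneModel(
            "CYP6CY4",
            FOCAL,
            "-",
            exons=(iv(316_200, 317_000), iv(315_000, 316_000)),
            promoter=iv(317_100, 317_400),
        ),
        "CYP6CY23": GeneModel(
            "CYP6CY23",
            FOCAL,
            "-",
            exons=(iv(318_900, 319_500), iv(318_000, 318_700)),
            promoter=iv(319_600, 319_900),
        ),
        "CaCh": GeneModel(
            "CaCh",
            FOCAL,
            "-",
            exons=(iv(322_500, 323_500), iv(320_000, 322_000)),
            promoter=iv(323_600, 323_900),
        ),
    }
    return genes


def standard_config(seed: int) -> simgen.TruthConfig:
    expression = {
        "RPS11": 5.0,
        "ADAMTS9": 1.0,
        "Src42A": 2.4,
        "Src42A|del6": SRC_VARIANT_RNA_LEVEL,
        "CYP6CY3": 19.9,
        "CYP6CY4": 14.7,
        "CYP6CY23": 2.4,
        "CaCh": 3.2,
        "fusion": 36.8,
    }
    reference_expression = {
        "RPS11": 5.0,
        "ADAMTS9": 1.0,
        "Src42A": 1.0,
        "CYP6CY3": 1.0,
        "CYP6CY4": 1.0,
        "CYP6CY23": 1.0,
        "CaCh": 1.0,
    }
    return simgen.TruthConfig(
        seed=seed,
        scaffold_lengths={FOCAL: 1_000_000, OTHER: 200_000},
        genes=standard_genes(),
        dup_unit=UNIT,
        copies_per_genome=8,
        te_plan=(
            simgen.TEInsertion(
                "hAT", offset=9_500, length=800,
                copies=frozenset(range(8)), in_translocated=True,
            ),
            simgen.TEInsertion(
                "TTAA3", offset=9_200, length=429,
                copies=frozenset({0, 1, 2}), in_translocated=True,
            ),
            simgen.TEInsertion(
                "MULE", offset=8_900, length=600,
                copies=frozenset({1, 2, 5}), in_translocated=False,
            ),
            simgen.TEInsertion(
                "Tc1", offset=9_700, length=1_200,
                copies=frozenset(), in_translocated=True,
            ),
        ),
        variant_plan=(
            simgen.VariantPlan(
                "src_del6",
                offset=SRC_VARIANT_POS - UNIT.start,
                kind="del",
                length=6,
                copies=SRC_VARIANT_COPIES,
            ),
        ),
        translocation=simgen.TranslocationPlan(
            target_scaffold=OTHER,
            target_offset=100_000,
            amplicon_offset=8_000,     # 2 kb upstream of CYP6CY3 (minus strand 3')
            amplicon_length=5_000,
        ),
        expression=expression,
        reference_expression=reference_expression,
        read_len=150,
        depth=60.0,
        rna_depth=40.0,
    )


def transcripts_for(
    config: simgen.TruthConfig, rearranged: bool
) -> dict[simgen.Transcript, float]:
    """The expressed transcript set of one sample with its relative levels."""
    levels = config.expression if rearranged else config.reference_expression
    genes = config.genes
    out: dict[simgen.Transcript, float] = {}
    for name, level in levels.items():
        if name == "fusion":
            tx = simgen.fusion_transcript(
                genes["RPS11"], genes["ADAMTS9"], config.dup_unit
            )
        elif name.endswith("|del6"):
            base = genes[name.split("|")[0]]
            tx = _deleted_transcript(base, SRC_VARIANT_POS, 6, name)
        else:
            tx = simgen.gene_transcript(genes[name])
        out[tx] = level
    return out


def _deleted_transcript(
    gene: GeneModel, pos: int, length: int, name: str
) -> simgen.Transcript:
    pieces = []
    for sc, s, e in simgen.gene_transcript(gene).pieces:
        if s <= pos and pos + length <= e:
            pieces.append((sc, s, pos))
            pieces.append((sc, pos + length, e))
        else:
            pieces.append((sc, s, e))
    return simgen.Transcript(name, tuple(pieces))


def ct_tables(config: simgen.TruthConfig, seed: int, replicates: int = 4):
    """(expression, copy-number, titer) Ct tables at the configured truth."""
    test, cal = "Mn", "Mp3"
    expr_levels = {}
    copy_levels = {}
    for gene, fold in EXPRESSION_FOLD.items():
        expr_levels[(test, gene)] = fold
        expr_levels[(cal, gene)] = 1.0
    for gene in ["Src42A", "CaCh", "CYP6CY23", "CYP6CY4", "fusion", "CYP6CY3"]:
        copy_levels[(test, gene)] = (
            COPY_FOLD_CYP6CY3 if gene == "CYP6CY3" else COPY_FOLD_DEFAULT
        )
        copy_levels[(cal, gene)] = 1.0
    titer_levels = {
        (f"{clone}_{diet}", "GroEL"): level
        for (clone, diet), level in TITER_TRUTH.items()
    }
    hk = ("actin", "para")
    expr = simgen.simulate_ct_table(
        expr_levels, hk, replicates, seed, sd=config.ct_noise_sd, assay="expression"
    )
    copy = simgen.simulate_ct_table(
        copy_levels, hk, replicates, seed + 101, sd=config.ct_noise_sd,
        assay="copy_number",
    )
    titer = simgen.simulate_ct_table(
        titer_levels, hk, replicates, seed + 202, sd=config.ct_noise_sd, assay="titer"
    )
    return expr, copy, titer


def te_observations() -> list[teorder.CopyObservation]:
    """Per-copy element co-occurrence implied by the standard TE plan."""
    cfg = standard_config(0)
    native = []
    for ci in range(cfg.copies_per_genome):
        elems = frozenset(
            te.name for te in cfg.te_plan if ci in te.copies
        )
        native.append(teorder.CopyObservation(f"copy{ci}", "native", elems))
    trans = teorder.CopyObservation(
        "copyT",
        "translocated",
        frozenset(te.name for te in cfg.te_plan if te.in_translocated),
    )
    return native + [trans]


@dataclass
class EndToEndResult:
    config: simgen.TruthConfig
    reference: object
    dup_call: svlink.TandemDupCall
    segments: list
    windows: pd.DataFrame
    tally: fusion.JunctionReadTally
    fusion_model: fusion.FusionModel | None
    copy_folds: dict[str, genefate.FoldEstimate]
    expression_folds: dict[str, genefate.FoldEstimate]
    fates: dict[str, genefate.FateCall]
    dna_variant: genefate.VariantReadFraction
    rna_variant: genefate.VariantReadFraction
    nmd_p: float
    minority: list
    event_dag: teorder.EventDAG
    extras: dict = field(default_factory=dict)


def run_end_to_end(seed: int, cnv_window: int = 10_000, cnv_step: int = 10_000) -> EndToEndResult:
    """Simulate the standard scenario and run every inference stage on it."""
    config = standard_config(seed)
    reference, test_genome = simgen.build_truth_genome(config)
    ref_genome = simgen.baseline_genome(config)

    dna_test = simgen.simulate_dna_reads(test_genome, seed=seed)
    dna_ref = simgen.simulate_dna_reads(ref_genome, seed=seed + 1)
    rna_test = simgen.simulate_rna_reads(
        reference, transcripts_for(config, True), "Mn", config.rna_depth,
        config.read_len, seed,
    )

    # read-depth copy-ratio scan
    windows = cnvscan.scan(
        dna_test, dna_ref, FOCAL, config.scaffold_lengths[FOCAL],
        window=cnv_window, step=cnv_step,
    )
    segments = cnvscan.call_segments(windows, FOCAL)

    # breakpoints and the tandem-duplication call
    clusters = svlink.collect_clip_clusters(dna_test)
    junctions = [svlink.link_junction(cl, reference) for cl in clusters]
    dup_call = svlink.call_tandem_duplication(junctions, segments)

    # chimeric transcript evidence and the fused gene model
    tally = fusion.tally_junction_reads(rna_test, dup_call, reference)
    fusion_model = fusion.predict_fusion_model(config.genes, dup_call)

    # qPCR folds and fate classification
    expr_ct, copy_ct, titer_ct = ct_tables(config, seed)
    hk = ("actin", "para")
    copy_folds, expr_folds, fates = {}, {}, {}
    for gene in EXPRESSION_FOLD:
        copy_folds[gene] = genefate.ddct_fold(copy_ct, gene, hk, "Mn", "Mp3")
        expr_folds[gene] = genefate.ddct_fold(expr_ct, gene, hk, "Mn", "Mp3")
        fates[gene] = genefate.concordance_classify(
            copy_folds[gene], expr_folds[gene], gene=gene
        )

    # loss-of-function minority variant, DNA vs RNA
    src_locus = config.genes["Src42A"].exons[0]
    variant = genefate.IndelVariant(pos=SRC_VARIANT_POS, kind="del", length=6)
    dna_vrf = genefate.variant_read_fraction(dna_test, src_locus, variant, layer="DNA")
    rna_vrf = genefate.variant_read_fraction(rna_test, src_locus, variant, layer="RNA")
    nmd_p = genefate.nmd_depletion_test(dna_vrf, rna_vrf)

    # secondary (minority) breakpoint around the focal P450
    minority = svlink.minority_breakpoint_scan(
        dna_test, config.genes["CYP6CY3"].span, reference, flank=5_000
    )

    # TE insertion ordering
    dag = teorder.build_event_dag(teorder.derive_constraints(te_observations()))

    return EndToEndResult(
        config=config,
        reference=reference,
        dup_call=dup_call,
        segments=segments,
        windows=windows,
        tally=tally,
        fusion_model=fusion_model,
        copy_folds=copy_folds,
        expression_folds=expr_folds,
        fates=fates,
        dna_variant=dna_vrf,
        rna_variant=rna_vrf,
        nmd_p=nmd_p,
        minority=minority,
        event_dag=dag,
        extras={"titer_ct": titer_ct},
    )
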