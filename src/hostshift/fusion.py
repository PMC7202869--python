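"""Chimeric junction transcripts and the fused gene model they imply.

A head-to-tail tandem junction concatenates unit-end sequence upstream of
unit-start sequence.  When one gene straddles each breakpoint of the unit
(both on the same strand, in the orientation for which the promoter-donor
fragment is transcriptionally upstream across the junction), every junction
between amplicon copies is predicted to splice the promoter donor's leading
exons onto the body donor's trailing exons.  This module tallies
junction-spanning RNA reads into chimeric vs wild-type counts and predicts
the fused gene model from the annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .formats_io import AlignmentRecord, GeneModel, GenomicInterval, ScaffoldSet
from .svlink import TandemDupCall


@dataclass(frozen=True)
class JunctionReadTally:
    n_chimeric: int
    n_wildtype: int

    @property
    def chimeric_fraction(self) -> float:
        total = self.n_chimeric + self.n_wildtype
        return self.n_chimeric / total if total else float("nan")

    @property
    def defined(self) -> bool:
        return (self.n_chimeric + self.n_wildtype) > 0


@dataclass(frozen=True)
class FusionModel:
    promoter_donor: str
    promoter_retained_exons: tuple[GenomicInterval, ...]
    body_donor: str
    body_retained_exons: tuple[GenomicInterval, ...]
    junction: GenomicInterval          # the unit, whose copies create the junction
    residues_lost_from_body: int | None = None
    residues_gained_from_promoter: int | None = None


def _matched_flanks(rec: AlignmentRecord, p: int) -> tuple[int, int]:
    """Matched (M) bases of ``rec`` strictly before and at-or-after ref pos p."""
    before = after = 0
    r = rec.pos
    for op, n in rec.cigar:
        if op == "M":
            lo, hi = r, r + n
            before += max(0, min(hi, p) - lo)
            after += max(0, hi - max(lo, p))
            r += n
        elif op == "D":
            r += n
    return before, after


def tally_junction_reads(
    rna: Iterable[AlignmentRecord],
    dup: TandemDupCall,
    reference: ScaffoldSet,
    anchor: int = 10,
) -> JunctionReadTally:
    """Count chimeric vs wild-type reads at the tandem junction.

    A read is chimeric when it is anchored with >= ``anchor`` matched bases
    on one side of the junction and its soft-clipped continuation matches
    the partner side: a right-clipped read ending at the unit end whose clip
    equals the unit-start sequence, or a left-clipped read starting at the
    unit start whose clip equals the unit-end suffix.  A read is wild-type
    when it crosses either breakpoint position with >= anchor matched bases
    on both sides and no clip at that position.  Everything else is ignored.
    """
    if anchor < 5:
        raise ValueError("anchor must be >= 5")
    s, e = dup.unit.start, dup.unit.end
    scaf = dup.unit.scaffold
    ref = reference[scaf]
    n_chim = n_wt = 0
    for rec in rna:
        if rec.scaffold != scaf:
            continue
        counted_chimeric = False
        if (
            rec.right_clip >= anchor
            and rec.reference_end == e
        ):
            before, _ = _matched_flanks(rec, e)
            clip = rec.right_clipped_seq
            if before >= anchor and clip == ref[s : s + len(clip)]:
                n_chim += 1
                counted_chimeric = True
        if (
            not counted_chimeric
            and rec.left_clip >= anchor
            and rec.pos == s
        ):
            _, after = _matched_flanks(rec, s)
            clip = rec.left_clipped_seq
            if after >= anchor and clip == ref[e - len(clip) : e]:
                n_chim += 1
                counted_chimeric = True
        if counted_chimeric:
            continue
        for p in (s, e):
            if rec.pos < p < rec.reference_end and rec.left_clip == 0 and rec.right_clip == 0:
                before, after = _matched_flanks(rec, p)
                if before >= anchor and after >= anchor:
                    n_wt += 1
                    break
    return JunctionReadTally(n_chimeric=n_chim, n_wildtype=n_wt)


def _strictly_inside(exon: GenomicInterval, unit: GenomicInterval) -> bool:
    return unit.contains(exon)


def predict_fusion_model(
    genes: Mapping[str, GeneModel],
    dup: TandemDupCall,
    coding_exon_residues: Mapping[str, Mapping[int, int]] | None = None,
) -> FusionModel | None:
    """Predict the fused gene model created by the tandem junction.

    The promoter donor is the gene straddling the unit-start breakpoint
    whose promoter and leading exons lie inside the unit; the body donor is
    the gene straddling the unit-end breakpoint whose trailing exons lie
    inside the unit.  "Inside" means strict containment of the whole exon
    interval in the half-open unit.  For a head-to-tail junction this
    containment pattern is transcription-compatible only on the minus
    strand; a strand pattern that cannot transcribe across the junction
    raises rather than mispredicting.  Genes fully inside the unit are not
    fusion candidates.  Returns None when no gene straddles a breakpoint.

    ``coding_exon_residues`` optionally maps gene -> {exon index (1-based,
    transcription order) -> coding residues}, from which the protein
    consequence (residues lost from the body donor's excluded exons,
    residues gained from the promoter donor's retained exons) is summed;
    no translation of genomic sequence is attempted.
    """
    unit = dup.unit
    start_straddlers = []
    end_straddlers = []
    for gid in sorted(genes):
        g = genes[gid]
        span = g.span
        if span.scaffold != unit.scaffold:
            continue
        if span.start < unit.start < span.end:
            start_straddlers.append(g)
        if span.start < unit.end < span.end:
            end_straddlers.append(g)
    if len(start_straddlers) != 1 or len(end_straddlers) != 1:
        return None
    prom, body = start_straddlers[0], end_straddlers[0]
    if prom.strand != body.strand:
        raise ValueError(
            "orientation-incompatible: straddling genes on opposite strands"
        )
    prom_retained = tuple(
        e for e in prom.exons if _strictly_inside(e, unit)
    )  # leading exons, transcription order
    body_retained = tuple(
        e for e in body.exons if _strictly_inside(e, unit)
    )  # trailing exons, transcription order
    if not prom_retained or not body_retained:
        return None
    if prom.strand != "-":
        # a candidate pair with exon material inside the unit on both sides
        # exists, but on the plus strand the promoter-donor fragment is not
        # transcriptionally upstream across a head-to-tail junction
        raise ValueError(
            "orientation-incompatible: promoter-donor fragment is not "
            "transcriptionally upstream across a head-to-tail junction on "
            f"strand {prom.strand!r}"
        )
    if prom.promoter is None or not unit.contains(prom.promoter):
        return None
    # the retained leading exons must be an uninterrupted prefix and the
    # retained trailing exons an uninterrupted suffix of transcription order
    n_lead = len(prom_retained)
    if prom.exons[:n_lead] != prom_retained:
        return None
    n_trail = len(body_retained)
    if body.exons[-n_trail:] != body_retained:
        return None
    lost = gained = None
    if coding_exon_residues is not None:
        body_res = coding_exon_residues.get(body.gene_id, {})
        n_excluded = len(body.exons) - n_trail
        lost = sum(body_res.get(i + 1, 0) for i in range(n_excluded))
        prom_res = coding_exon_residues.get(prom.gene_id, {})
        gained = sum(prom_res.get(i + 1, 0) for i in range(n_lead))
    return FusionModel(
        promoter_donor=prom.gene_id,
        promoter_retained_exons=prom_retained,
        body_donor=body.gene_id,
        body_retained_exons=body_retained,
        junction=unit,
        residues_lost_from_body=lost,
        residues_gained_from_promoter=gained,
    )
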