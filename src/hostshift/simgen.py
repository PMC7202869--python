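"""Ground-truth simulator: rearranged genomes and every downstream evidence layer.

The generator encodes a host-shift amplification scenario as an explicit
truth configuration and emits everything the inference stages consume:

* a reference genome and a diploid sample genome in which a focal unit has
  been tandemly duplicated head-to-tail, with transposable elements,
  per-copy indel variants and an optional translocated amplicon;
* pre-aligned DNA and RNA reads projected back to reference coordinates
  through an exact liftover map (a read crossing a novel junction is emitted
  soft-clipped, with the clipped bases equal to the partner-locus sequence);
* qPCR Ct tables under an efficiency model with housekeeping genes;
* per-comparison differential-expression tables; and
* binomially distributed dose-mortality tables under a probit model.

Everything is deterministic given (config, seed): same inputs, byte-identical
outputs.  Reads are never passed through an external mapper - projection
through the liftover map gives exact, deterministic evidence, which is what
lets downstream tests assert recovery against known truth.

Diploid accounting: ``copies_per_genome`` is the total number of unit copies
across both haplotypes, with baseline 2 (one per haplotype).  One haplotype
carries all extra copies; copy-fold reported downstream is copies/2.
"""

from __future__ import annotations

import math
import zlib
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formats_io import (
    AlignmentRecord,
    GeneModel,
    GenomicInterval,
    ScaffoldSet,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Reference gaps / novel insertions at or below this size are representable
# inside one alignment as D / I ops; anything larger breaks the alignment
# into an anchored part plus a soft clip.
MAX_SMALL_INDEL = 50


class TruthConfigError(ValueError):
    """The truth configuration violates one of its invariants."""


# ---------------------------------------------------------------------------
# Truth configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TEInsertion:
    """One transposable-element insertion within the duplication unit."""

    name: str
    offset: int               # insertion point, relative to unit start
    length: int               # element length (sequence is seeded from name)
    copies: frozenset[int]    # native copy indices (0-based) carrying it
    in_translocated: bool = False


@dataclass(frozen=True)
class VariantPlan:
    """A small per-copy indel inside the unit (offset relative to unit start)."""

    name: str
    offset: int
    kind: str                 # "del" | "ins"
    length: int
    copies: frozenset[int]    # native copy indices carrying the variant

    def __post_init__(self) -> None:
        if self.kind not in ("del", "ins"):
            raise TruthConfigError(f"variant kind must be del/ins, got {self.kind!r}")
        if self.length <= 0 or self.length > MAX_SMALL_INDEL:
            raise TruthConfigError(
                f"variant length must be in [1, {MAX_SMALL_INDEL}]"
            )


@dataclass(frozen=True)
class TranslocationPlan:
    """A sub-amplicon of the unit copied into another scaffold."""

    target_scaffold: str
    target_offset: int        # insertion point on the target scaffold
    amplicon_offset: int      # start of the amplicon, relative to unit start
    amplicon_length: int


@dataclass
class TruthConfig:
    seed: int
    scaffold_lengths: dict[str, int]
    genes: dict[str, GeneModel]
    dup_unit: GenomicInterval
    copies_per_genome: int = 2
    te_plan: tuple[TEInsertion, ...] = ()
    variant_plan: tuple[VariantPlan, ...] = ()
    translocation: TranslocationPlan | None = None
    # transcript name -> relative expression level in the *test* sample;
    # "fusion" names the chimeric junction transcript.
    expression: dict[str, float] = field(default_factory=dict)
    reference_expression: dict[str, float] = field(default_factory=dict)
    ct_base: float = 20.0
    ct_noise_sd: float = 0.15
    read_len: int = 150
    depth: float = 60.0
    rna_depth: float = 5.0

    def __post_init__(self) -> None:
        if self.copies_per_genome < 2:
            raise TruthConfigError("copies_per_genome must be >= 2")
        if self.dup_unit.scaffold not in self.scaffold_lengths:
            raise TruthConfigError("duplication unit on unknown scaffold")
        if self.dup_unit.end > self.scaffold_lengths[self.dup_unit.scaffold]:
            raise TruthConfigError("duplication unit outside scaffold")
        if self.depth <= 0:
            raise TruthConfigError("depth must be > 0")
        unit_len = self.dup_unit.length
        offsets: list[tuple[int, int]] = []
        for te in self.te_plan:
            if not (0 <= te.offset <= unit_len):
                raise TruthConfigError(f"TE {te.name} offset outside unit")
            if any(c >= self.copies_per_genome for c in te.copies):
                raise TruthConfigError(f"TE {te.name} assigned to nonexistent copy")
            offsets.append((te.offset, te.length))
        for a, b in zip(sorted(offsets), sorted(offsets)[1:]):
            if a[0] == b[0]:
                raise TruthConfigError("overlapping planned insertions")
        for v in self.variant_plan:
            if not (0 <= v.offset < unit_len):
                raise TruthConfigError(f"variant {v.name} offset outside unit")
            if any(c >= self.copies_per_genome for c in v.copies):
                raise TruthConfigError(
                    f"variant {v.name} assigned to nonexistent copy"
                )
        for level in list(self.expression.values()) + list(
            self.reference_expression.values()
        ):
            if level <= 0:
                raise TruthConfigError("expression levels must be > 0")

    @property
    def copy_fold(self) -> float:
        """Copy number fold of the unit relative to the diploid baseline."""
        return self.copies_per_genome / 2.0


# ---------------------------------------------------------------------------
# Liftover map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LiftoverBlock:
    """One block of a sample scaffold: a reference image or novel sequence."""

    length: int
    ref_scaffold: str | None   # None for novel (TE / inserted) sequence
    ref_start: int | None
    label: str = ""

    @property
    def is_ref(self) -> bool:
        return self.ref_scaffold is not None


class LiftoverMap:
    """Ordered blocks tiling each sample scaffold exactly once."""

    def __init__(self, blocks: dict[str, list[LiftoverBlock]]):
        self.blocks = blocks
        self._starts: dict[str, list[int]] = {}
        for name, blist in blocks.items():
            starts, pos = [], 0
            for b in blist:
                if b.length <= 0:
                    raise TruthConfigError("empty liftover block")
                starts.append(pos)
                pos += b.length
            self._starts[name] = starts

    def scaffold_length(self, name: str) -> int:
        return self._starts[name][-1] + self.blocks[name][-1].length

    def tiles_exactly(self, scaffolds: ScaffoldSet) -> bool:
        """Blocks cover each sample scaffold with no gaps or overlaps."""
        return all(
            self.scaffold_length(name) == scaffolds.length_of(name)
            for name in scaffolds
        )

    def pieces(self, name: str, start: int, end: int) -> list[LiftoverBlock]:
        """Decompose sample interval [start, end) into sub-block pieces."""
        starts = self._starts[name]
        blist = self.blocks[name]
        i = bisect_right(starts, start) - 1
        out: list[LiftoverBlock] = []
        pos = start
        while pos < end:
            bstart = starts[i]
            b = blist[i]
            off = pos - bstart
            take = min(end, bstart + b.length) - pos
            out.append(
                LiftoverBlock(
                    take,
                    b.ref_scaffold,
                    None if b.ref_start is None else b.ref_start + off,
                    b.label,
                )
            )
            pos += take
            i += 1
        return out


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def te_sequence(name: str, length: int, seed: int) -> str:
    """Deterministic element sequence derived from (name, seed)."""
    tag = zlib.crc32(name.encode()) % (2**31)
    sub = int(np.random.SeedSequence([seed, tag]).generate_state(1)[0])
    return _random_seq(np.random.default_rng(sub), length)


def make_reference(config: TruthConfig) -> ScaffoldSet:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    return ScaffoldSet(
        {name: _random_seq(rng, n) for name, n in sorted(config.scaffold_lengths.items())}
    )


@dataclass
class SampleGenome:
    """A sample's haplotype-resolved genome with its liftover to reference."""

    sample_id: str
    reference: ScaffoldSet
    scaffolds: ScaffoldSet          # haplotype scaffolds, names "<scaf>|hapA/B"
    liftover: LiftoverMap
    config: TruthConfig


def _unit_copy_blocks(
    config: TruthConfig, reference: ScaffoldSet, copy_idx: int
) -> tuple[list[LiftoverBlock], str]:
    """Blocks and sequence of one unit copy, with its planned TEs and variants."""
    unit = config.dup_unit
    edits: list[tuple[int, str, object]] = []  # (offset, kind, payload)
    for te in config.te_plan:
        if copy_idx in te.copies:
            edits.append((te.offset, "te", te))
    for v in config.variant_plan:
        if copy_idx in v.copies:
            edits.append((v.offset, "var", v))
    edits.sort(key=lambda t: t[0])
    blocks: list[LiftoverBlock] = []
    seqs: list[str] = []
    cur = unit.start
    for offset, kind, payload in edits:
        at = unit.start + offset
        if at > cur:
            blocks.append(LiftoverBlock(at - cur, unit.scaffold, cur))
            seqs.append(reference[unit.scaffold][cur:at])
            cur = at
        if kind == "te":
            te: TEInsertion = payload
            seq = te_sequence(te.name, te.length, config.seed)
            blocks.append(LiftoverBlock(te.length, None, None, label=te.name))
            seqs.append(seq)
        else:
            v: VariantPlan = payload
            if v.kind == "del":
                cur = at + v.length    # skip reference bases -> D in reads
            else:
                ins = te_sequence(f"ins:{v.name}", v.length, config.seed)
                blocks.append(LiftoverBlock(v.length, None, None, label=v.name))
                seqs.append(ins)
    if cur < unit.end:
        blocks.append(LiftoverBlock(unit.end - cur, unit.scaffold, cur))
        seqs.append(reference[unit.scaffold][cur : unit.end])
    return blocks, "".join(seqs)


def build_truth_genome(config: TruthConfig) -> tuple[ScaffoldSet, SampleGenome]:
    """Construct (reference, sample genome) for the configured scenario.

    Haplotype A of the focal scaffold carries ``copies_per_genome - 1``
    direct head-to-tail copies of the unit; haplotype B carries one (the
    baseline).  Native copy indices 0..copies-2 live on haplotype A and
    index copies-1 is the haplotype-B copy.  The translocated amplicon, if
    planned, is inserted into haplotype A of its target scaffold.
    """
    reference = make_reference(config)
    unit = config.dup_unit
    blocks: dict[str, list[LiftoverBlock]] = {}
    seqs: dict[str, str] = {}

    for scaf in sorted(config.scaffold_lengths):
        L = config.scaffold_lengths[scaf]
        for hap in ("hapA", "hapB"):
            name = f"{scaf}|{hap}"
            blist: list[LiftoverBlock] = []
            parts: list[str] = []
            if scaf == unit.scaffold:
                if hap == "hapA":
                    copy_indices = range(config.copies_per_genome - 1)
                else:
                    copy_indices = [config.copies_per_genome - 1]
                if unit.start > 0:
                    blist.append(LiftoverBlock(unit.start, scaf, 0))
                    parts.append(reference[scaf][: unit.start])
                for ci in copy_indices:
                    cb, cs = _unit_copy_blocks(config, reference, ci)
                    blist.extend(cb)
                    parts.append(cs)
                if unit.end < L:
                    blist.append(LiftoverBlock(L - unit.end, scaf, unit.end))
                    parts.append(reference[scaf][unit.end :])
            elif (
                config.translocation is not None
                and scaf == config.translocation.target_scaffold
                and hap == "hapA"
            ):
                tr = config.translocation
                a_start = unit.start + tr.amplicon_offset
                a_end = a_start + tr.amplicon_length
                if a_end > unit.end:
                    raise TruthConfigError("translocated amplicon exceeds unit")
                t = tr.target_offset
                blist.append(LiftoverBlock(t, scaf, 0))
                parts.append(reference[scaf][:t])
                # the translocated copy: amplicon sub-interval, with the TEs
                # planned for it (variants are native-copy features)
                amp_cfg_edits = [
                    te for te in config.te_plan if te.in_translocated
                ]
                cur = a_start
                for te in sorted(amp_cfg_edits, key=lambda x: x.offset):
                    at = unit.start + te.offset
                    if not (a_start <= at <= a_end):
                        raise TruthConfigError(
                            f"TE {te.name} marked translocated but lies outside "
                            "the amplicon"
                        )
                    if at > cur:
                        blist.append(LiftoverBlock(at - cur, unit.scaffold, cur))
                        parts.append(reference[unit.scaffold][cur:at])
                        cur = at
                    blist.append(LiftoverBlock(te.length, None, None, label=te.name))
                    parts.append(te_sequence(te.name, te.length, config.seed))
                if cur < a_end:
                    blist.append(LiftoverBlock(a_end - cur, unit.scaffold, cur))
                    parts.append(reference[unit.scaffold][cur:a_end])
                blist.append(LiftoverBlock(L - t, scaf, t))
                parts.append(reference[scaf][t:])
            else:
                blist.append(LiftoverBlock(L, scaf, 0))
                parts.append(reference[scaf])
            blocks[name] = blist
            seqs[name] = "".join(parts)

    sample_scaffolds = ScaffoldSet(seqs)
    liftover = LiftoverMap(blocks)
    assert liftover.tiles_exactly(sample_scaffolds)
    genome = SampleGenome(
        sample_id="test",
        reference=reference,
        scaffolds=sample_scaffolds,
        liftover=liftover,
        config=config,
    )
    return reference, genome


def baseline_genome(config: TruthConfig, sample_id: str = "ref") -> SampleGenome:
    """The unrearranged comparator: both haplotypes identical to reference."""
    reference = make_reference(config)
    blocks = {}
    seqs = {}
    for scaf in sorted(config.scaffold_lengths):
        L = config.scaffold_lengths[scaf]
        for hap in ("hapA", "hapB"):
            name = f"{scaf}|{hap}"
            blocks[name] = [LiftoverBlock(L, scaf, 0)]
            seqs[name] = reference[scaf]
    return SampleGenome(
        sample_id=sample_id,
        reference=reference,
        scaffolds=ScaffoldSet(seqs),
        liftover=LiftoverMap(blocks),
        config=config,
    )


# ---------------------------------------------------------------------------
# Read simulation: projection of sample reads to reference coordinates
# ---------------------------------------------------------------------------

def _project_pieces(
    pieces: list[LiftoverBlock], seq: str
) -> AlignmentRecord | None:
    """Turn a block decomposition of one read into a reference alignment.

    Maximal reference-colinear runs (adjacent pieces on one scaffold whose
    reference gap is 0..MAX_SMALL_INDEL, or small novel pieces bridged by a
    contiguous resumption) are assembled; the run with the most matched
    bases anchors the read and everything outside it is soft-clipped.
    """
    runs: list[tuple[int, int, int, str, int, list[tuple[str, int]]]] = []
    # each run: (qstart, qend, m_bases, scaffold, ref_pos, cigar_ops)
    i, q = 0, 0
    n = len(pieces)
    while i < n:
        p = pieces[i]
        if not p.is_ref:
            q += p.length
            i += 1
            continue
        run_qstart = q
        scaf = p.ref_scaffold
        ref_pos = p.ref_start
        ops: list[tuple[str, int]] = [("M", p.length)]
        m_bases = p.length
        ref_end = p.ref_start + p.length
        q += p.length
        i += 1
        while i < n:
            nxt = pieces[i]
            if nxt.is_ref and nxt.ref_scaffold == scaf:
                gap = nxt.ref_start - ref_end
                if gap == 0:
                    ops.append(("M", nxt.length))
                elif 0 < gap <= MAX_SMALL_INDEL:
                    ops.append(("D", gap))
                    ops.append(("M", nxt.length))
                else:
                    break
                m_bases += nxt.length
                ref_end = nxt.ref_start + nxt.length
                q += nxt.length
                i += 1
            elif (
                not nxt.is_ref
                and nxt.length <= MAX_SMALL_INDEL
                and i + 1 < n
                and pieces[i + 1].is_ref
                and pieces[i + 1].ref_scaffold == scaf
                and pieces[i + 1].ref_start == ref_end
            ):
                ops.append(("I", nxt.length))
                q += nxt.length
                i += 1
            else:
                break
        runs.append((run_qstart, q, m_bases, scaf, ref_pos, ops))
    if not runs:
        return None
    best = max(runs, key=lambda r: (r[2], -r[0]))
    qstart, qend, _m, scaf, ref_pos, ops = best
    # merge consecutive M ops produced by gap-0 adjacency
    merged: list[tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    cigar: list[tuple[str, int]] = []
    if qstart > 0:
        cigar.append(("S", qstart))
    cigar.extend(merged)
    if qend < len(seq):
        cigar.append(("S", len(seq) - qend))
    return AlignmentRecord(
        read_id="",
        sample_id="",
        layer="DNA",
        scaffold=scaf,
        pos=ref_pos,
        cigar=tuple(cigar),
        seq=seq,
        mapq=60,
    )


def simulate_dna_reads(
    genome: SampleGenome,
    depth: float | None = None,
    read_len: int | None = None,
    seed: int | None = None,
) -> list[AlignmentRecord]:
    """Uniform error-free reads from the diploid sample, projected to reference.

    ``depth`` is the expected coverage of a single-copy reference position
    summed over both haplotypes, so a position inside a c-copy unit receives
    about (c/2) * depth.
    """
    cfg = genome.config
    depth = cfg.depth if depth is None else depth
    read_len = cfg.read_len if read_len is None else read_len
    seed = cfg.seed if seed is None else seed
    if depth is None or depth <= 0:
        raise TruthConfigError("depth must be given and > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    names = sorted(genome.scaffolds)
    lengths = np.array([genome.scaffolds.length_of(n) for n in names])
    usable = np.maximum(lengths - read_len + 1, 0)
    total = int(lengths.sum())
    n_reads = int(round(depth / 2.0 * total / read_len))
    scaf_idx = rng.choice(len(names), size=n_reads, p=usable / usable.sum())
    start_arr = (rng.random(n_reads) * usable[scaf_idx]).astype(np.int64)
    out: list[AlignmentRecord] = []
    for k in range(n_reads):
        name = names[scaf_idx[k]]
        start = int(start_arr[k])
        pieces = genome.liftover.pieces(name, start, start + read_len)
        seq = genome.scaffolds[name][start : start + read_len]
        rec = _project_pieces(pieces, seq)
        if rec is None:
            continue
        out.append(
            AlignmentRecord(
                read_id=f"{genome.sample_id}:dna:{name}:{start}:{k}",
                sample_id=genome.sample_id,
                layer="DNA",
                scaffold=rec.scaffold,
                pos=rec.pos,
                cigar=rec.cigar,
                seq=rec.seq,
            )
        )
    return out


# -- transcripts -------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    """A named chain of reference pieces in ascending genome-walk order.

    Pieces are (scaffold, start, end) reference intervals; a backward jump
    between consecutive pieces represents a tandem-junction crossing and
    projects to a soft clip, a small forward gap to a deletion.
    """

    name: str
    pieces: tuple[tuple[str, int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.pieces)

    def sequence(self, reference: ScaffoldSet) -> str:
        return "".join(reference[sc][s:e] for sc, s, e in self.pieces)

    def blocks(self) -> list[LiftoverBlock]:
        return [LiftoverBlock(e - s, sc, s) for sc, s, e in self.pieces]


def gene_transcript(gene: GeneModel, name: str | None = None) -> Transcript:
    """Wild-type transcript: the gene's exons in ascending genomic order."""
    pieces = tuple(
        (e.scaffold, e.start, e.end)
        for e in sorted(gene.exons, key=lambda x: x.start)
    )
    return Transcript(name or gene.gene_id, pieces)


def fusion_transcript(
    promoter_donor: GeneModel,
    body_donor: GeneModel,
    unit: GenomicInterval,
    name: str = "fusion",
) -> Transcript:
    """Chimeric junction transcript created by the head-to-tail repeat.

    In ascending genome-walk order the chain is: the body donor's exon
    material inside the unit (its trailing exons, plus the inside-unit part
    of any exon straddling the unit end), then - across the tandem junction -
    the promoter donor's leading exons inside the unit.
    """
    body_pieces = []
    for e in sorted(body_donor.exons, key=lambda x: x.start):
        if e.end <= unit.start or e.start >= unit.end:
            continue
        body_pieces.append((e.scaffold, max(e.start, unit.start), min(e.end, unit.end)))
    prom_pieces = [
        (e.scaffold, e.start, e.end)
        for e in sorted(promoter_donor.exons, key=lambda x: x.start)
        if unit.contains(e)
    ]
    if not body_pieces or not prom_pieces:
        raise TruthConfigError("fusion transcript requires exon material inside the unit")
    return Transcript(name, tuple(body_pieces + prom_pieces))


def simulate_rna_reads(
    reference: ScaffoldSet,
    transcripts: dict[Transcript, float],
    sample_id: str,
    depth: float,
    read_len: int,
    seed: int,
) -> list[AlignmentRecord]:
    """Reads drawn from spliced transcripts, projected to reference.

    The read count of a transcript is depth * level * length / read_len;
    start positions are uniform along the transcript.
    """
    if seed is None:
        raise TruthConfigError("seed must be explicit")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out: list[AlignmentRecord] = []
    for tx in sorted(transcripts, key=lambda t: t.name):
        level = transcripts[tx]
        if tx.length < read_len:
            raise TruthConfigError(
                f"read length {read_len} exceeds transcript {tx.name!r} "
                f"length {tx.length}"
            )
        n_reads = int(round(depth * level * tx.length / read_len))
        seq = tx.sequence(reference)
        blocks = tx.blocks()
        lmap = LiftoverMap({"tx": blocks})
        starts = rng.integers(0, tx.length - read_len + 1, size=n_reads)
        for k, start in enumerate(starts):
            start = int(start)
            pieces = lmap.pieces("tx", start, start + read_len)
            rec = _project_pieces(pieces, seq[start : start + read_len])
            if rec is None:
                continue
            out.append(
                AlignmentRecord(
                    read_id=f"{sample_id}:rna:{tx.name}:{start}:{k}",
                    sample_id=sample_id,
                    layer="RNA",
                    scaffold=rec.scaffold,
                    pos=rec.pos,
                    cigar=rec.cigar,
                    seq=rec.seq,
                )
            )
    return out


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    levels: dict[tuple[str, str], float],
    housekeepers: tuple[str, ...],
    replicates: int,
    seed: int,
    sd: float = 0.15,
    base: float = 20.0,
    assay: str = "expression",
) -> pd.DataFrame:
    """Ct values under the efficiency-2 model: Ct = base - log2(level) + noise.

    ``levels`` maps (sample, target) to the true relative quantity;
    housekeepers are pinned to level 1 in every sample listed.  Only Ct
    differences matter downstream, so ``base`` is arbitrary but fixed.
    """
    if replicates < 2:
        raise TruthConfigError("replicates must be >= 2")
    for (sample, target), level in levels.items():
        if level <= 0:
            raise TruthConfigError(f"nonpositive level for {(sample, target)}")
    samples = sorted({s for s, _ in levels})
    full = dict(levels)
    for s in samples:
        for hk in housekeepers:
            full.setdefault((s, hk), 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows = []
    for (sample, target) in sorted(full):
        level = full[(sample, target)]
        for rep in range(1, replicates + 1):
            ct = base - math.log2(level) + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "assay": assay,
                    "replicate": rep,
                    "ct": round(ct, 6),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose-mortality bioassay
# ---------------------------------------------------------------------------

def simulate_bioassay(
    lc50: float,
    slope: float,
    doses: list[float],
    n_per_dose: int,
    control_mortality: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Binomial deaths under a probit dose-response with control mortality.

    probit(p') = slope * (log10 dose - log10 lc50); the observed mortality is
    p = c + (1 - c) p'.  A dose-0 control row is emitted when c is modelled.
    Returns columns dose, n, dead (one row per replicate vial).
    """
    if lc50 <= 0 or slope <= 0:
        raise TruthConfigError("lc50 and slope must be > 0")
    if any(d <= 0 for d in doses):
        raise TruthConfigError("doses must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    rows = []
    for _ in range(replicates):
        rows.append(
            {
                "dose": 0.0,
                "n": n_per_dose,
                "dead": int(rng.binomial(n_per_dose, control_mortality)),
            }
        )
    for dose in doses:
        p_raw = norm.cdf(slope * (math.log10(dose) - math.log10(lc50)))
        p = control_mortality + (1 - control_mortality) * p_raw
        for _ in range(replicates):
            rows.append(
                {"dose": dose, "n": n_per_dose, "dead": int(rng.binomial(n_per_dose, p))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

def simulate_de_tables(
    core_plan: dict[str, int],
    n_test: int,
    n_ref: int,
    n_background: int,
    seed: int,
    sig_rate: float = 0.3,
    q_threshold: float = 0.05,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One DE table per (test clone, reference clone) pair.

    Planned-core genes are significant with their planned sign in every
    pair; background genes are significant (random sign) in a ~sig_rate
    fraction of pairs, so the expected number surviving a k-way consistent
    intersection is N * sig_rate**k - negligible for k = 36.
    """
    for gene, sign in core_plan.items():
        if sign not in (-1, 1):
            raise TruthConfigError(f"core gene {gene} sign must be +-1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    genes = list(core_plan) + [f"bg{i:05d}" for i in range(n_background)]
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for ti in range(1, n_test + 1):
        for ri in range(1, n_ref + 1):
            rows = []
            for g in genes:
                if g in core_plan:
                    q = float(rng.uniform(1e-8, q_threshold * 0.9))
                    lfc = core_plan[g] * float(rng.uniform(1.0, 4.0))
                else:
                    if rng.random() < sig_rate:
                        q = float(rng.uniform(1e-8, q_threshold * 0.9))
                        lfc = float(rng.choice([-1, 1]) * rng.uniform(0.5, 3.0))
                    else:
                        q = float(rng.uniform(q_threshold, 1.0))
                        lfc = float(rng.normal(0.0, 0.3))
                rows.append({"gene": g, "log2fc": round(lfc, 4), "q": q})
            tables[(f"Mn{ti}", f"Mp{ri}")] = pd.DataFrame(rows)
    return tables


# ---------------------------------------------------------------------------
# Randomised TE insertion histories (for ordering soundness checks)
# ---------------------------------------------------------------------------

def random_te_history(rng: np.random.Generator, n_elements: int = 3):
    """Draw a random mutational history and the observations it implies.

    Events: a duplication (always), optionally a translocation after it, and
    ``n_elements`` element insertions at random times.  An element inserted
    before the duplication is present in every copy (and in the translocated
    copy); one inserted after the duplication lands in a random proper
    subset of native copies, and is carried by the translocated copy only if
    it was present in the source copy before the translocation; one inserted
    after the translocation lands either in a native subset or only in the
    translocated copy.

    Returns (observations, true_order) where observations is a list of
    (copy_id, locus_class, frozenset(elements)) and true_order maps each
    event name to its (strictly ordered) time.
    """
    n_native = int(rng.integers(2, 6))
    has_transloc = bool(rng.random() < 0.6)
    times = {"dup": 0.0}
    if has_transloc:
        times["transloc"] = float(rng.uniform(0.1, 1.0))
    native_sets: list[set[str]] = [set() for _ in range(n_native)]
    transloc_set: set[str] = set()
    source_copy = int(rng.integers(0, n_native))  # copy the translocation copied
    for j in range(n_elements):
        name = f"E{j}"
        t = float(rng.uniform(-0.5, 1.5))
        times[name] = t
        if t < times["dup"]:
            for s in native_sets:
                s.add(name)
            if has_transloc:
                transloc_set.add(name)
        else:
            if has_transloc and t > times["transloc"] and rng.random() < 0.3:
                transloc_set.add(name)  # inserted into the translocated copy
            else:
                k = int(rng.integers(1, n_native))  # proper subset
                for idx in rng.choice(n_native, size=k, replace=False):
                    native_sets[int(idx)].add(name)
                if (
                    has_transloc
                    and t < times["transloc"]
                    and name in native_sets[source_copy]
                ):
                    transloc_set.add(name)
    observations = [
        (f"copy{i}", "native", frozenset(s)) for i, s in enumerate(native_sets)
    ]
    if has_transloc:
        observations.append(("copyT", "translocated", frozenset(transloc_set)))
    return observations, times
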