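"""Text-format I/O and the coordinate conventions shared by every stage.

Internal coordinates are 0-based half-open everywhere; anything printed or
parsed from the standard 1-based-inclusive formats (GFF3, SAM POS) is
converted exactly once, at the I/O boundary.  Supported formats are the
plain-text subsets the pipeline actually touches: FASTA references, a GFF3
subset with ``gene``/``exon``/``promoter`` features, a SAM-text subset whose
CIGARs use only M/I/D/S, and TSV tables with a header row.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")
CIGAR_OPS = frozenset("MIDS")
_CIGAR_RE = re.compile(r"(\d+)([A-Za-z=])")


class FormatError(ValueError):
    """A record violated the format subset or a declared invariant."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based interval on a named scaffold.

    ``from_1based``/``to_1based`` convert to and from the 1-based inclusive
    convention used in GFF3 and in printed breakpoint coordinates; the two
    conversions are exact inverses: (s, e) 1-based inclusive <-> (s-1, e)
    0-based half-open.
    """

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    @classmethod
    def from_1based(cls, scaffold: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive (GFF3-style) coordinates."""
        return cls(scaffold, start1 - 1, end1)

    def to_1based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive coordinates."""
        return self.start + 1, self.end


# ---------------------------------------------------------------------------
# Scaffolds (FASTA)
# ---------------------------------------------------------------------------

class ScaffoldSet:
    """Mapping of scaffold name -> uppercase ACGTN sequence string."""

    def __init__(self, sequences: Mapping[str, str]):
        seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = str(seq).upper()
            if len(seq) < 1:
                raise FormatError(f"scaffold {name!r} is empty")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FormatError(
                    f"scaffold {name!r} contains invalid characters {sorted(bad)}"
                )
            if name in seqs:
                raise FormatError(f"duplicate scaffold name {name!r}")
            seqs[name] = seq
        self._seqs = seqs

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise KeyError(
                f"unknown scaffold {name!r}; known: {sorted(self._seqs)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ScaffoldSet) and self._seqs == other._seqs

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def length_of(self, name: str) -> int:
        return len(self[name])

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self[interval.scaffold]
        if interval.end > len(seq):
            raise FormatError(
                f"interval {interval} exceeds scaffold length {len(seq)}"
            )
        return seq[interval.start : interval.end]


def read_fasta(handle: TextIO | str) -> ScaffoldSet:
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_fasta(fh)
    return ScaffoldSet({rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")})


def write_fasta(scaffolds: ScaffoldSet, handle: TextIO | str) -> None:
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_fasta(scaffolds, fh)
            return
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in scaffolds.items()
    ]
    SeqIO.write(records, handle, "fasta")


# ---------------------------------------------------------------------------
# Alignments (SAM-text subset)
# ---------------------------------------------------------------------------

def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Decode a CIGAR string into ordered (op, length) pairs.

    Only M, I, D and S are accepted; anything else (N/H/P/X/=) is rejected
    rather than silently reinterpreted.
    """
    if cigar in ("", "*"):
        raise FormatError("empty CIGAR")
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR {cigar!r}")
        op = m.group(2)
        if op not in CIGAR_OPS:
            raise FormatError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        n = int(m.group(1))
        if n <= 0:
            raise FormatError(f"zero-length op in CIGAR {cigar!r}")
        ops.append((op, n))
        pos = m.end()
    if pos != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return ops


def cigar_to_string(ops: Sequence[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def reference_span(ops: Sequence[tuple[str, int]]) -> int:
    """Number of reference bases consumed (M and D ops)."""
    return sum(n for op, n in ops if op in "MD")


def query_span(ops: Sequence[tuple[str, int]]) -> int:
    """Number of read bases consumed (M, I and S ops)."""
    return sum(n for op, n in ops if op in "MIS")


@dataclass(frozen=True, slots=True)
class AlignmentRecord:
    """One mapped read: the evidence substrate for every DNA/RNA stage.

    ``pos`` is the 0-based leftmost mapped reference base (converted from the
    SAM 1-based POS at parse time).  ``cigar`` is an ordered (op, length)
    tuple over {M, I, D, S}; S ops may appear only at the ends.
    """

    read_id: str
    sample_id: str
    layer: str  # "DNA" | "RNA"
    scaffold: str
    pos: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.layer not in ("DNA", "RNA"):
            raise FormatError(f"layer must be DNA or RNA, got {self.layer!r}")
        if query_span(self.cigar) != len(self.seq):
            raise FormatError(
                f"read {self.read_id}: CIGAR consumes {query_span(self.cigar)} "
                f"read bases but SEQ has length {len(self.seq)}"
            )
        for i, (op, _) in enumerate(self.cigar):
            if op == "S" and i not in (0, len(self.cigar) - 1):
                raise FormatError(
                    f"read {self.read_id}: internal S op in CIGAR"
                )
        if self.pos < 0:
            raise FormatError(f"read {self.read_id}: negative position")

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.pos + reference_span(self.cigar)

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar[-1][0] == "S" else 0

    @property
    def left_clipped_seq(self) -> str:
        return self.seq[: self.left_clip]

    @property
    def right_clipped_seq(self) -> str:
        return self.seq[len(self.seq) - self.right_clip :] if self.right_clip else ""

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query index, reference position) for every M-op base."""
        q, r = 0, self.pos
        for op, n in self.cigar:
            if op == "M":
                for k in range(n):
                    yield q + k, r + k
                q += n
                r += n
            elif op == "I" or op == "S":
                q += n
            elif op == "D":
                r += n


def parse_alignments(
    handle: TextIO | str | Iterable[str],
    sample_id: str = "sample",
    layer: str = "DNA",
    scaffolds: ScaffoldSet | None = None,
) -> list[AlignmentRecord]:
    """Parse a SAM-text subset stream into AlignmentRecords.

    Header lines (``@``) are skipped.  Records failing an invariant are
    rejected with an error naming the offending line; nothing is silently
    repaired.  When ``scaffolds`` is given, RNAME must be a known scaffold
    and the aligned span must fit inside it.
    """
    if isinstance(handle, str):
        with open(handle) as fh:
            return parse_alignments(fh, sample_id, layer, scaffolds)
    records: list[AlignmentRecord] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise FormatError(
                f"line {lineno}: expected 11 tab-separated SAM fields, got {len(fields)}"
            )
        qname, _flag, rname, pos1, mapq, cigar = fields[0], fields[1], fields[2], fields[3], fields[4], fields[5]
        seq = fields[9]
        try:
            ops = parse_cigar(cigar)
            rec = AlignmentRecord(
                read_id=qname,
                sample_id=sample_id,
                layer=layer,
                scaffold=rname,
                pos=int(pos1) - 1,
                cigar=tuple(ops),
                seq=seq.upper(),
                mapq=int(mapq),
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if scaffolds is not None:
            if rname not in scaffolds:
                raise FormatError(
                    f"line {lineno}: unknown scaffold {rname!r}; "
                    f"known: {sorted(scaffolds)}"
                )
            if rec.reference_end > scaffolds.length_of(rname):
                raise FormatError(
                    f"line {lineno}: alignment extends past end of {rname!r}"
                )
        records.append(rec)
    return records


def write_alignments(records: Iterable[AlignmentRecord], handle: TextIO | str) -> None:
    """Write records as minimal SAM text (flag 0, no header)."""
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_alignments(records, fh)
            return
    for rec in records:
        handle.write(
            "\t".join(
                [
                    rec.read_id,
                    "0",
                    rec.scaffold,
                    str(rec.pos + 1),
                    str(rec.mapq),
                    cigar_to_string(rec.cigar),
                    "*",
                    "0",
                    "0",
                    rec.seq,
                    "*",
                ]
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# Gene models (GFF3 subset)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A gene with ordered exons and an optional promoter interval.

    Exons are stored in transcription order: ascending coordinates on the
    plus strand, descending on the minus strand.  All intervals are internal
    0-based half-open.
    """

    gene_id: str
    scaffold: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    promoter: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        by_coord = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_coord, by_coord[1:]):
            if a.end > b.start:
                raise FormatError(f"gene {self.gene_id}: overlapping exons")
        expected = by_coord if self.strand == "+" else by_coord[::-1]
        if tuple(expected) != self.exons:
            raise FormatError(
                f"gene {self.gene_id}: exons not in transcription order"
            )

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        if self.promoter is not None:
            starts.append(self.promoter.start)
            ends.append(self.promoter.end)
        return GenomicInterval(self.scaffold, min(starts), max(ends))


def parse_gene_models(
    handle: TextIO | str | Iterable[str],
    scaffolds: ScaffoldSet | None = None,
) -> dict[str, GeneModel]:
    """Parse a GFF3 subset (gene/exon/promoter with ID/Parent attributes)."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return parse_gene_models(fh, scaffolds)
    genes: dict[str, dict] = {}
    exons: list[tuple[str, GenomicInterval]] = []
    promoters: dict[str, GenomicInterval] = {}
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: expected 9 GFF3 columns")
        seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        try:
            iv = GenomicInterval.from_1based(seqid, int(start1), int(end1))
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if scaffolds is not None:
            if seqid not in scaffolds:
                raise FormatError(f"line {lineno}: unknown scaffold {seqid!r}")
            if iv.end > scaffolds.length_of(seqid):
                raise FormatError(
                    f"line {lineno}: feature outside scaffold bounds"
                )
        if ftype == "gene":
            gid = attr.get("ID")
            if gid is None:
                raise FormatError(f"line {lineno}: gene without ID")
            genes[gid] = {"scaffold": seqid, "strand": strand}
        elif ftype == "exon":
            parent = attr.get("Parent")
            if parent is None:
                raise FormatError(f"line {lineno}: exon without Parent")
            exons.append((parent, iv))
        elif ftype == "promoter":
            parent = attr.get("Parent")
            if parent is None:
                raise FormatError(f"line {lineno}: promoter without Parent")
            promoters[parent] = iv
        # other feature types in the stream are ignored
    for parent, _ in exons:
        if parent not in genes:
            raise FormatError(f"exon references unknown gene {parent!r}")
    models: dict[str, GeneModel] = {}
    for gid, info in genes.items():
        gexons = sorted(
            (iv for p, iv in exons if p == gid), key=lambda e: e.start
        )
        if not gexons:
            raise FormatError(f"gene {gid!r} has no exons")
        if info["strand"] == "-":
            gexons = gexons[::-1]
        models[gid] = GeneModel(
            gene_id=gid,
            scaffold=info["scaffold"],
            strand=info["strand"],
            exons=tuple(gexons),
            promoter=promoters.get(gid),
        )
    return models


def write_gene_models(models: Mapping[str, GeneModel], handle: TextIO | str) -> None:
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_gene_models(models, fh)
            return
    handle.write("##gff-version 3\n")
    for gid in sorted(models):
        g = models[gid]
        s1, e1 = g.span.to_1based()
        handle.write(
            f"{g.scaffold}\thostshift\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={gid}\n"
        )
        if g.promoter is not None:
            ps, pe = g.promoter.to_1based()
            handle.write(
                f"{g.scaffold}\thostshift\tpromoter\t{ps}\t{pe}\t.\t{g.strand}\t.\tParent={gid}\n"
            )
        for ex in sorted(g.exons, key=lambda e: e.start):
            xs, xe = ex.to_1based()
            handle.write(
                f"{g.scaffold}\thostshift\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\tParent={gid}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(handle: TextIO | str, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with a header row; fail loudly on missing columns."""
    df = pd.read_csv(handle, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"table is missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, handle: TextIO | str) -> None:
    df.to_csv(handle, sep="\t", index=False)


def validate_file(path: str, kind: str | None = None) -> str:
    """Validate a file against the format subset inferred from its suffix.

    Returns a short human-readable summary; raises FormatError on failure.
    """
    if kind is None:
        low = path.lower()
        if low.endswith((".fa", ".fasta")):
            kind = "fasta"
        elif low.endswith((".gff", ".gff3")):
            kind = "gff3"
        elif low.endswith(".sam"):
            kind = "sam"
        elif low.endswith((".tsv", ".txt")):
            kind = "tsv"
        else:
            raise FormatError(f"cannot infer format of {path!r}")
    if kind == "fasta":
        sc = read_fasta(path)
        return f"FASTA OK: {len(sc)} scaffold(s)"
    if kind == "gff3":
        models = parse_gene_models(path)
        return f"GFF3 OK: {len(models)} gene model(s)"
    if kind == "sam":
        recs = parse_alignments(path)
        return f"SAM OK: {len(recs)} alignment(s)"
    if kind == "tsv":
        df = read_table(path)
        return f"TSV OK: {len(df)} row(s), columns {list(df.columns)}"
    raise FormatError(f"unknown format kind {kind!r}")
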