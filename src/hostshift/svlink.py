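"""Soft-clip breakpoint clustering, junction linking and tandem-dup calling.

A rearrangement junction leaves two reciprocal signatures in a mapped read
set: reads running off the last base of the duplicated unit whose clipped
tails equal the unit-start sequence (right-side cluster), and reads whose
mapped portion begins at the unit start with clipped heads equal to the
unit-end sequence (left-side cluster).  Clusters are located, given a
column-majority consensus, and linked back to the reference by exact seed
matching plus ungapped extension; a reciprocally linked same-scaffold pair
in head-to-tail orientation is a direct tandem duplication.

Coordinate convention: a cluster's ``position`` is the 0-based reference
coordinate of the junction point - for right-side clusters the first base
after the aligned span, for left-side clusters the first aligned base.  The
printed (1-based) positions of the two clusters of a tandem junction are
therefore the first base of the unit and the first base after it, so the
printed difference equals the unit length exactly.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cnvscan import AmplifiedSegment
from .formats_io import AlignmentRecord, GenomicInterval, ScaffoldSet

DEFAULT_MIN_CLIP = 10
DEFAULT_CLUSTER_TOL = 3
DEFAULT_MIN_SEED = 15
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MINORITY_MIN_FRACTION = 0.03


@dataclass(frozen=True)
class ClipCluster:
    scaffold: str
    position: int          # 0-based junction coordinate (see module docstring)
    side: str              # "left" | "right"
    n_clipped: int
    n_crossing: int
    consensus: str

    @property
    def clip_fraction(self) -> float:
        return self.n_clipped / self.n_crossing if self.n_crossing else float("nan")

    @property
    def printed_position(self) -> int:
        """1-based coordinate as printed in breakpoint reports."""
        return self.position + 1


@dataclass(frozen=True)
class Junction:
    cluster: ClipCluster
    partner_scaffold: str | None
    partner_position: int | None   # 0-based junction coordinate at the partner
    identity: float
    classification: str            # tandem_dup | interscaffold_insertion | unresolved


@dataclass(frozen=True)
class TandemDupCall:
    unit: GenomicInterval          # internal 0-based half-open
    supporting: tuple[Junction, ...]
    mean_clip_fraction: float
    copy_fold: float | None        # from the overlapping amplified segment
    depth_supported: bool

    @property
    def unit_length(self) -> int:
        return self.unit.length

    @property
    def printed_breakpoints(self) -> tuple[int, int]:
        """(first unit base, first base after the unit), both 1-based."""
        return self.unit.start + 1, self.unit.end + 1


# ---------------------------------------------------------------------------
# Clip clustering
# ---------------------------------------------------------------------------

def _consensus(seqs: Sequence[str], align_right: bool) -> str:
    """Column-wise majority; ties become N.  Left-clip consensi are aligned
    on their right edge (the base abutting the junction)."""
    if not seqs:
        return ""
    width = max(len(s) for s in seqs)
    cols: list[str] = []
    for j in range(width):
        counts: Counter[str] = Counter()
        for s in seqs:
            idx = j if not align_right else len(s) - width + j
            if not align_right:
                if idx < len(s):
                    counts[s[idx]] += 1
            else:
                if idx >= 0:
                    counts[s[idx]] += 1
        best = counts.most_common(2)
        if len(best) > 1 and best[0][1] == best[1][1]:
            cols.append("N")
        else:
            cols.append(best[0][0])
    return "".join(cols)


def collect_clip_clusters(
    alignments: Iterable[AlignmentRecord],
    min_clip: int = DEFAULT_MIN_CLIP,
    cluster_tol: int = DEFAULT_CLUSTER_TOL,
    region: GenomicInterval | None = None,
) -> list[ClipCluster]:
    """Group reads with terminal soft clips >= min_clip into clusters.

    Clip positions agreeing within ``cluster_tol`` merge.  ``n_crossing``
    counts every read whose extent - aligned span plus clipped tails -
    crosses the junction with at least one base on each side, so clipped
    reads themselves are part of the denominator and the clip fraction of a
    c-copy tandem junction tends to (c-2)/c.
    """
    if min_clip < 5:
        raise ValueError("min_clip must be >= 5")
    alignments = list(alignments)
    events: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
    extents: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rec in alignments:
        if region is not None and rec.scaffold != region.scaffold:
            continue
        extents[rec.scaffold].append(
            (rec.pos - rec.left_clip, rec.reference_end + rec.right_clip)
        )
        if rec.right_clip >= min_clip:
            p = rec.reference_end
            if region is None or region.start <= p < region.end:
                events[(rec.scaffold, "right")].append((p, rec.right_clipped_seq))
        if rec.left_clip >= min_clip:
            p = rec.pos
            if region is None or region.start <= p < region.end:
                events[(rec.scaffold, "left")].append((p, rec.left_clipped_seq))
    # sorted extent arrays allow counting junction-crossing reads in O(log n)
    ext_arrays: dict[str, tuple] = {}
    for scaf, pairs in extents.items():
        a = np.array(pairs, dtype=np.int64)
        order = np.argsort(a[:, 0], kind="stable")
        starts = a[order, 0]
        ends = a[order, 1]
        ext_arrays[scaf] = (starts, np.sort(ends))
    clusters: list[ClipCluster] = []
    for (scaffold, side), evs in sorted(events.items()):
        evs.sort(key=lambda t: t[0])
        group: list[tuple[int, str]] = []
        for ev in evs:
            if group and ev[0] - group[-1][0] > cluster_tol:
                clusters.append(
                    _finish_cluster(scaffold, side, group, ext_arrays[scaffold])
                )
                group = []
            group.append(ev)
        if group:
            clusters.append(_finish_cluster(scaffold, side, group, ext_arrays[scaffold]))
    return clusters


def _finish_cluster(
    scaffold: str,
    side: str,
    group: list[tuple[int, str]],
    ext: tuple,
) -> ClipCluster:
    position = Counter(p for p, _ in group).most_common(1)[0][0]
    consensus = _consensus([s for _, s in group], align_right=(side == "left"))
    starts, ends_sorted = ext
    # reads with ext_start <= position-1 and ext_end >= position+1
    n_start_ok = int(np.searchsorted(starts, position - 1, side="right"))
    n_end_bad = int(np.searchsorted(ends_sorted, position + 1, side="left"))
    n_crossing = max(0, n_start_ok - n_end_bad)
    return ClipCluster(
        scaffold=scaffold,
        position=position,
        side=side,
        n_clipped=len(group),
        n_crossing=n_crossing,
        consensus=consensus,
    )


# ---------------------------------------------------------------------------
# Junction linking
# ---------------------------------------------------------------------------

def _seed_hits(reference: ScaffoldSet, seed: str) -> list[tuple[str, int]]:
    hits = []
    for name, seq in reference.items():
        start = 0
        while True:
            i = seq.find(seed, start)
            if i < 0:
                break
            hits.append((name, i))
            start = i + 1
    return hits


def link_junction(
    cluster: ClipCluster,
    reference: ScaffoldSet,
    min_seed: int = DEFAULT_MIN_SEED,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> Junction:
    """Locate a cluster's clipped consensus on the reference.

    The junction-proximal end of the consensus (its first bases for a
    right-side cluster, its last for a left-side one) is used as an exact
    seed; the full consensus is then compared by ungapped extension and a
    junction is emitted only when identity >= min_identity (N columns never
    match).  Head-to-tail same-scaffold linkage classifies as tandem_dup,
    a different scaffold as interscaffold_insertion, everything else is
    unresolved.
    """
    cons = cluster.consensus
    if len(cons) < min_seed:
        return Junction(cluster, None, None, 0.0, "unresolved")
    seed = cons[:min_seed] if cluster.side == "right" else cons[-min_seed:]
    if "N" in seed:
        return Junction(cluster, None, None, 0.0, "unresolved")
    best: tuple[float, str, int] | None = None
    for scaf, hit in _seed_hits(reference, seed):
        if cluster.side == "right":
            window_start = hit
        else:
            window_start = hit + min_seed - len(cons)
        if window_start < 0 or window_start + len(cons) > reference.length_of(scaf):
            continue
        ref_window = reference[scaf][window_start : window_start + len(cons)]
        matches = sum(
            1 for a, b in zip(cons, ref_window) if a == b and a != "N"
        )
        identity = matches / len(cons)
        if best is None or identity > best[0]:
            if cluster.side == "right":
                partner = window_start               # partner's first base
            else:
                partner = window_start + len(cons)   # first base after partner
            best = (identity, scaf, partner)
    if best is None or best[0] < min_identity:
        return Junction(cluster, None, None, best[0] if best else 0.0, "unresolved")
    identity, scaf, partner = best
    if scaf != cluster.scaffold:
        cls = "interscaffold_insertion"
    elif cluster.side == "right" and partner < cluster.position:
        cls = "tandem_dup"
    elif cluster.side == "left" and partner > cluster.position:
        cls = "tandem_dup"
    else:
        cls = "unresolved"
    return Junction(cluster, scaf, partner, identity, cls)


# ---------------------------------------------------------------------------
# Tandem duplication call
# ---------------------------------------------------------------------------

def call_tandem_duplication(
    junctions: Iterable[Junction],
    segments: Iterable[AmplifiedSegment] = (),
    tol: int = DEFAULT_CLUSTER_TOL,
) -> TandemDupCall:
    """Compose reciprocal tandem_dup junctions into one unit call.

    The unit is [left-cluster position, right-cluster position) half-open,
    so its length equals the difference of the two printed 1-based
    positions.  A call overlapping an amplified segment carries that
    segment's copy-fold estimate (2**mean log2 ratio); otherwise it is
    flagged depth-unsupported.
    """
    tandem = [j for j in junctions if j.classification == "tandem_dup"]
    if not tandem:
        raise ValueError("no tandem_dup junction supplied")
    rights = [j for j in tandem if j.cluster.side == "right"]
    lefts = [j for j in tandem if j.cluster.side == "left"]
    support: list[Junction] = []
    if rights and lefts:
        # reciprocal pair: each cluster's partner is the other's position
        pair = None
        for jr in rights:
            for jl in lefts:
                if (
                    abs(jr.partner_position - jl.cluster.position) <= tol
                    and abs(jl.partner_position - jr.cluster.position) <= tol
                ):
                    pair = (jl, jr)
                    break
            if pair:
                break
        if pair is None:
            pair = (lefts[0], rights[0])
        jl, jr = pair
        start, end = jl.cluster.position, jr.cluster.position
        support = [jl, jr]
    elif rights:
        jr = max(rights, key=lambda j: j.cluster.n_clipped)
        start, end = jr.partner_position, jr.cluster.position
        support = [jr]
    else:
        jl = max(lefts, key=lambda j: j.cluster.n_clipped)
        start, end = jl.cluster.position, jl.partner_position
        support = [jl]
    unit = GenomicInterval(support[0].cluster.scaffold, start, end)
    fracs = [j.cluster.clip_fraction for j in support if j.cluster.n_crossing]
    mean_frac = sum(fracs) / len(fracs) if fracs else float("nan")
    copy_fold = None
    supported = False
    for seg in segments:
        if seg.interval.overlaps(unit):
            copy_fold = 2.0 ** seg.mean_log2_ratio
            supported = True
            break
    return TandemDupCall(
        unit=unit,
        supporting=tuple(support),
        mean_clip_fraction=mean_frac,
        copy_fold=copy_fold,
        depth_supported=supported,
    )


def junction_pair_from_breakpoints(
    scaffold: str, left_printed: int, right_printed: int
) -> list[Junction]:
    """Build a reciprocal junction pair from printed 1-based breakpoints.

    ``left_printed`` is the first base of the unit and ``right_printed`` the
    first base after it, as printed in breakpoint reports; the resulting
    call has unit length right_printed - left_printed.
    """
    left = ClipCluster(scaffold, left_printed - 1, "left", 0, 0, "")
    right = ClipCluster(scaffold, right_printed - 1, "right", 0, 0, "")
    return [
        Junction(left, scaffold, right_printed - 1, 1.0, "tandem_dup"),
        Junction(right, scaffold, left_printed - 1, 1.0, "tandem_dup"),
    ]


# ---------------------------------------------------------------------------
# Minority (secondary) breakpoints
# ---------------------------------------------------------------------------

def minority_breakpoint_scan(
    alignments: Iterable[AlignmentRecord],
    gene: GenomicInterval,
    reference: ScaffoldSet,
    flank: int = 5_000,
    min_fraction: float = DEFAULT_MINORITY_MIN_FRACTION,
    min_clip: int = DEFAULT_MIN_CLIP,
    cluster_tol: int = DEFAULT_CLUSTER_TOL,
    min_seed: int = DEFAULT_MIN_SEED,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[tuple[ClipCluster, Junction, int]]:
    """Sub-majority clip clusters around a gene, with their linked partners.

    Returns (cluster, junction, offset) triples for clusters inside
    gene +- flank whose clip fraction is >= min_fraction; ``offset`` is the
    distance from the cluster to the nearest gene boundary (0 inside the
    gene).
    """
    if not (0 < min_fraction < 1):
        raise ValueError("min_fraction must be in (0, 1)")
    region = GenomicInterval(
        gene.scaffold, max(0, gene.start - flank), gene.end + flank
    )
    clusters = collect_clip_clusters(
        alignments, min_clip=min_clip, cluster_tol=cluster_tol, region=region
    )
    out = []
    for cl in clusters:
        if not cl.n_crossing or cl.clip_fraction < min_fraction:
            continue
        j = link_junction(cl, reference, min_seed=min_seed, min_identity=min_identity)
        if j.classification == "unresolved":
            continue
        if cl.position < gene.start:
            offset = gene.start - cl.position
        elif cl.position >= gene.end:
            offset = cl.position - gene.end + 1
        else:
            offset = 0
        out.append((cl, j, offset))
    return out
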