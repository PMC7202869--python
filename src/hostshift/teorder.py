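"""Partial ordering of mutational events from per-copy element presence/absence.

Long reads attest which transposable elements co-occur with each observed
copy of an amplified gene, at its native locus or at a translocated one.
Five local rules turn these observations into precedence constraints over
{duplication, translocation, element insertions}:

R1  element present in every observed copy            -> element < dup
R2  element in a proper nonempty subset of natives    -> dup < element
R3  element in the translocated copy and in some but
    not all native copies                             -> element < transloc
R4  element only in the translocated copy             -> transloc < element
R5  a translocated copy exists at all                 -> dup < transloc

The rules are deliberately sound rather than complete: an ambiguous
configuration (e.g. an element in all native copies but absent from the
translocated one) yields no edge rather than a guess.  Rules never relate
two elements directly; any element-element order in the displayed
linearization is tie-breaking only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

DUP = "dup"
TRANSLOC = "transloc"


@dataclass(frozen=True)
class CopyObservation:
    copy_id: str
    locus_class: str                 # "native" | "translocated"
    elements: frozenset[str]

    def __post_init__(self) -> None:
        if self.locus_class not in ("native", "translocated"):
            raise ValueError(
                f"locus_class must be native/translocated, got {self.locus_class!r}"
            )


@dataclass(frozen=True)
class PrecedenceEdge:
    before: str
    after: str
    rule: str


@dataclass(frozen=True)
class EventDAG:
    events: frozenset[str]
    edges: tuple[PrecedenceEdge, ...]    # transitively reduced
    linearization: tuple[str, ...]       # deterministic (lexicographic ties)


@dataclass(frozen=True)
class ContradictionReport:
    cycle: tuple[PrecedenceEdge, ...]


def _as_observations(
    observations: Iterable[CopyObservation | tuple],
) -> list[CopyObservation]:
    out = []
    for obs in observations:
        if isinstance(obs, CopyObservation):
            out.append(obs)
        else:
            cid, cls, elems = obs
            out.append(CopyObservation(cid, cls, frozenset(elems)))
    return out


def derive_constraints(
    observations: Iterable[CopyObservation | tuple],
) -> set[PrecedenceEdge]:
    """Apply rules R1-R5 to a set of per-copy observations.

    Observation order and copy ids are irrelevant; duplicate observations
    collapse (copies are read-level attestations, not phased genomic
    copies).
    """
    obs = _as_observations(observations)
    natives = {o.elements for o in obs if o.locus_class == "native"}
    translocated = {o.elements for o in obs if o.locus_class == "translocated"}
    if sum(1 for o in obs if o.locus_class == "native") < 2:
        raise ValueError("at least two native copy observations are required")
    elements = set().union(*(o.elements for o in obs)) if obs else set()
    edges: set[PrecedenceEdge] = set()
    all_sets = natives | translocated
    trans_union = set().union(*translocated) if translocated else set()
    for el in sorted(elements):
        in_all = all(el in s for s in all_sets)
        in_native = [el in s for s in natives]
        in_trans = el in trans_union
        if in_all:
            edges.add(PrecedenceEdge(el, DUP, "R1"))
            continue
        if any(in_native) and not all(in_native):
            edges.add(PrecedenceEdge(DUP, el, "R2"))
            if in_trans:
                edges.add(PrecedenceEdge(el, TRANSLOC, "R3"))
        elif in_trans and not any(in_native):
            edges.add(PrecedenceEdge(TRANSLOC, el, "R4"))
        # element in all natives but not in the translocated copy, or in no
        # copy at all: ambiguous, no edge (soundness over completeness)
    if translocated:
        edges.add(PrecedenceEdge(DUP, TRANSLOC, "R5"))
    return edges


def build_event_dag(
    edges: Iterable[PrecedenceEdge],
    extra_events: Sequence[str] = (),
) -> EventDAG | ContradictionReport:
    """Transitively reduce the constraint set and attach a linearization.

    A cyclic constraint set returns a ContradictionReport carrying a cycle
    with the justification codes of its edges instead of raising.
    """
    edges = list(edges)
    g = nx.DiGraph()
    for ev in extra_events:
        g.add_node(ev)
    code: dict[tuple[str, str], str] = {}
    for e in edges:
        g.add_edge(e.before, e.after)
        code[(e.before, e.after)] = e.rule
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        return ContradictionReport(
            cycle=tuple(
                PrecedenceEdge(u, v, code.get((u, v), "?")) for u, v, *_ in cyc
            )
        )
    reduced = nx.transitive_reduction(g)
    reduced.add_nodes_from(g.nodes)
    kept = tuple(
        sorted(
            (PrecedenceEdge(u, v, code.get((u, v), "implied")) for u, v in reduced.edges),
            key=lambda e: (e.before, e.after),
        )
    )
    linear = tuple(nx.lexicographical_topological_sort(reduced))
    return EventDAG(
        events=frozenset(g.nodes), edges=kept, linearization=linear
    )


def all_linear_extensions(
    events: Iterable[str], edges: Iterable[PrecedenceEdge]
) -> list[tuple[str, ...]]:
    """Every total order consistent with the constraints (brute force).

    Exhaustive-enumeration oracle for small event sets; used to verify
    statements of the form "X precedes Y in every admissible history".
    """
    import itertools

    events = sorted(set(events))
    pairs = {(e.before, e.after) for e in edges}
    out = []
    for perm in itertools.permutations(events):
        index = {ev: i for i, ev in enumerate(perm)}
        if all(index[a] < index[b] for a, b in pairs):
            out.append(perm)
    return out


def to_dot(dag: EventDAG) -> str:
    lines = ["digraph events {"]
    for ev in sorted(dag.events):
        lines.append(f'  "{ev}";')
    for e in dag.edges:
        lines.append(f'  "{e.before}" -> "{e.after}" [label="{e.rule}"];')
    lines.append("}")
    return "\n".join(lines)


def observations_from_table(rows: Iterable[dict]) -> list[CopyObservation]:
    """Build observations from TSV rows: copy_id, locus_class, elements
    (comma-separated, possibly empty)."""
    out = []
    for row in rows:
        elems = str(row.get("elements", "") or "")
        elements = frozenset(e.strip() for e in elems.split(",") if e.strip())
        out.append(
            CopyObservation(str(row["copy_id"]), str(row["locus_class"]), elements)
        )
    return out
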