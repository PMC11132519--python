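"""Tower of Hanoi state space.

A configuration of an ``n``-disk puzzle is written as a string of ``n``
digits, one per disk from smallest (leftmost) to largest (rightmost); the
digit is the peg (0, 1, or 2) holding that disk.  Because the stacking order
on a peg is forced by disk size, *every* such digit string is a legal
configuration, so the state space has exactly ``3**n`` states.  Moving one
top disk at a time induces a graph in which every state has two or three
neighbours and which decomposes recursively into three triangles — the
familiar Sierpinski-like structure.

Triangle names follow the largest disk's peg:

* ``T1`` — largest disk on peg 0 (contains the canonical start ``0...0``),
* ``T2`` — largest disk on peg 2 (lower-left triangle),
* ``T3`` — largest disk on peg 1 (lower-right triangle).

This convention is the single source of truth for all labelling in the
package; it is fixed by the inter-triangle bridge edges ``1110 -- 1112``
(into T2) and ``2220 -- 2221`` (into T3) of the 4-disk puzzle.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, product

import networkx as nx

PEGS = "012"
TRIANGLES = ("T1", "T2", "T3")

#: largest-disk peg -> triangle name (see module docstring)
PEG_TO_TRIANGLE = {"0": "T1", "2": "T2", "1": "T3"}
TRIANGLE_TO_PEG = {t: p for p, t in PEG_TO_TRIANGLE.items()}

#: the same peg -> corner convention, as a 1-based sub-triangle index
PEG_TO_INDEX = {"0": 1, "2": 2, "1": 3}
INDEX_TO_PEG = {i: p for p, i in PEG_TO_INDEX.items()}

#: peg whose perfect state sits at a triangle's corner nearest the start
#: (for T2 the entry corner is 1...12, i.e. the small disks sit on peg 1)
TRIANGLE_TOP_PEG = {"T1": "0", "T2": "1", "T3": "2"}


class MalformedStateError(ValueError):
    """Raised when a state string is not a valid disk configuration."""


def validate_state(state: str) -> str:
    """Return ``state`` unchanged if it is a well-formed configuration."""
    if not isinstance(state, str) or len(state) < 1:
        raise MalformedStateError(f"state must be a non-empty digit string, got {state!r}")
    if any(c not in PEGS for c in state):
        raise MalformedStateError(f"state digits must be in {{0,1,2}}, got {state!r}")
    return state


def legal_moves(state: str) -> set[str]:
    """All configurations reachable from ``state`` by one legal disk move.

    The top disk of a peg is the smallest disk on it; it may move onto an
    empty peg or onto a peg whose top disk is larger.  Every state has
    exactly two (one peg empty or all disks on one peg) or three such moves.
    """
    state = validate_state(state)
    # first occurrence of a peg digit = smallest disk on that peg = its top
    tops = {p: state.find(p) for p in PEGS}
    moves: set[str] = set()
    for p in PEGS:
        i = tops[p]
        if i == -1:
            continue
        for q in PEGS:
            if q == p:
                continue
            j = tops[q]
            if j == -1 or j > i:
                moves.add(state[:i] + q + state[i + 1 :])
    return moves


def triangle_of(state: str) -> str:
    """Triangle label (``T1``/``T2``/``T3``) from the largest disk's peg."""
    return PEG_TO_TRIANGLE[validate_state(state)[-1]]


def subtriangle_of(state: str) -> tuple[str, int]:
    """``(triangle, index)`` with the index taken from the second-largest
    disk's peg, using the same peg -> corner convention recursively.

    Undefined for the 1-disk puzzle, which has no sub-triangles.
    """
    state = validate_state(state)
    if len(state) < 2:
        raise ValueError("sub-triangles require at least two disks")
    return triangle_of(state), PEG_TO_INDEX[state[-2]]


def _third_peg(p: str, q: str) -> str:
    return (set(PEGS) - {p, q}).pop()


@dataclass(frozen=True, eq=False)
class TohGraph:
    """The legal-configuration graph of an ``n``-disk puzzle.

    ``states`` is sorted lexicographically and is the canonical ordering
    used by every array-based computation downstream.
    """

    n_disks: int
    nx_graph: nx.Graph
    states: tuple[str, ...]
    #: triangle pair (frozenset of labels) -> the two endpoints of the single
    #: bridge edge, ordered to match ``sorted(pair)``
    critical_states: dict[frozenset, tuple[str, str]]

    @property
    def start_state(self) -> str:
        """All disks on peg 0 — the standardized initial configuration."""
        return "0" * self.n_disks

    def neighbors(self, state: str) -> list[str]:
        return sorted(self.nx_graph.neighbors(state))

    def triangle_states(self, triangle: str) -> list[str]:
        peg = TRIANGLE_TO_PEG[triangle]
        return [s for s in self.states if s[-1] == peg]

    def subtriangle_states(self, triangle: str, index: int) -> list[str]:
        suffix = INDEX_TO_PEG[index] + TRIANGLE_TO_PEG[triangle]
        return [s for s in self.states if s.endswith(suffix)]

    def critical_pair(self, tri_a: str, tri_b: str) -> tuple[str, str]:
        """Endpoints of the unique edge joining two triangles, ordered so the
        first state lies in ``tri_a``."""
        pair = frozenset((tri_a, tri_b))
        first, second = self.critical_states[pair]
        return (first, second) if triangle_of(first) == tri_a else (second, first)

    def entry_state(self, triangle: str) -> str:
        """The critical state inside ``triangle`` on the bridge from T1."""
        if triangle == "T1":
            raise ValueError("entry state is defined for T2/T3 only")
        return self.critical_pair(triangle, "T1")[0]

    def gate_state(self, triangle: str) -> str:
        """The T1-side endpoint of the bridge into ``triangle`` (the sub-goal
        configuration shown to participants: 1110 or 2220 for 4 disks)."""
        if triangle == "T1":
            raise ValueError("gate state is defined for T2/T3 only")
        return self.critical_pair("T1", triangle)[0]

    def subtriangle_corners(self, triangle: str, index: int) -> list[str]:
        """The three corner states ``xx..x d2 d1`` of a first-level
        sub-triangle (all disks below the top two on a single peg)."""
        suffix = INDEX_TO_PEG[index] + TRIANGLE_TO_PEG[triangle]
        return [x * (self.n_disks - 2) + suffix for x in PEGS]

    def subtriangle_top_vertex(self, triangle: str, index: int) -> str:
        """Corner of a sub-triangle nearest the start side of the figure.

        Within triangle ``T`` the corner pointing towards the top of the
        figure is the one whose smaller disks all sit on the peg of ``T``'s
        entry corner (e.g. peg 1 for T2, whose entry corner is 1...12).
        """
        e = TRIANGLE_TOP_PEG[triangle]
        return e * (self.n_disks - 2) + INDEX_TO_PEG[index] + TRIANGLE_TO_PEG[triangle]

    def is_critical(self, state: str) -> bool:
        return any(state in pair for pair in self.critical_states.values())


@lru_cache(maxsize=8)
def build_graph(n_disks: int) -> TohGraph:
    """Construct the full ``3**n``-state graph with triangle annotations."""
    if not isinstance(n_disks, int) or n_disks < 1:
        raise ValueError(f"n_disks must be a positive integer, got {n_disks!r}")
    states = tuple("".join(p) for p in product(PEGS, repeat=n_disks))
    g = nx.Graph()
    g.add_nodes_from(states)
    for s in states:
        for t in legal_moves(s):
            g.add_edge(s, t)

    critical: dict[frozenset, tuple[str, str]] = {}
    if n_disks >= 2:
        for pa, pb in combinations(PEGS, 2):
            c = _third_peg(pa, pb)
            sa, sb = c * (n_disks - 1) + pa, c * (n_disks - 1) + pb
            pair = frozenset((PEG_TO_TRIANGLE[pa], PEG_TO_TRIANGLE[pb]))
            key = tuple(sorted(pair))
            ordered = (sa, sb) if PEG_TO_TRIANGLE[pa] == key[0] else (sb, sa)
            critical[pair] = ordered
    return TohGraph(n_disks=n_disks, nx_graph=g, states=states, critical_states=critical)


def sparse_vertex_states(n_disks: int) -> list[str]:
    """The eight sub-triangle vertex states used as the sparse feature set.

    For four disks these are 2200, 1100 (corners of the start sub-triangle),
    1110, 2220 (the T1-side bridge corners), 0012, 2212 (non-critical corners
    of T2's entry sub-triangle) and 1121, 0021 (likewise for T3).  The same
    geometric roles define the set for any ``n >= 3``.
    """
    if n_disks < 3:
        raise ValueError("the sparse vertex set requires at least 3 disks")
    m = n_disks - 2
    return [
        "2" * m + "00",
        "1" * m + "00",
        "1" * m + "10",
        "2" * m + "20",
        "0" * m + "12",
        "2" * m + "12",
        "1" * m + "21",
        "0" * m + "21",
    ]


def export_edge_csv(graph: TohGraph, path) -> None:
    """Write the edge list as ``state_a,state_b`` rows."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["state_a", "state_b"])
        for a, b in sorted(tuple(sorted(e)) for e in graph.nx_graph.edges):
            writer.writerow([a, b])


def export_state_annotations(graph: TohGraph, path) -> None:
    """Write per-state triangle/sub-triangle/criticality annotations (JSON)."""
    rows = []
    for s in graph.states:
        rows.append(
            {
                "state": s,
                "triangle": triangle_of(s),
                "subtriangle": list(subtriangle_of(s)) if graph.n_disks >= 2 else None,
                "is_critical": graph.is_critical(s),
            }
        )
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=1)
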