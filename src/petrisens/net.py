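"""Classical place/transition Petri nets and semi-positive invariant computation.

A Petri net is a weighted bipartite directed graph: places model passive
components (molecular species), transitions model active components
(reactions), and a marking assigns tokens to places.  All structural
analysis in this package is driven by the incidence matrix ``A`` (rows =
places, columns = transitions) whose entry ``(i, j)`` is the net token
change of place ``i`` when transition ``j`` fires.

t-invariants are nonnegative integer solutions of ``A @ x == 0``; firing
every transition ``x_j`` times restores the marking, so a t-invariant is
read as a steady-state subprocess.  p-invariants are the corresponding
left-nullspace vectors ``y @ A == 0`` and describe token conservation.
The engine computes the *minimal* semi-positive invariants (support-minimal,
gcd-normalized) with exact integer arithmetic via Farkas-style column
elimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gcd
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NetStructureError",
    "PetriNet",
    "IncidenceMatrix",
    "Invariant",
    "InvariantSet",
    "build_incidence_matrix",
    "minimal_t_invariants",
    "minimal_p_invariants",
    "support",
    "is_covered",
]


class NetStructureError(ValueError):
    """Raised when a net violates bipartiteness, uniqueness or references."""


class PetriNet:
    """A classical place/transition net with weighted arcs and a marking.

    Places and transitions are identified by unique string ids and carry an
    optional display name.  Arcs connect one place and one transition with a
    positive integer weight; parallel same-direction arcs are summed into a
    single weighted arc (with a warning, since duplicated input rows usually
    indicate a modelling slip).
    """

    def __init__(self, net_id: str = "net") -> None:
        self.net_id = net_id
        self._places: dict[str, str] = {}       # id -> display name
        self._transitions: dict[str, str] = {}  # id -> display name
        self._arcs: dict[tuple[str, str], int] = {}
        self.initial_marking: dict[str, int] = {}

    # -- construction -----------------------------------------------------

    def add_place(self, pid: str, name: str | None = None, marking: int = 0) -> str:
        if pid in self._transitions:
            raise NetStructureError(f"id {pid!r} already used by a transition")
        if marking < 0:
            raise NetStructureError(f"negative marking for place {pid!r}")
        if pid not in self._places:
            self._places[pid] = name if name is not None else pid
            self.initial_marking[pid] = marking
        elif name is not None:
            self._places[pid] = name
        return pid

    def add_transition(self, tid: str, name: str | None = None) -> str:
        if tid in self._places:
            raise NetStructureError(f"id {tid!r} already used by a place")
        if tid not in self._transitions:
            self._transitions[tid] = name if name is not None else tid
        elif name is not None:
            self._transitions[tid] = name
        return tid

    def add_arc(self, source: str, target: str, weight: int = 1) -> None:
        if weight < 1 or int(weight) != weight:
            raise NetStructureError(
                f"arc {source!r}->{target!r} weight must be a positive integer"
            )
        for endpoint in (source, target):
            if endpoint not in self._places and endpoint not in self._transitions:
                raise NetStructureError(f"arc endpoint {endpoint!r} does not exist")
        src_is_place = source in self._places
        tgt_is_place = target in self._places
        if src_is_place == tgt_is_place:
            kind = "place" if src_is_place else "transition"
            raise NetStructureError(
                f"arc {source!r}->{target!r} connects two {kind}s; nets are bipartite"
            )
        key = (source, target)
        if key in self._arcs:
            warnings.warn(
                f"duplicate arc {source!r}->{target!r}: weights summed",
                stacklevel=2,
            )
            self._arcs[key] += int(weight)
        else:
            self._arcs[key] = int(weight)

    def set_marking(self, pid: str, tokens: int) -> None:
        if pid not in self._places:
            raise NetStructureError(f"unknown place {pid!r}")
        if tokens < 0:
            raise NetStructureError("marking must be nonnegative")
        self.initial_marking[pid] = int(tokens)

    # -- views ------------------------------------------------------------

    @property
    def places(self) -> list[str]:
        return list(self._places)

    @property
    def transitions(self) -> list[str]:
        return list(self._transitions)

    @property
    def arcs(self) -> list[tuple[str, str, int]]:
        return [(s, t, w) for (s, t), w in self._arcs.items()]

    def place_name(self, pid: str) -> str:
        return self._places[pid]

    def transition_name(self, tid: str) -> str:
        return self._transitions[tid]

    def has_place(self, pid: str) -> bool:
        return pid in self._places

    def has_transition(self, tid: str) -> bool:
        return tid in self._transitions

    def arc_weight(self, source: str, target: str) -> int:
        return self._arcs.get((source, target), 0)

    def pre_places(self, tid: str) -> list[str]:
        """Places with an arc into transition ``tid``."""
        return [s for (s, t) in self._arcs if t == tid]

    def post_places(self, tid: str) -> list[str]:
        return [t for (s, t) in self._arcs if s == tid]

    def reorder_places(self, order: Sequence[str]) -> "PetriNet":
        """Return a copy with places listed in ``order`` (same structure)."""
        if sorted(order) != sorted(self._places):
            raise NetStructureError("order must be a permutation of the places")
        out = PetriNet(self.net_id)
        for pid in order:
            out.add_place(pid, self._places[pid], self.initial_marking[pid])
        for tid, name in self._transitions.items():
            out.add_transition(tid, name)
        for (s, t), w in self._arcs.items():
            out.add_arc(s, t, w)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PetriNet):
            return NotImplemented
        return (
            self._places == other._places
            and self._transitions == other._transitions
            and self._arcs == other._arcs
            and self.initial_marking == other.initial_marking
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PetriNet({self.net_id!r}, |P|={len(self._places)}, "
            f"|T|={len(self._transitions)}, |F|={len(self._arcs)})"
        )


@dataclass(frozen=True)
class IncidenceMatrix:
    """Incidence matrix of a net: entry (i, j) = post-weight − pre-weight."""

    entries: np.ndarray  # shape (n_places, n_transitions), dtype int64
    place_order: tuple[str, ...]
    transition_order: tuple[str, ...]

    def __post_init__(self) -> None:
        n, m = self.entries.shape
        if n != len(self.place_order) or m != len(self.transition_order):
            raise NetStructureError("incidence dimensions do not match index maps")


@dataclass(frozen=True)
class Invariant:
    """A minimal semi-positive invariant in canonical (gcd = 1) form."""

    kind: str                      # "t" or "p"
    vector: tuple[int, ...]
    support: frozenset[str]

    def __post_init__(self) -> None:
        if not any(self.vector):
            raise NetStructureError("invariant vector must be nonzero")
        positives = [v for v in self.vector if v > 0]
        if any(v < 0 for v in self.vector):
            raise NetStructureError("invariant vector must be nonnegative")
        g = 0
        for v in positives:
            g = gcd(g, v)
        if g != 1:
            raise NetStructureError("invariant vector must be gcd-normalized")


@dataclass
class InvariantSet:
    """Set of minimal invariants of one kind, lexicographically ordered by support."""

    kind: str
    invariants: list[Invariant]
    node_order: tuple[str, ...]     # transitions for t-kind, places for p-kind
    source_net_id: str = ""

    def __len__(self) -> int:
        return len(self.invariants)

    def __iter__(self):
        return iter(self.invariants)

    def supports(self) -> list[frozenset[str]]:
        return [inv.support for inv in self.invariants]

    def as_vectors(self) -> np.ndarray:
        return np.array([inv.vector for inv in self.invariants], dtype=np.int64)


# ---------------------------------------------------------------------------
# incidence matrix

def build_incidence_matrix(net: PetriNet) -> IncidenceMatrix:
    """Build the n×m incidence matrix of ``net`` (rows places, columns transitions)."""
    places = net.places
    transitions = net.transitions
    p_index = {p: i for i, p in enumerate(places)}
    t_index = {t: j for j, t in enumerate(transitions)}
    A = np.zeros((len(places), len(transitions)), dtype=np.int64)
    for source, target, w in net.arcs:
        if source in p_index:       # place -> transition: consumption
            A[p_index[source], t_index[target]] -= w
        else:                       # transition -> place: production
            A[p_index[target], t_index[source]] += w
    return IncidenceMatrix(A, tuple(places), tuple(transitions))


# ---------------------------------------------------------------------------
# Farkas-style minimal invariant engine (exact integer arithmetic)

def _vec_gcd(values: Iterable[int]) -> int:
    g = 0
    for v in values:
        g = gcd(g, abs(v))
        if g == 1:
            break
    return g


def _prune_minimal(rows: list[list[int]], inv_offset: int) -> list[list[int]]:
    """Drop duplicate rows and rows whose invariant-part support strictly
    contains another row's support."""
    seen: set[tuple[int, ...]] = set()
    unique: list[list[int]] = []
    for r in rows:
        key = tuple(r)
        if key not in seen:
            seen.add(key)
            unique.append(r)
    sups = [frozenset(k for k, v in enumerate(r[inv_offset:]) if v > 0) for r in unique]
    keep = []
    for i, si in enumerate(sups):
        minimal = True
        for j, sj in enumerate(sups):
            if i != j and sj < si:
                minimal = False
                break
        if minimal:
            keep.append(unique[i])
    return keep


def _farkas_minimal(columns: list[list[int]]) -> list[tuple[int, ...]]:
    """Minimal semi-positive solutions of ``M @ x == 0``.

    ``columns[j]`` is the j-th column of ``M``; the
    routine runs place-by-place elimination on the table ``[M^T | I]``:
    rows with opposite signs in the current column are combined with positive
    integer coefficients to cancel it, rows still nonzero in that column are
    discarded, and non-minimal-support rows are pruned after every step.
    Plain Python ints keep the arithmetic exact at arbitrary precision.
    """
    m = len(columns)
    if m == 0:
        return []
    n = len(columns[0])
    rows: list[list[int]] = []
    for j, col in enumerate(columns):
        unit = [0] * m
        unit[j] = 1
        rows.append([int(v) for v in col] + unit)
    remaining = set(range(n))
    while remaining:
        # fewest nonzero entries first: keeps intermediate tables small
        c = min(remaining, key=lambda k: sum(1 for r in rows if r[k] != 0))
        remaining.discard(c)
        zero = [r for r in rows if r[c] == 0]
        pos = [r for r in rows if r[c] > 0]
        neg = [r for r in rows if r[c] < 0]
        new_rows = list(zero)
        for rp in pos:
            for rn in neg:
                a, b = -rn[c], rp[c]
                comb = [a * x + b * y for x, y in zip(rp, rn)]
                g = _vec_gcd(comb)
                if g > 1:
                    comb = [v // g for v in comb]
                new_rows.append(comb)
        rows = _prune_minimal(new_rows, n)
    out: set[tuple[int, ...]] = set()
    for r in rows:
        vec = r[n:]
        g = _vec_gcd(vec)
        if g > 1:
            vec = [v // g for v in vec]
        out.add(tuple(vec))
    return sorted(out, key=lambda v: tuple(k for k, x in enumerate(v) if x > 0))


def _make_set(kind: str, vectors: list[tuple[int, ...]], ids: Sequence[str],
              net_id: str) -> InvariantSet:
    invs = [
        Invariant(kind, vec, frozenset(ids[k] for k, v in enumerate(vec) if v > 0))
        for vec in vectors
    ]
    return InvariantSet(kind, invs, tuple(ids), net_id)


def minimal_t_invariants(net: PetriNet) -> InvariantSet:
    """All minimal semi-positive t-invariants of ``net`` (``A @ x == 0``)."""
    if not net.transitions:
        raise NetStructureError("net has no transitions")
    inc = build_incidence_matrix(net)
    cols = [list(map(int, inc.entries[:, j])) for j in range(inc.entries.shape[1])]
    vectors = _farkas_minimal(cols)
    return _make_set("t", vectors, inc.transition_order, net.net_id)


def minimal_p_invariants(net: PetriNet) -> InvariantSet:
    """All minimal semi-positive p-invariants of ``net`` (``y @ A == 0``)."""
    if not net.places:
        raise NetStructureError("net has no places")
    inc = build_incidence_matrix(net)
    # p-invariants are t-invariants of the transposed matrix
    cols = [list(map(int, inc.entries[i, :])) for i in range(inc.entries.shape[0])]
    vectors = _farkas_minimal(cols)
    return _make_set("p", vectors, inc.place_order, net.net_id)


def support(inv: Invariant) -> frozenset[str]:
    """Support of an invariant: ids with positive entries."""
    return inv.support


def is_covered(net: PetriNet, invs: InvariantSet) -> tuple[bool, list[str]]:
    """Whether every transition (t-kind) or place (p-kind) of ``net`` occurs in
    at least one support; returns the uncovered ids otherwise.

    Coverage by t-invariants is the prerequisite for significance analysis:
    a transition outside every support carries no steady-state subprocess.
    """
    nodes = net.transitions if invs.kind == "t" else net.places
    covered: set[str] = set()
    for inv in invs:
        covered |= inv.support
    uncovered = [x for x in nodes if x not in covered]
    return (not uncovered, uncovered)
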