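"""Structural analyses over a computed t-invariant set.

Three analyses are provided, all reading a minimal t-invariant set as the
catalogue of steady-state subprocesses of a signaling network:

* **significance** — for each transition (elementary process), the fraction
  of invariant supports that contain it, ``S = f * 100 / s`` percent, where
  ``f`` is the number of supports containing the transition and ``s`` the
  total number of t-invariants.  Highly significant transitions participate
  in most subprocesses and are candidate intervention points.
* **knockout** — removing a set of transitions excludes every invariant
  whose support meets the set; the exclusion percentage
  ``E = (tinv_b − tinv_a) * 100 / tinv_b`` quantifies how much of the
  modeled behavior the knockout switches off.
* **significant subsets** — transition sets jointly contained in a large
  fraction of supports (level-wise Apriori-style search), or greedily
  assembled to maximize knockout exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Sequence

import pandas as pd

from .net import InvariantSet, PetriNet, minimal_t_invariants

__all__ = [
    "AnalysisError",
    "SignificanceReport",
    "KnockoutResult",
    "SubsetSearchConfig",
    "SubsetResult",
    "round_half_up",
    "significance_pct",
    "exclusion_pct",
    "transition_significance",
    "knockout",
    "knockout_by_recompute",
    "significant_subset_search",
]


class AnalysisError(ValueError):
    """Raised on invalid analysis inputs (empty invariant set, bad threshold...)."""


def round_half_up(value: float | Decimal, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching conventional report formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def significance_pct(f: int, s: int) -> float:
    """Transition significance S = f*100/s percent, rounded half-up to 2 dp."""
    if s <= 0:
        raise AnalysisError("significance undefined for an empty invariant set")
    if not 0 <= f <= s:
        raise AnalysisError(f"count f={f} outside [0, s={s}]")
    return round_half_up(Decimal(f * 100) / Decimal(s))


def exclusion_pct(before: int, after: int) -> float:
    """Knockout exclusion E = (tinv_b − tinv_a)*100/tinv_b percent."""
    if before <= 0:
        raise AnalysisError("exclusion undefined: no invariants before knockout")
    if not 0 <= after <= before:
        raise AnalysisError(f"invariant count after ({after}) outside [0, {before}]")
    return round_half_up(Decimal((before - after) * 100) / Decimal(before))


@dataclass(frozen=True)
class SignificanceRow:
    transition_id: str
    name: str
    t_inv_count: int
    significance: float


@dataclass
class SignificanceReport:
    """Per-transition invariant counts and percentage significances."""

    rows: list[SignificanceRow]
    total_invariants: int

    def __getitem__(self, tid: str) -> SignificanceRow:
        for row in self.rows:
            if row.transition_id == tid:
                return row
        raise KeyError(tid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.transition_id, r.name, r.t_inv_count, r.significance)
                for r in self.rows
            ],
            columns=["transition_id", "name", "t_inv_count", "significance_pct"],
        )

    def to_csv(self, stream: IO[str] | str) -> None:
        self.to_frame().to_csv(stream, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "total_invariants": self.total_invariants,
                "rows": [r.__dict__ for r in self.rows],
            },
            indent=2,
        )


@dataclass
class KnockoutResult:
    """Outcome of removing a transition set from the invariant catalogue."""

    knocked: frozenset[str]
    tinv_before: int
    tinv_after: int
    exclusion: float
    surviving: InvariantSet

    def to_json(self) -> str:
        return json.dumps(
            {
                "knocked": sorted(self.knocked),
                "tinv_before": self.tinv_before,
                "tinv_after": self.tinv_after,
                "exclusion_pct": self.exclusion,
            },
            indent=2,
        )


@dataclass
class SubsetSearchConfig:
    """Configuration for significant-subset search.

    ``threshold`` is the joint-containment fraction a set must reach to count
    as necessary for the system's functioning (default 0.8: contained in more
    than 80% of all supports).  ``mode`` selects between the containment
    search and greedy union-knockout assembly.
    """

    threshold: float = 0.8
    max_set_size: int = 12
    mode: str = "joint"   # "joint" | "union"

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise AnalysisError(f"threshold {self.threshold} outside (0, 1]")
        if self.max_set_size < 1:
            raise AnalysisError("max_set_size must be >= 1")
        if self.mode not in ("joint", "union"):
            raise AnalysisError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SubsetResult:
    transitions: frozenset[str]
    frequency: float      # joint containment fraction of all supports
    exclusion: float      # knockout E of the set, percent


def transition_significance(invs: InvariantSet, net: PetriNet) -> SignificanceReport:
    """Significance of every transition of ``net`` against the t-invariant set.

    Transitions outside every support get f = 0, S = 0.00; rows are sorted by
    descending significance, ties by transition id.
    """
    if invs.kind != "t":
        raise AnalysisError("significance analysis requires t-invariants")
    s = len(invs)
    if s == 0:
        raise AnalysisError("significance undefined for an empty invariant set")
    supports = invs.supports()
    rows = []
    for tid in net.transitions:
        f = sum(1 for sup in supports if tid in sup)
        rows.append(
            SignificanceRow(tid, net.transition_name(tid), f, significance_pct(f, s))
        )
    rows.sort(key=lambda r: (-r.significance, r.transition_id))
    return SignificanceReport(rows, s)


def knockout(invs: InvariantSet, knocked: Iterable[str]) -> KnockoutResult:
    """Exclude every invariant whose support intersects ``knocked``.

    For minimal t-invariants this filtering coincides with recomputing the
    minimal invariants of the net with the knocked transition columns deleted
    (cross-checked by :func:`knockout_by_recompute`): an invariant avoiding
    the knocked columns solves the reduced system iff it solves the full one,
    and support-minimality is unaffected by deleting unused columns.
    """
    knocked = frozenset(knocked)
    known = set(invs.node_order)
    unknown = sorted(knocked - known)
    if unknown:
        raise AnalysisError(f"unknown transition id(s): {', '.join(unknown)}")
    before = len(invs)
    survivors = [inv for inv in invs if not (inv.support & knocked)]
    surviving = InvariantSet(invs.kind, survivors, invs.node_order, invs.source_net_id)
    return KnockoutResult(
        knocked, before, len(survivors), exclusion_pct(before, len(survivors)), surviving
    )


def knockout_by_recompute(net: PetriNet, knocked: Iterable[str]) -> InvariantSet:
    """Minimal t-invariants of ``net`` with the knocked transitions deleted.

    Reference semantics for :func:`knockout`; O(exponential) where filtering
    is O(|invs|), so it is used as a cross-check, not the default path.
    """
    knocked = frozenset(knocked)
    unknown = sorted(knocked - set(net.transitions))
    if unknown:
        raise AnalysisError(f"unknown transition id(s): {', '.join(unknown)}")
    reduced = PetriNet(net.net_id + "-knockout")
    for pid in net.places:
        reduced.add_place(pid, net.place_name(pid), net.initial_marking[pid])
    for tid in net.transitions:
        if tid not in knocked:
            reduced.add_transition(tid, net.transition_name(tid))
    for s, t, w in net.arcs:
        if s not in knocked and t not in knocked:
            reduced.add_arc(s, t, w)
    if not reduced.transitions:   # everything knocked out
        return InvariantSet("t", [], (), reduced.net_id)
    return minimal_t_invariants(reduced)


def _joint_frequency(supports: Sequence[frozenset[str]], tset: frozenset[str]) -> float:
    return sum(1 for sup in supports if tset <= sup) / len(supports)


def _joint_containment_search(
    supports: Sequence[frozenset[str]], cfg: SubsetSearchConfig
) -> list[frozenset[str]]:
    """Level-wise (Apriori-style) enumeration of all maximal transition sets
    with joint containment frequency >= threshold."""
    n = len(supports)
    items = sorted({t for sup in supports for t in sup})
    freq_items = [
        t for t in items
        if sum(1 for sup in supports if t in sup) / n >= cfg.threshold
    ]
    frequent: list[set[frozenset[str]]] = []
    level = {frozenset([t]) for t in freq_items}
    while level and len(frequent) < cfg.max_set_size:
        level = {c for c in level if _joint_frequency(supports, c) >= cfg.threshold}
        if not level:
            break
        frequent.append(level)
        # candidate (k+1)-sets from frequent k-sets sharing all but one item
        nxt: set[frozenset[str]] = set()
        for a in level:
            for t in freq_items:
                if t not in a:
                    cand = a | {t}
                    # Apriori pruning: all k-subsets must be frequent
                    if all(cand - {x} in level for x in cand):
                        nxt.add(cand)
        level = nxt
    all_frequent = {c for lvl in frequent for c in lvl}
    return [
        c for c in all_frequent
        if not any(c < other for other in all_frequent)
    ]


def _greedy_union_knockout(
    invs: InvariantSet, cfg: SubsetSearchConfig, seed_set: Iterable[str] | None
) -> list[SubsetResult]:
    """Greedy forward selection maximizing knockout exclusion per added
    transition; one result row per set size up to ``max_set_size``."""
    supports = invs.supports()
    chosen: list[str] = []
    if seed_set:
        chosen = sorted(seed_set)
    results: list[SubsetResult] = []
    candidates = sorted(set(invs.node_order))

    def record(current: Sequence[str]) -> None:
        cset = frozenset(current)
        res = knockout(invs, cset)
        results.append(
            SubsetResult(cset, _joint_frequency(supports, cset), res.exclusion)
        )

    if chosen:
        record(chosen)
    while len(chosen) < cfg.max_set_size:
        best = None
        for t in candidates:
            if t in chosen:
                continue
            e = knockout(invs, frozenset(chosen) | {t}).exclusion
            if best is None or e > best[0] or (e == best[0] and t < best[1]):
                best = (e, t)
        if best is None:
            break
        chosen.append(best[1])
        record(chosen)
        if best[0] >= 100.0:
            break
    return results


def significant_subset_search(
    invs: InvariantSet,
    cfg: SubsetSearchConfig | None = None,
    seed_set: Iterable[str] | None = None,
) -> list[SubsetResult]:
    """Search for significant transition subsets.

    mode ``joint``: all maximal sets whose joint containment frequency over
    the supports is at least ``cfg.threshold``, ordered by larger set size,
    then higher frequency, then lexicographic ids.  mode ``union``: greedy
    forward selection maximizing knockout exclusion, optionally starting from
    ``seed_set``, reporting exclusion at each size up to ``max_set_size``.
    """
    cfg = cfg or SubsetSearchConfig()
    if len(invs) == 0:
        raise AnalysisError("subset search requires a nonempty invariant set")
    if cfg.mode == "union":
        return _greedy_union_knockout(invs, cfg, seed_set)
    supports = invs.supports()
    maximal = _joint_containment_search(supports, cfg)
    results = [
        SubsetResult(
            c, _joint_frequency(supports, c), knockout(invs, c).exclusion
        )
        for c in maximal
    ]
    results.sort(
        key=lambda r: (-len(r.transitions), -r.frequency, sorted(r.transitions))
    )
    return results
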