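"""Synthetic nets, oracles and support families for testing the engine.

The generators produce nets whose minimal t-invariant structure is known by
construction (disjoint cycles and source→place→sink chains contribute one
minimal invariant each), plus arbitrary random bipartite nets for
cross-validation, and :func:`brute_force_t_invariants` provides an
independent bounded-enumeration oracle against which the Farkas engine is
checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

from .net import (
    Invariant,
    InvariantSet,
    NetStructureError,
    PetriNet,
    build_incidence_matrix,
)

__all__ = [
    "SyntheticNetSpec",
    "random_invariant_net",
    "random_net",
    "brute_force_t_invariants",
    "support_enumeration_t_invariants",
    "random_support_family",
]


@dataclass
class SyntheticNetSpec:
    """Specification for a net with a known minimal t-invariant count.

    Disjoint cycles and chains give exactly one minimal t-invariant each;
    ``n_shared`` > 0 glues consecutive cycles on a shared transition, in
    which case the expected count must come from the brute-force oracle.
    """

    cycle_lengths: tuple[int, ...] = (3,)
    n_chains: int = 0
    n_shared: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.cycle_lengths):
            raise NetStructureError("cycle lengths must be >= 1")
        if self.n_chains < 0 or self.n_shared < 0:
            raise NetStructureError("counts must be nonnegative")
        if self.n_shared >= max(len(self.cycle_lengths), 1):
            raise NetStructureError("cannot share more transitions than cycle pairs")


def random_invariant_net(spec: SyntheticNetSpec) -> tuple[PetriNet, int | None]:
    """Build a net from cycles and source/sink chains.

    Returns ``(net, expected_minimal_t_invariant_count)``; the count is
    ``n_cycles + n_chains`` for the disjoint construction and ``None`` when
    cycles are glued (use the oracle to establish the expected set).
    """
    net = PetriNet(f"synthetic-{spec.seed}")
    cycle_transitions: list[list[str]] = []
    for c, length in enumerate(spec.cycle_lengths):
        ps = [net.add_place(f"p_c{c}_{k}") for k in range(length)]
        ts = [net.add_transition(f"t_c{c}_{k}") for k in range(length)]
        for k in range(length):
            net.add_arc(ps[k], ts[k])
            net.add_arc(ts[k], ps[(k + 1) % length])
        cycle_transitions.append(ts)
    for c in range(spec.n_chains):
        p = net.add_place(f"p_h{c}")
        t_in = net.add_transition(f"t_h{c}_in")
        t_out = net.add_transition(f"t_h{c}_out")
        net.add_arc(t_in, p)
        net.add_arc(p, t_out)
    # glue: cycle c+1 additionally routes through a transition of cycle c
    for c in range(spec.n_shared):
        shared = cycle_transitions[c][0]
        bridge = net.add_place(f"p_g{c}")
        net.add_arc(cycle_transitions[c + 1][0], bridge)
        net.add_arc(bridge, shared)
        net.add_arc(shared, f"p_c{c + 1}_0")
    if spec.n_shared == 0:
        return net, len(spec.cycle_lengths) + spec.n_chains
    return net, None


def random_net(
    rng: np.random.Generator | int,
    max_places: int = 8,
    max_transitions: int = 8,
    arc_prob: float = 0.3,
    max_weight: int = 2,
) -> PetriNet:
    """A random bipartite net: each (place, transition) pair gets an arc in
    either direction independently with ``arc_prob``, weights in
    [1, max_weight].  Used for engine/oracle cross-validation."""
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = int(rng.integers(1, max_places + 1))
    m = int(rng.integers(1, max_transitions + 1))
    net = PetriNet("random")
    for i in range(n):
        net.add_place(f"p{i}")
    for j in range(m):
        net.add_transition(f"t{j}")
    for i in range(n):
        for j in range(m):
            if rng.random() < arc_prob:
                net.add_arc(f"p{i}", f"t{j}", int(rng.integers(1, max_weight + 1)))
            if rng.random() < arc_prob:
                net.add_arc(f"t{j}", f"p{i}", int(rng.integers(1, max_weight + 1)))
    return net


def brute_force_t_invariants(net: PetriNet, bound: int = 3) -> InvariantSet:
    """Exhaustive oracle: all minimal t-invariants with entries ≤ ``bound``.

    Enumerates every nonnegative vector with entries up to ``bound``, keeps
    exact solutions of ``A @ x == 0``, gcd-normalizes and reduces to the
    support-minimal set.  Guarded to ``m · (bound+1)^m ≤ 10^7`` work units.
    Independent of the Farkas engine by construction.
    """
    inc = build_incidence_matrix(net)
    n, m = inc.entries.shape
    if m * (bound + 1) ** m > 10**7:
        raise NetStructureError(
            f"oracle guard exceeded: {m} transitions with bound {bound}"
        )
    grids = np.meshgrid(*([np.arange(bound + 1)] * m), indexing="ij")
    X = np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)
    X = X[X.any(axis=1)]
    sols = X[(inc.entries @ X.T == 0).all(axis=0)]
    canon: set[tuple[int, ...]] = set()
    for row in sols:
        g = 0
        for v in row:
            g = gcd(g, int(v))
        canon.add(tuple(int(v) // g for v in row))
    sups = {vec: frozenset(k for k, v in enumerate(vec) if v > 0) for vec in canon}
    minimal = [
        vec for vec, sup in sups.items()
        if not any(other < sup for o, other in sups.items() if o != vec)
    ]
    minimal.sort(key=lambda v: tuple(k for k, x in enumerate(v) if x > 0))
    order = inc.transition_order
    invs = [
        Invariant("t", vec, frozenset(order[k] for k, v in enumerate(vec) if v > 0))
        for vec in minimal
    ]
    return InvariantSet("t", invs, order, net.net_id)


def support_enumeration_t_invariants(net: PetriNet) -> InvariantSet:
    """Second independent oracle: exhaustive search over transition supports.

    Candidate supports are enumerated by increasing size with superset
    pruning.  A support ``S`` carries a minimal t-invariant iff no accepted
    smaller support is contained in it and the incidence matrix restricted
    to the columns of ``S`` has a one-dimensional exact nullspace spanned by
    a strictly positive vector (a standard characterization of minimal
    semiflows: the solution cone's extreme rays have minimal supports and
    one-dimensional restricted nullspaces).  Rational arithmetic throughout,
    so unlike :func:`brute_force_t_invariants` there is no entry bound; work
    is O(2^m) nullspace computations, so only viable for small nets.
    """
    import itertools

    import sympy as sp

    inc = build_incidence_matrix(net)
    A = sp.Matrix(inc.entries.tolist())
    m = A.cols
    if m > 14:
        raise NetStructureError("support-enumeration oracle limited to <= 14 transitions")
    found: list[tuple[frozenset[int], tuple[int, ...]]] = []
    for size in range(1, m + 1):
        for S in itertools.combinations(range(m), size):
            s_set = frozenset(S)
            if any(sup <= s_set for sup, _ in found):
                continue
            ns = A[:, list(S)].nullspace()
            if len(ns) != 1:
                continue
            v = ns[0]
            if all(x > 0 for x in v):
                pass
            elif all(x < 0 for x in v):
                v = -v
            else:
                continue
            scale = sp.ilcm(*[sp.Rational(x).q for x in v]) if size > 1 else sp.Rational(v[0]).q
            ints = [sp.Integer(x * scale) for x in v]
            g = sp.igcd(*ints) if size > 1 else ints[0]
            vec = [0] * m
            for j, x in zip(S, ints):
                vec[j] = int(x // g)
            found.append((s_set, tuple(vec)))
    order = inc.transition_order
    vectors = sorted(
        (vec for _, vec in found),
        key=lambda v: tuple(k for k, x in enumerate(v) if x > 0),
    )
    invs = [
        Invariant("t", vec, frozenset(order[k] for k, v in enumerate(vec) if v > 0))
        for vec in vectors
    ]
    return InvariantSet("t", invs, order, net.net_id)


def random_support_family(
    n_invariants: int,
    n_transitions: int,
    planted: frozenset[str] | set[str],
    planted_frequency: float,
    seed: int = 0,
) -> list[frozenset[str]]:
    """Support family with a planted jointly-frequent transition set.

    Exactly ``round(planted_frequency * n_invariants)`` supports contain the
    whole planted set; the rest omit at least one planted member.  Remaining
    membership is independent random noise.  Used to validate the subset
    search: the planted set must be recovered iff its frequency clears the
    threshold.
    """
    if n_invariants < 1:
        raise NetStructureError("support family must be nonempty")
    planted = frozenset(planted)
    universe = [f"t{k}" for k in range(n_transitions)]
    if not planted <= set(universe):
        raise NetStructureError("planted set must lie within t0..t{n-1}")
    rng = np.random.default_rng(seed)
    n_with = round(planted_frequency * n_invariants)
    family: list[frozenset[str]] = []
    others = [t for t in universe if t not in planted]
    for i in range(n_invariants):
        noise = {t for t in others if rng.random() < 0.4}
        if i < n_with:
            family.append(frozenset(planted | noise))
        else:
            # drop at least one planted member so the joint set is absent
            dropped = rng.choice(sorted(planted)) if planted else None
            kept = set(planted) - ({dropped} if dropped else set())
            # also drop each remaining member with probability 1/2
            kept = {t for t in kept if rng.random() < 0.5}
            support = frozenset(kept | noise)
            if not support:
                support = frozenset({others[0] if others else sorted(planted)[0]})
            family.append(support)
    # order carries no signal
    return [family[i] for i in rng.permutation(n_invariants)]
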