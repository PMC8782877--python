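"""Builders for the recurring motifs of manual ODE-to-Petri-net translation.

Each additive rate term of an ODE pathway model maps onto a small classical
Petri-net fragment.  Because classical nets have only one arc type (no read
or inhibitor arcs), three adaptations are needed:

* enzymes/catalysts are consumed by the reactions they enable and returned
  to circulation by dedicated *pool* source transitions;
* inhibition is modeled as an extra *drain* transition that competes for the
  inhibited reaction's pre-place tokens (weakening the reaction; complete
  inhibition is the job of knockout analysis, not of the net structure);
* degradation is an explicit *output* transition with no post-places, which
  is also what makes the net coverable by t-invariants.

:func:`build_p53_fragment` assembles the nuclear-p53 activation fragment —
spontaneous, ATM-dependent and Chk2-dependent activation of p53, Wip1-
dependent inactivation, spontaneous and Mdm2-mediated degradation, plus p53
synthesis and the catalyst pools — the net counterpart of the reduced ODE
model in :mod:`petrisens.ode`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .net import NetStructureError, PetriNet

__all__ = [
    "MotifKind",
    "MotifSpec",
    "add_spontaneous_conversion",
    "add_catalyzed_conversion",
    "add_inactivation",
    "add_degradation",
    "add_synthesis_source",
    "add_pool_source",
    "add_inhibition_drain",
    "apply_motif",
    "build_p53_fragment",
]


class MotifKind(str, Enum):
    SPONTANEOUS_CONVERSION = "spontaneous_conversion"
    CATALYZED_CONVERSION = "catalyzed_conversion"
    INACTIVATION = "inactivation"
    DEGRADATION = "degradation"
    MEDIATED_DEGRADATION = "mediated_degradation"
    SYNTHESIS_SOURCE = "synthesis_source"
    INHIBITION_DRAIN = "inhibition_drain"
    POOL_SOURCE = "pool_source"


_REQUIRED_ROLES = {
    MotifKind.SPONTANEOUS_CONVERSION: {"substrate", "product"},
    MotifKind.CATALYZED_CONVERSION: {"substrate", "catalyst", "product"},
    MotifKind.INACTIVATION: {"active", "agent", "inactive"},
    MotifKind.DEGRADATION: {"target"},
    MotifKind.MEDIATED_DEGRADATION: {"target", "mediator"},
    MotifKind.SYNTHESIS_SOURCE: {"product"},
    MotifKind.INHIBITION_DRAIN: {"inhibited_transition", "inhibitor"},
    MotifKind.POOL_SOURCE: {"product"},
}


@dataclass(frozen=True)
class MotifSpec:
    """Declarative motif description: kind, role→id map, transition id/name."""

    kind: MotifKind
    participants: dict[str, str]
    transition_id: str
    name: str = ""

    def __post_init__(self) -> None:
        missing = _REQUIRED_ROLES[self.kind] - set(self.participants)
        if missing:
            raise NetStructureError(
                f"motif {self.kind.value} missing role(s): {', '.join(sorted(missing))}"
            )


def _ensure_place(net: PetriNet, pid: str) -> None:
    if not net.has_place(pid):
        net.add_place(pid)


def _new_transition(net: PetriNet, tid: str, name: str) -> str:
    if net.has_transition(tid):
        raise NetStructureError(f"transition id {tid!r} already exists")
    return net.add_transition(tid, name or tid)


def add_spontaneous_conversion(
    net: PetriNet, substrate: str, product: str, name: str, tid: str | None = None
) -> PetriNet:
    """substrate → t → product; no co-factor needed (spontaneous reaction)."""
    _ensure_place(net, substrate)
    _ensure_place(net, product)
    t = _new_transition(net, tid or f"t_{name}".replace(" ", "_"), name)
    net.add_arc(substrate, t)
    net.add_arc(t, product)
    return net


def add_catalyzed_conversion(
    net: PetriNet,
    substrate: str,
    catalyst: str,
    product: str,
    name: str,
    tid: str | None = None,
    with_pool: bool = False,
) -> PetriNet:
    """{substrate, catalyst} → t → product.

    Both pre-places must carry tokens for the transition to fire.  The
    catalyst token is consumed; pass ``with_pool=True`` to add a pool source
    transition replenishing it (the return-to-circulation pattern).
    """
    for pid in (substrate, catalyst, product):
        _ensure_place(net, pid)
    t = _new_transition(net, tid or f"t_{name}".replace(" ", "_"), name)
    net.add_arc(substrate, t)
    net.add_arc(catalyst, t)
    net.add_arc(t, product)
    if with_pool:
        add_pool_source(net, catalyst, f"pool of {catalyst}")
    return net


def add_inactivation(
    net: PetriNet,
    active: str,
    agent: str,
    inactive: str,
    name: str,
    tid: str | None = None,
    with_pool: bool = False,
) -> PetriNet:
    """{active, agent} → t → inactive: a catalyzed conversion with the arc
    direction mirrored relative to activation (active form is the substrate)."""
    return add_catalyzed_conversion(
        net, active, agent, inactive, name, tid=tid, with_pool=with_pool
    )


def add_degradation(
    net: PetriNet,
    target: str,
    name: str,
    mediator: str | None = None,
    tid: str | None = None,
    with_pool: bool = False,
) -> PetriNet:
    """Output transition consuming ``target`` (and ``mediator``, if any);
    no post-places, so tokens leave the system here."""
    _ensure_place(net, target)
    t = _new_transition(net, tid or f"t_{name}".replace(" ", "_"), name)
    net.add_arc(target, t)
    if mediator is not None:
        _ensure_place(net, mediator)
        net.add_arc(mediator, t)
        if with_pool:
            add_pool_source(net, mediator, f"pool of {mediator}")
    return net


def add_synthesis_source(
    net: PetriNet, product: str, name: str, tid: str | None = None
) -> PetriNet:
    """Input transition with no pre-places producing ``product``."""
    _ensure_place(net, product)
    t = _new_transition(net, tid or f"t_{name}".replace(" ", "_"), name)
    net.add_arc(t, product)
    return net


def add_pool_source(
    net: PetriNet, product: str, name: str, tid: str | None = None
) -> PetriNet:
    """Pool source: identical structure to a synthesis source, but names the
    intent of returning a consumed catalyst to circulation."""
    return add_synthesis_source(
        net, product, name, tid=tid or f"t_pool_{product}"
    )


def add_inhibition_drain(
    net: PetriNet,
    inhibited_transition: str,
    inhibitor: str,
    name: str,
    tid: str | None = None,
) -> PetriNet:
    """Drain transition weakening ``inhibited_transition``: its pre-places are
    the inhibitor plus the inhibited transition's pre-places, and it consumes
    their tokens without producing anything.  This only weakens the reaction —
    complete inhibition is expressed through knockout analysis instead."""
    if not net.has_transition(inhibited_transition):
        raise NetStructureError(f"unknown transition {inhibited_transition!r}")
    _ensure_place(net, inhibitor)
    t = _new_transition(net, tid or f"t_{name}".replace(" ", "_"), name)
    net.add_arc(inhibitor, t)
    for pre in net.pre_places(inhibited_transition):
        net.add_arc(pre, t)
    return net


def apply_motif(net: PetriNet, spec: MotifSpec) -> PetriNet:
    """Apply a declarative :class:`MotifSpec` to ``net``."""
    p = spec.participants
    k = spec.kind
    if k is MotifKind.SPONTANEOUS_CONVERSION:
        return add_spontaneous_conversion(
            net, p["substrate"], p["product"], spec.name, spec.transition_id
        )
    if k is MotifKind.CATALYZED_CONVERSION:
        return add_catalyzed_conversion(
            net, p["substrate"], p["catalyst"], p["product"], spec.name,
            spec.transition_id, with_pool=p.get("with_pool", "") == "yes",
        )
    if k is MotifKind.INACTIVATION:
        return add_inactivation(
            net, p["active"], p["agent"], p["inactive"], spec.name,
            spec.transition_id, with_pool=p.get("with_pool", "") == "yes",
        )
    if k is MotifKind.DEGRADATION:
        return add_degradation(net, p["target"], spec.name, tid=spec.transition_id)
    if k is MotifKind.MEDIATED_DEGRADATION:
        return add_degradation(
            net, p["target"], spec.name, mediator=p["mediator"],
            tid=spec.transition_id,
        )
    if k is MotifKind.SYNTHESIS_SOURCE:
        return add_synthesis_source(net, p["product"], spec.name, spec.transition_id)
    if k is MotifKind.POOL_SOURCE:
        return add_pool_source(net, p["product"], spec.name, spec.transition_id)
    if k is MotifKind.INHIBITION_DRAIN:
        return add_inhibition_drain(
            net, p["inhibited_transition"], p["inhibitor"], spec.name,
            spec.transition_id,
        )
    raise NetStructureError(f"unknown motif kind {k!r}")  # pragma: no cover


def build_p53_fragment() -> PetriNet:
    """The nuclear-p53 activation fragment as a classical Petri net.

    Places: p53n (inactive nuclear p53), p53pn (phosphorylated nuclear p53),
    ATM (active ATM kinase), CHK2pn (phosphorylated Chk2), WIP1n (nuclear
    Wip1 phosphatase), MDM2pn (nuclear phosphorylated Mdm2).  Transitions:
    p53 synthesis, the six rate-term counterparts (spontaneous / ATM- /
    Chk2-dependent activation, Wip1-dependent inactivation, spontaneous and
    Mdm2-mediated degradation) and one pool source per consumed catalyst.

    Mdm2pn is consumed by the mediated degradation and replenished from a
    pool, mirroring the catalyst treatment.  Marking: 1 token on each
    source-fed place (markings do not affect invariant analysis, which is
    purely structural; they are set for reproducibility only).
    """
    net = PetriNet("p53-fragment")
    for pid, name in [
        ("p53n", "nuclear p53 (inactive)"),
        ("p53pn", "nuclear phosphorylated p53"),
        ("ATM", "active ATM"),
        ("CHK2pn", "phosphorylated Chk2"),
        ("WIP1n", "nuclear Wip1"),
        ("MDM2pn", "nuclear phosphorylated Mdm2"),
    ]:
        net.add_place(pid, name)
    add_synthesis_source(net, "p53n", "production of p53n", tid="t_syn_p53")
    add_spontaneous_conversion(
        net, "p53n", "p53pn", "spontaneous phosphorylation of p53n",
        tid="t_act_spont",
    )
    add_catalyzed_conversion(
        net, "p53n", "ATM", "p53pn", "phosphorylation of p53n by ATM",
        tid="t_act_atm", with_pool=True,
    )
    add_catalyzed_conversion(
        net, "p53n", "CHK2pn", "p53pn", "phosphorylation of p53n by Chk2pn",
        tid="t_act_chk2", with_pool=True,
    )
    add_inactivation(
        net, "p53pn", "WIP1n", "p53n", "dephosphorylation of p53pn by Wip1n",
        tid="t_inact_wip1", with_pool=True,
    )
    add_degradation(net, "p53pn", "degradation of p53pn", tid="t_deg_spont")
    add_degradation(
        net, "p53pn", "degradation of p53pn by Mdm2pn", mediator="MDM2pn",
        tid="t_deg_mdm2", with_pool=True,
    )
    for pid in ("p53n", "ATM", "CHK2pn", "WIP1n", "MDM2pn"):
        net.set_marking(pid, 1)
    return net
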