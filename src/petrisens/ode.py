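"""ODE pathway models as named additive rate terms, plus the three-phase
TNF/IR stimulation protocol.

A model is a list of signed rate terms, each attached to one target species
and one named biochemical process; the right-hand side of a species is the
signed sum of its terms.  Terms are plain expression strings over declared
species, parameters and input signals, parsed with sympy and compiled once
per model.

:func:`reduced_fixture_model` builds a closed six-species reduction of the
nuclear p53 activation module: the balance for phosphorylated nuclear p53
(spontaneous activation, saturating ATM- and Chk2-dependent activation,
Wip1-dependent inactivation, spontaneous and Mdm2-dependent degradation),
its unphosphorylated precursor, and first-order production/decay drivers
for the regulators (radiation-gated for ATM and Chk2).  Its parameter
values are package defaults chosen to give a plausible damped stress
response; they are not fitted to data.

The simulation protocol has three consecutive phases: an equilibration
phase with no stimulus (default 24 h), a stimulation phase in which TNF is
switched on and ionizing radiation is delivered (default 1 h at 10 ng/ml
TNF and a total dose of 4 or 10 Gy, applied as a rectangular dose-rate
pulse), and a long recovery phase with TNF still present but no radiation
(default 240 h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Callable, Mapping, Sequence

import numpy as np
import sympy as sp
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ModelError",
    "IntegrationError",
    "RateTerm",
    "ODEModel",
    "SimulationProtocol",
    "Trajectory",
    "evaluate_rhs",
    "simulate_protocol",
    "reduced_fixture_model",
    "settling_time",
    "load_model",
    "NOT_SETTLED",
]

NOT_SETTLED = float("nan")


class ModelError(ValueError):
    """Raised on ill-formed models or states."""


class IntegrationError(RuntimeError):
    """Raised when the solver fails; carries the last valid time reached."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class RateTerm:
    """One signed additive rate term of one species' balance equation."""

    target: str
    sign: int            # +1 production, -1 consumption
    rate: str            # expression over species, parameters and inputs
    name: str = ""

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ModelError(f"term {self.name!r}: sign must be +1 or -1")


class ODEModel:
    """Species, parameters, named rate terms and input signals."""

    def __init__(
        self,
        species: Sequence[str],
        parameters: Mapping[str, float],
        terms: Sequence[RateTerm],
        inputs: Sequence[str] = ("TNF", "IR"),
        name: str = "model",
        initial_state: Sequence[float] | None = None,
    ) -> None:
        self.name = name
        self.species = list(species)
        self.parameters = dict(parameters)
        self.terms = list(terms)
        self.inputs = list(inputs)
        if initial_state is None:
            self.initial_state = np.zeros(len(self.species))
        else:
            self.initial_state = np.asarray(initial_state, dtype=float)
            if self.initial_state.shape != (len(self.species),):
                raise ModelError("initial_state length does not match species")
        self._validate()
        self._compiled: Callable | None = None

    def _validate(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ModelError("duplicate species names")
        declared = set(self.species) | set(self.parameters) | set(self.inputs)
        used_params: set[str] = set()
        for term in self.terms:
            if term.target not in self.species:
                raise ModelError(f"term {term.name!r}: unknown target {term.target!r}")
            symbols = {str(s) for s in sp.sympify(term.rate).free_symbols}
            unknown = symbols - declared
            if unknown:
                raise ModelError(
                    f"term {term.name!r}: undeclared symbol(s) "
                    f"{', '.join(sorted(unknown))}"
                )
            used_params |= symbols & set(self.parameters)
        unused = set(self.parameters) - used_params
        if unused:
            # kept representable (not an error) so that a structurally inert
            # parameter can be shown to have sensitivity index exactly zero
            warnings.warn(
                f"parameter(s) never used in any term: {', '.join(sorted(unused))}",
                stacklevel=3,
            )

    # -- symbolic views ---------------------------------------------------

    def rhs_expressions(self) -> dict[str, sp.Expr]:
        """Signed sum of terms per species, as sympy expressions."""
        out = {s: sp.Integer(0) for s in self.species}
        for term in self.terms:
            out[term.target] = out[term.target] + term.sign * sp.sympify(term.rate)
        return out

    def parameters_of_species(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.species}
        for term in self.terms:
            symbols = {str(x) for x in sp.sympify(term.rate).free_symbols}
            out[term.target] |= symbols & set(self.parameters)
        return out

    def depends_on(self, param: str) -> bool:
        """Whether ``param`` occurs in any rate term (structural, not numeric)."""
        for term in self.terms:
            if param in {str(x) for x in sp.sympify(term.rate).free_symbols}:
                return True
        return False

    def _compile(self) -> Callable:
        if self._compiled is None:
            exprs = self.rhs_expressions()
            args = (
                [sp.Symbol(s) for s in self.species]
                + [sp.Symbol(s) for s in self.inputs]
                + [sp.Symbol(p) for p in sorted(self.parameters)]
            )
            self._compiled = sp.lambdify(
                args, [exprs[s] for s in self.species], modules="numpy"
            )
        return self._compiled

    def with_parameters(self, overrides: Mapping[str, float]) -> "ODEModel":
        unknown = set(overrides) - set(self.parameters)
        if unknown:
            raise ModelError(f"unknown parameter(s): {', '.join(sorted(unknown))}")
        params = {**self.parameters, **overrides}
        clone = ODEModel(self.species, params, self.terms, self.inputs, self.name,
                         initial_state=self.initial_state)
        clone._compiled = self._compiled   # structure unchanged
        return clone


@dataclass
class SimulationProtocol:
    """Three-phase stimulation protocol (durations in hours).

    Phase 1: no inputs, the model settles to steady state.  Phase 2: TNF on
    at ``tnf_level`` (ng/ml) and radiation delivered as a constant dose-rate
    pulse totalling ``ir_dose`` (Gy).  Phase 3: TNF stays on, radiation off.
    """

    phase1_duration: float = 24.0
    phase2_duration: float = 1.0
    phase3_duration: float = 240.0
    tnf_level: float = 10.0
    ir_dose: float = 4.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if min(self.phase1_duration, self.phase2_duration, self.phase3_duration) <= 0:
            raise ModelError("phase durations must be positive")
        if self.ir_dose < 0:
            raise ModelError("ir_dose must be nonnegative")
        if self.step <= 0:
            raise ModelError("sampling step must be positive")

    @property
    def phase_boundaries(self) -> tuple[float, float]:
        return (
            self.phase1_duration,
            self.phase1_duration + self.phase2_duration,
        )

    @property
    def total_duration(self) -> float:
        return self.phase1_duration + self.phase2_duration + self.phase3_duration

    def inputs_for_phase(self, phase: int) -> dict[str, float]:
        if phase == 1:
            return {"TNF": 0.0, "IR": 0.0}
        ir_rate = self.ir_dose / self.phase2_duration
        if phase == 2:
            return {"TNF": self.tnf_level, "IR": ir_rate}
        return {"TNF": self.tnf_level, "IR": 0.0}


@dataclass
class Trajectory:
    """Time grid (hours), species × time value matrix and phase boundaries."""

    time: np.ndarray
    values: np.ndarray            # shape (n_species, n_times)
    species: tuple[str, ...]
    phase_boundaries: tuple[float, float]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]

    def final_state(self) -> np.ndarray:
        return self.values[:, -1]

    def window(self, t_from: float, t_to: float | None = None) -> np.ndarray:
        mask = self.time >= t_from
        if t_to is not None:
            mask &= self.time <= t_to
        return mask

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_h": self.time, **{s: self[s] for s in self.species}}
        )

    def to_csv(self, stream: IO[str] | str) -> None:
        self.to_frame().to_csv(stream, index=False)


def evaluate_rhs(
    model: ODEModel,
    state: Sequence[float],
    t: float = 0.0,
    inputs: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Derivative vector at ``state``: per species, the signed sum of its terms."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(model.species),):
        raise ModelError(
            f"state length {state.shape} does not match {len(model.species)} species"
        )
    if not np.all(np.isfinite(state)):
        raise ModelError("state contains NaN or infinite entries")
    inputs = inputs or {}
    fn = model._compile()
    args = (
        list(state)
        + [float(inputs.get(u, 0.0)) for u in model.inputs]
        + [float(model.parameters[p]) for p in sorted(model.parameters)]
    )
    return np.asarray(fn(*args), dtype=float)


def _integrate_phase(
    model: ODEModel,
    x0: np.ndarray,
    t0: float,
    t1: float,
    inputs: Mapping[str, float],
    step: float,
    method: str,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    fn = model._compile()
    input_vals = [float(inputs.get(u, 0.0)) for u in model.inputs]
    param_vals = [float(model.parameters[p]) for p in sorted(model.parameters)]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return np.asarray(fn(*y, *input_vals, *param_vals), dtype=float)

    n_pts = max(2, int(round((t1 - t0) / step)) + 1)
    t_eval = np.linspace(t0, t1, n_pts)
    sol = solve_ivp(rhs, (t0, t1), x0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t0
        raise IntegrationError(f"integration failed: {sol.message}", last)
    return sol.t, sol.y


def simulate_protocol(
    model: ODEModel,
    protocol: SimulationProtocol,
    overrides: Mapping[str, float] | None = None,
    initial_state: Sequence[float] | None = None,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    equilibrium_tol: tuple[float, float] = (1e-6, 1e-9),
) -> Trajectory:
    """Integrate the model through the three protocol phases.

    Uses a stiff-capable adaptive solver; inputs are piecewise constant and
    switched exactly at the phase boundaries.  If the end of phase 1 is not
    at equilibrium (``‖dx/dt‖∞ < rtol_eq·‖x‖∞ + atol_eq``) a warning is
    issued.  Small negative excursions below the absolute solver tolerance
    are clipped to zero; larger ones are left visible as a modelling error.
    """
    if overrides:
        model = model.with_parameters(overrides)
    x = np.asarray(
        initial_state if initial_state is not None else model.initial_state,
        dtype=float,
    )
    t_start = 0.0
    times: list[np.ndarray] = []
    values: list[np.ndarray] = []
    b1, b2 = protocol.phase_boundaries
    spans = [(1, t_start, b1), (2, b1, b2), (3, b2, protocol.total_duration)]
    for phase, t0, t1 in spans:
        inputs = protocol.inputs_for_phase(phase)
        t_arr, y_arr = _integrate_phase(
            model, x, t0, t1, inputs, protocol.step, method, rtol, atol
        )
        x = y_arr[:, -1].copy()
        if phase == 1:
            deriv = evaluate_rhs(model, np.maximum(x, 0.0), t1, inputs)
            bound = (
                equilibrium_tol[0] * float(np.max(np.abs(x), initial=0.0))
                + equilibrium_tol[1]
            )
            if float(np.max(np.abs(deriv), initial=0.0)) >= bound:
                warnings.warn(
                    "phase 1 did not reach equilibrium within tolerance "
                    f"(‖dx/dt‖∞ = {float(np.max(np.abs(deriv))):.3g})",
                    stacklevel=2,
                )
        times.append(t_arr if not times else t_arr[1:])
        values.append(y_arr if len(values) == 0 else y_arr[:, 1:])
    time = np.concatenate(times)
    vals = np.concatenate(values, axis=1)
    vals[(vals < 0) & (vals > -10 * atol)] = 0.0
    return Trajectory(time, vals, tuple(model.species), (b1, b2))


def settling_time(
    traj: Trajectory,
    species: str,
    band: float = 0.05,
    reference: float | None = None,
) -> float:
    """Settling time after the stimulation phase.

    The smallest ``t*`` past the end of phase 2 such that the species stays
    within ``±band·reference`` of its final value at every later grid point.
    ``reference`` defaults to the post-stimulus excursion amplitude
    ``max|x(t) − x_final|`` (the usual control-engineering convention of a
    tolerance band relative to the step size).  Returns ``NOT_SETTLED``
    (NaN) when the response has not entered the band for good.
    """
    if band <= 0:
        raise ModelError("band must be positive")
    x = traj[species]
    t = traj.time
    mask = t >= traj.phase_boundaries[1]
    if not np.any(mask):
        raise ModelError("trajectory does not extend past the stimulation phase")
    xw, tw = x[mask], t[mask]
    final = float(xw[-1])
    if reference is None:
        reference = float(np.max(np.abs(xw - final), initial=0.0))
        if reference == 0.0:
            return 0.0
    tol = band * reference
    inside = np.abs(xw - final) <= tol
    if not inside[-1]:
        return NOT_SETTLED
    # last index where the trajectory is outside the band
    outside = np.nonzero(~inside)[0]
    if outside.size == 0:
        return 0.0
    idx = outside[-1] + 1
    # the final value trivially lies in its own band, so demand that the
    # settled tail has real extent; otherwise (e.g. a sustained oscillation
    # sampled near a crossing) the response has not settled
    if len(xw) - idx < max(2, int(0.05 * len(xw))):
        return NOT_SETTLED
    t_star = float(tw[idx])
    return t_star - float(traj.phase_boundaries[1])


def reduced_fixture_model() -> ODEModel:
    """Closed six-species reduction of the nuclear p53 activation module.

    Species: ``p53_n``, ``p53_pn``, ``ATM_an``, ``CHK2_pn``, ``WIP1_n``,
    ``MDM2_pn`` (arbitrary concentration units, time in hours).  The
    ``p53_pn`` balance carries the six canonical terms: spontaneous
    activation, ATM- and Chk2-dependent activation (each saturating in the
    kinase level), Wip1-dependent inactivation, spontaneous and
    Mdm2-dependent (quadratic in Mdm2) degradation.  ``p53_n`` mirrors the
    activation/inactivation terms and adds synthesis and first-order decay.
    The four regulators are simple first-order drivers: ATM and Chk2
    production is gated by the radiation dose-rate input, Wip1 and Mdm2 are
    constitutive, so without radiation the stress arms settle at zero and
    the model sits in low-stress homeostasis.

    Parameter values are package defaults on an arbitrary scale, chosen so
    that activation, inactivation and degradation compete at comparable
    magnitudes and the no-input steady state is reached well within 24 h;
    they are deliberately not calibrated to any measured kinetics.
    """
    terms = [
        # p53_pn: the six-term balance
        RateTerm("p53_pn", +1, "act_spont * p53_n", "spontaneous p53 activation"),
        RateTerm(
            "p53_pn", +1,
            "act_atm_max * ATM_an / (ATM_an + km_atm) * p53_n",
            "ATM-dependent p53 activation",
        ),
        RateTerm(
            "p53_pn", +1,
            "act_chk2_max * CHK2_pn / (CHK2_pn + km_chk2) * p53_n",
            "Chk2-dependent p53 activation",
        ),
        RateTerm(
            "p53_pn", -1, "inact_wip1 * p53_pn * WIP1_n",
            "Wip1-dependent p53 inactivation",
        ),
        RateTerm("p53_pn", -1, "deg_spont * p53_pn", "spontaneous p53pn degradation"),
        RateTerm(
            "p53_pn", -1, "deg_mdm2 * MDM2_pn**2 * p53_pn",
            "Mdm2-dependent p53pn degradation",
        ),
        # p53_n: synthesis, mirrored conversion terms, decay
        RateTerm("p53_n", +1, "p53_syn", "p53 synthesis"),
        RateTerm("p53_n", -1, "act_spont * p53_n", "spontaneous p53 activation"),
        RateTerm(
            "p53_n", -1,
            "act_atm_max * ATM_an / (ATM_an + km_atm) * p53_n",
            "ATM-dependent p53 activation",
        ),
        RateTerm(
            "p53_n", -1,
            "act_chk2_max * CHK2_pn / (CHK2_pn + km_chk2) * p53_n",
            "Chk2-dependent p53 activation",
        ),
        RateTerm(
            "p53_n", +1, "inact_wip1 * p53_pn * WIP1_n",
            "Wip1-dependent p53 inactivation",
        ),
        RateTerm("p53_n", -1, "p53n_deg * p53_n", "p53n degradation"),
        # first-order drivers, IR-gated for the damage arm
        RateTerm("ATM_an", +1, "atm_act * IR", "ATM activation by radiation"),
        RateTerm("ATM_an", -1, "atm_deact * ATM_an", "ATM deactivation"),
        RateTerm("CHK2_pn", +1, "chk2_act * IR", "Chk2 activation by radiation"),
        RateTerm("CHK2_pn", -1, "chk2_deact * CHK2_pn", "Chk2 dephosphorylation"),
        RateTerm("WIP1_n", +1, "wip1_syn", "Wip1 synthesis"),
        RateTerm("WIP1_n", -1, "wip1_deg * WIP1_n", "Wip1 degradation"),
        RateTerm("MDM2_pn", +1, "mdm2_syn", "Mdm2 synthesis"),
        RateTerm("MDM2_pn", -1, "mdm2_deg * MDM2_pn", "Mdm2 degradation"),
    ]
    parameters = {
        "act_spont": 0.03,     # 1/h
        "act_atm_max": 0.5,    # 1/h at kinase saturation
        "act_chk2_max": 0.3,   # 1/h at kinase saturation
        "km_atm": 1.0,         # half-saturation level, a.u.
        "km_chk2": 1.0,
        "inact_wip1": 0.4,     # 1/(a.u.·h)
        "deg_spont": 0.1,      # 1/h
        "deg_mdm2": 0.1,       # 1/(a.u.²·h)
        "p53_syn": 0.5,        # a.u./h
        "p53n_deg": 0.8,       # 1/h
        "atm_act": 0.5,        # a.u. per Gy
        "atm_deact": 0.5,      # 1/h
        "chk2_act": 0.3,       # a.u. per Gy
        "chk2_deact": 0.4,     # 1/h
        "wip1_syn": 1.0,       # a.u./h
        "wip1_deg": 1.0,       # 1/h
        "mdm2_syn": 1.0,       # a.u./h
        "mdm2_deg": 1.0,       # 1/h
    }
    return ODEModel(
        ["p53_n", "p53_pn", "ATM_an", "CHK2_pn", "WIP1_n", "MDM2_pn"],
        parameters,
        terms,
        inputs=("TNF", "IR"),
        name="p53-reduced",
    )


def load_model(stream: IO[str] | str) -> ODEModel:
    """Load a model from a YAML configuration.

    Layout::

        name: mymodel
        species: [x, y]
        inputs: [TNF, IR]
        parameters: {a: 1.0, b: 0.5}
        terms:
          - {target: x, sign: "+", rate: "a", name: production}
          - {target: x, sign: "-", rate: "b * x", name: decay}
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return load_model(fh)
    cfg = yaml.safe_load(stream)
    try:
        terms = [
            RateTerm(
                t["target"],
                +1 if str(t.get("sign", "+")).strip() in ("+", "+1", "1") else -1,
                str(t["rate"]),
                t.get("name", ""),
            )
            for t in cfg["terms"]
        ]
        return ODEModel(
            cfg["species"],
            {k: float(v) for k, v in cfg["parameters"].items()},
            terms,
            inputs=cfg.get("inputs", ["TNF", "IR"]),
            name=cfg.get("name", "model"),
            initial_state=(
                [float(cfg["initial_state"][s]) for s in cfg["species"]]
                if "initial_state" in cfg else None
            ),
        )
    except KeyError as exc:
        raise ModelError(f"model configuration missing key: {exc}") from exc
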