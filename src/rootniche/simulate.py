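"""Hybrid simulation: ODE integration with threshold-triggered cell divisions.

Between events the regulatory ODEs are integrated with an adaptive explicit
Runge-Kutta 4(5) scheme; division events are located by root-finding on
threshold crossings.  When an agent divides its capacity doubles, which is
represented by halving every protein abundance in that agent, and the
integration restarts from the halved state.

Division rules: the QC divides when the SHR/SCR complex crosses its
threshold upward while WOX5 is below its bound; the CEI divides when
CYCD6;1 crosses its threshold upward, subject (in the repressor-X model)
to a refractory window enforcing a minimum time between successive CEI
divisions.  Each rule latches: after a firing (or a gated non-firing) the
trigger species must fall back below threshold before it can fire again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    IntegrationFailureError,
    RuleViolationError,
    UnsupportedVariantError,
)
from .model import CellType, RegulatoryModel, Species, build_model

__all__ = [
    "DivisionRules",
    "DivisionEvent",
    "Trajectory",
    "simulate",
    "apply_division",
    "detect_events",
    "simulate_mutant",
    "division_intervals",
    "MUTANT_INITIAL_SCALES",
]

#: Residual initial expression in loss-of-function lines, as a fraction of
#: wild type (from mutant transcriptome quantification: WOX5 reduced by
#: 99.53%, AN3 by 88.12%).
MUTANT_INITIAL_SCALES = {"wox5": 0.0047, "an3": 0.1188}


@dataclass(frozen=True)
class DivisionRules:
    """Thresholds and timing constraints converting trajectories into divisions.

    ``theta_ssc_qc``/``theta_wox5_qc`` define the QC predicate (SSC high and
    WOX5 low, both in FPKM); ``theta_cycd6`` the CEI trigger.  ``refractory_cei``
    is the minimum time (h) between successive CEI divisions — 0 in the
    wild-type model, 16 h in the repressor-X model.
    """

    theta_ssc_qc: float
    theta_wox5_qc: float
    theta_cycd6: float
    refractory_cei: float = 0.0
    refractory_qc: float = 0.0
    latch: bool = True

    def __post_init__(self):
        if self.theta_ssc_qc <= 0 or self.theta_wox5_qc <= 0 or self.theta_cycd6 <= 0:
            raise ConfigurationError("division thresholds must be > 0")
        if self.refractory_cei < 0 or self.refractory_qc < 0:
            raise ConfigurationError("refractory windows must be >= 0")


@dataclass(frozen=True)
class DivisionEvent:
    agent: CellType
    time: float  # hours post-germination


@dataclass
class Trajectory:
    """Simulated states on a dense grid plus the located division events.

    Event times appear twice in ``times``: the first row holds the pre-division
    state, the second the halved post-division state.
    """

    times: np.ndarray
    states: np.ndarray  # n_times x n_states, FPKM
    events: list[DivisionEvent]
    variant: str
    model: RegulatoryModel = field(repr=False)
    solver_report: dict = field(default_factory=dict)

    def series(self, cell_type, species) -> np.ndarray:
        """Abundance trace of one species in one agent."""
        return self.states[:, self.model.index(cell_type, species)]

    def state_at(self, t: float) -> np.ndarray:
        """Linearly interpolated state vector at time ``t``."""
        out = np.empty(self.states.shape[1])
        for j in range(self.states.shape[1]):
            out[j] = np.interp(t, self.times, self.states[:, j])
        return out

    def event_times(self, agent) -> list[float]:
        agent = CellType(agent)
        return [e.time for e in self.events if e.agent is agent]


def apply_division(
    state: np.ndarray, agent, model: RegulatoryModel
) -> np.ndarray:
    """Halve every species of a dividing agent; other agents are untouched."""
    agent = CellType(agent)
    if not agent.division_capable:
        raise RuleViolationError(f"{agent.value} agents do not divide")
    out = np.array(state, dtype=float)
    out[model.agent_indices(agent)] *= 0.5
    return out


def detect_events(
    model: RegulatoryModel,
    rules: DivisionRules,
    t: float,
    state: np.ndarray,
    history: list[DivisionEvent],
) -> list[DivisionEvent]:
    """Which divisions fire at time ``t`` given the state and past events.

    The caller is responsible for crossing detection (this predicate assumes
    the trigger species are at/above threshold *now* following an upward
    crossing); this function applies the gating conditions: the QC WOX5
    bound and the CEI refractory window.
    """
    # triggers are compared with a small relative slack: the located root
    # sits at the threshold only up to solver tolerance
    def at_or_above(value, theta):
        return value >= theta * (1.0 - 1e-9) - 1e-12

    fired = []
    ssc_q = state[model.index(CellType.QC, Species.SSC)]
    wox_q = state[model.index(CellType.QC, Species.WOX5)]
    if at_or_above(ssc_q, rules.theta_ssc_qc) and wox_q < rules.theta_wox5_qc:
        last_qc = max(
            (e.time for e in history if e.agent is CellType.QC), default=-math.inf
        )
        if t - last_qc >= rules.refractory_qc:
            fired.append(DivisionEvent(CellType.QC, t))
    cyc = state[model.index(CellType.CEI, Species.CYCD6)]
    if at_or_above(cyc, rules.theta_cycd6):
        last_cei = max(
            (e.time for e in history if e.agent is CellType.CEI), default=-math.inf
        )
        if t - last_cei >= rules.refractory_cei:
            fired.append(DivisionEvent(CellType.CEI, t))
    return fired


class _LatchedCrossing:
    """Terminal upward-crossing event with a latch.

    While disarmed it reports -1; it re-arms once the trigger falls a small
    hysteresis band below threshold, so each upward crossing fires at most
    once and a gated (non-fired) crossing cannot retrigger at the restart
    point, where the trigger sits exactly at the threshold.
    """

    terminal = True
    direction = 1

    def __init__(self, index: int, theta: float, armed: bool):
        self.index = index
        self.theta = theta
        self.hysteresis = max(1e-9, 1e-6 * theta)
        self.armed = armed

    def __call__(self, t, y):
        v = y[self.index] - self.theta
        if not self.armed:
            if v < -self.hysteresis:
                self.armed = True
            else:
                return -1.0
        return v

    def rearm_from(self, y) -> bool:
        """Armed status to carry into the next segment given its start state."""
        return bool(y[self.index] < self.theta - self.hysteresis)


def simulate(
    model: RegulatoryModel,
    init: np.ndarray,
    t_span: tuple[float, float],
    rules: DivisionRules | None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    dt_out: float = 0.25,
    max_events: int = 200,
    method: str = "RK45",
    state_cap: float | None = None,
) -> Trajectory:
    """Integrate the hybrid model over ``t_span``.

    ``rules=None`` disables event detection (pure ODE run, used for fitting
    and sensitivity analysis).  Returns a :class:`Trajectory`; event location
    uses the solver's root finder (well below 1e-3 h error at the default
    tolerances).  ``state_cap`` aborts the run (integration-failure signal)
    as soon as any abundance exceeds the cap — parameter-search callers use
    it to cut off diverging candidates instead of integrating them slowly.
    """
    y = np.asarray(init, dtype=float)
    if y.shape != (model.n_states,):
        raise ConfigurationError(
            f"initial state has shape {y.shape}, model needs ({model.n_states},)"
        )
    if np.any(y < 0):
        raise ConfigurationError("initial state must be nonnegative")
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ConfigurationError("t_span must be increasing")

    out_grid = np.arange(t0, t1, dt_out)
    out_grid = np.append(out_grid, t1)  # endpoint exact, never outside t_span

    rhs = model.rhs
    if state_cap is not None:

        def rhs(t, state, _inner=model.rhs, _cap=float(state_cap)):
            if not np.all(np.isfinite(state)) or np.max(np.abs(state)) > _cap:
                raise IntegrationFailureError(
                    f"state magnitude exceeded cap {_cap:g}", last_time=t
                )
            return _inner(t, state)

    if rules is None:
        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, t_eval=out_grid, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise IntegrationFailureError(sol.message, last_time=sol.t[-1] if len(sol.t) else t0)
        return Trajectory(
            times=sol.t,
            states=sol.y.T,
            events=[],
            variant=model.variant,
            model=model,
            solver_report={"rtol": rtol, "atol": atol, "nfev": sol.nfev, "segments": 1},
        )

    i_ssc_q = model.index(CellType.QC, Species.SSC)
    i_cyc_c = model.index(CellType.CEI, Species.CYCD6)

    times: list[float] = []
    states: list[np.ndarray] = []
    events: list[DivisionEvent] = []
    nfev = 0
    segments = 0
    t_cur = t0
    # latch: an event starts armed only if its trigger is below threshold
    qc_armed = y[i_ssc_q] < rules.theta_ssc_qc
    cei_armed = y[i_cyc_c] < rules.theta_cycd6

    while t_cur < t1 - 1e-12:
        ev_qc = _LatchedCrossing(i_ssc_q, rules.theta_ssc_qc, qc_armed)
        ev_cei = _LatchedCrossing(i_cyc_c, rules.theta_cycd6, cei_armed)
        seg_eval = out_grid[(out_grid > t_cur + 1e-12) & (out_grid <= t1)]
        sol = solve_ivp(
            rhs,
            (t_cur, t1),
            y,
            method=method,
            events=[ev_qc, ev_cei],
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
        )
        segments += 1
        nfev += sol.nfev
        if sol.status < 0:
            raise IntegrationFailureError(
                sol.message, last_time=sol.t[-1] if len(sol.t) else t_cur
            )
        if not times or (len(times) and times[-1] < t_cur):
            times.append(t_cur)
            states.append(y.copy())

        sol_t = np.asarray(sol.t, dtype=float)
        sol_y = np.asarray(sol.y, dtype=float)
        if sol.status == 1:  # a threshold crossing stopped the segment
            cand = []
            for k in range(2):
                if len(sol.t_events[k]):
                    cand.append((sol.t_events[k][0], k, sol.y_events[k][0]))
            te, which, ye = min(cand, key=lambda c: c[0])
            if sol_t.size:
                keep = sol_t < te - 1e-12
                times.extend(sol_t[keep])
                states.extend(sol_y.T[keep])
            times.append(te)
            states.append(np.array(ye))
            fired = detect_events(model, rules, te, ye, events)
            agent = CellType.QC if which == 0 else CellType.CEI
            fired_here = next((e for e in fired if e.agent is agent), None)
            if fired_here is not None and len(events) < max_events:
                events.append(fired_here)
                y = apply_division(ye, agent, model)
                times.append(te)
                states.append(y.copy())
            else:
                y = np.array(ye)
            # latches: a trigger at/above threshold stays disarmed until it
            # falls back below (prevents chattering and immediate refiring)
            qc_armed = ev_qc.rearm_from(y)
            cei_armed = ev_cei.rearm_from(y)
            t_cur = te
        else:
            if sol_t.size:
                times.extend(sol_t)
                states.extend(sol_y.T)
            t_cur = t1

    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        events=events,
        variant=model.variant,
        model=model,
        solver_report={
            "rtol": rtol,
            "atol": atol,
            "nfev": nfev,
            "segments": segments,
        },
    )


def simulate_mutant(
    model: RegulatoryModel,
    mutant: str,
    base_init: np.ndarray,
    t_span: tuple[float, float],
    rules: DivisionRules | None,
    scale: float | None = None,
    **solver_opts,
) -> Trajectory:
    """Simulate a loss-of-function mutant from a scaled wild-type initial state.

    ``wox5``: every WOX5 component is scaled to 0.47% of its wild-type
    initial value (wild-type topology).  ``an3``: every AN3 component (QC,
    CEI, endodermis) is scaled to 11.88%, run on the repressor-X topology.
    ``base_init`` is the wild-type 4-day initial condition for ``model``'s
    own roster, or for the 17-state wild-type roster (it is then embedded,
    with X starting at zero).
    """
    if mutant not in MUTANT_INITIAL_SCALES:
        raise UnsupportedVariantError(
            f"unknown mutant {mutant!r}; expected one of {tuple(MUTANT_INITIAL_SCALES)}"
        )
    factor = MUTANT_INITIAL_SCALES[mutant] if scale is None else float(scale)
    species = Species.WOX5 if mutant == "wox5" else Species.AN3

    base_init = np.asarray(base_init, dtype=float)
    if base_init.shape != (model.n_states,):
        init = embed_initial_state(model, base_init)
    else:
        init = base_init.copy()
    for (ct, sp), i in model.state_index.items():
        if sp is species:
            init[i] *= factor
    return simulate(model, init, t_span, rules, **solver_opts)


def embed_initial_state(model: RegulatoryModel, wt_init: np.ndarray) -> np.ndarray:
    """Embed a 17-state wild-type initial condition into ``model``'s roster.

    Shared (agent, species) entries are copied; extra states (repressor X)
    start at zero.
    """
    wt = build_model("wt", model.params)
    wt_init = np.asarray(wt_init, dtype=float)
    if wt_init.shape != (wt.n_states,):
        raise ConfigurationError(
            f"base initial state has shape {wt_init.shape}; expected ({wt.n_states},)"
        )
    init = np.zeros(model.n_states)
    for key, i in model.state_index.items():
        if key in wt.state_index:
            init[i] = wt_init[wt.state_index[key]]
    return init


def division_intervals(traj: Trajectory, agent) -> list[float]:
    """Successive differences of one agent's division times (empty if < 2)."""
    times = traj.event_times(agent)
    return list(np.diff(times)) if len(times) >= 2 else []
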