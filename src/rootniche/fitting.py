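"""Fitting: time-course extrapolation, schedule fitting and parameter estimation.

The model is fitted to cell-type-specific FPKM time courses on the 8-h grid
from 4 to 6 days.  These are built by overlaying 5-day cell-type FPKM values
onto stem-cell-niche fold-change time courses (anchored at 5 days).  The
time-dependent production rates of WOX5 and AN3 are fitted interval by
interval in closed form; the remaining sensitive parameters are estimated by
simulated annealing started from a Latin-hypercube sample, and the runs are
averaged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import qmc

from .errors import (
    CalibrationError,
    ConfigurationError,
    IncompleteGridError,
    IntegrationFailureError,
    RootNicheError,
)
from .model import (
    SCHEDULE_GRID,
    SCHEDULED_PRODUCTIONS,
    CellType,
    RegulatoryModel,
    Species,
    build_model,
)
from .simulate import DivisionRules, Trajectory, simulate

__all__ = [
    "TimeCourse",
    "ParameterEstimate",
    "extrapolate_timecourse",
    "fit_production_schedule",
    "initial_state_from_timecourse",
    "objective",
    "estimate_parameters",
    "calibrate_thresholds",
    "OBJECTIVE_SENTINEL",
]

#: Large finite surrogate returned when the solver fails inside the objective.
OBJECTIVE_SENTINEL = 1e12


@dataclass(frozen=True)
class TimeCourse:
    """Cell-type x species x time FPKM grid.

    ``frame`` is tidy with columns ``species, cell_type, time_h, fpkm``.
    ``provenance`` records how the grid was obtained
    (measured | extrapolated | synthetic).
    """

    frame: pd.DataFrame
    provenance: str = "synthetic"

    def __post_init__(self):
        required = {"species", "cell_type", "time_h", "fpkm"}
        if not required.issubset(self.frame.columns):
            raise ConfigurationError(f"time course frame needs columns {sorted(required)}")
        if (self.frame["fpkm"] < 0).any():
            raise ConfigurationError("FPKM values must be >= 0")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(
            {(r.species, r.cell_type) for r in self.frame.itertuples()}
        )

    def value(self, species: str, cell_type: str, time_h: float) -> float:
        m = self.frame[
            (self.frame["species"] == species)
            & (self.frame["cell_type"] == cell_type)
            & (np.isclose(self.frame["time_h"], time_h))
        ]
        if m.empty:
            raise KeyError((species, cell_type, time_h))
        return float(m["fpkm"].iloc[0])

    def series(self, species: str, cell_type: str) -> np.ndarray:
        """FPKM values on the full grid, in grid order."""
        sub = self.frame[
            (self.frame["species"] == species) & (self.frame["cell_type"] == cell_type)
        ].sort_values("time_h")
        if len(sub) != len(SCHEDULE_GRID) or not np.allclose(
            sub["time_h"].to_numpy(), SCHEDULE_GRID
        ):
            raise IncompleteGridError(
                f"({species}, {cell_type}) does not cover the full 8-h grid"
            )
        return sub["fpkm"].to_numpy()

    def require_full_grid(self) -> None:
        for s, c in self.pairs:
            self.series(s, c)


@dataclass(frozen=True)
class ParameterEstimate:
    """All annealing runs plus their arithmetic mean."""

    names: tuple[str, ...]
    runs: np.ndarray  # n_runs x n_free
    objectives: np.ndarray  # n_runs
    bounds: np.ndarray  # n_free x 2 (natural scale)
    seed: int | None

    @property
    def mean(self) -> np.ndarray:
        return self.runs.mean(axis=0)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.mean))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"name": n, "run": r, "estimate": self.runs[r, j]}
            for r in range(self.runs.shape[0])
            for j, n in enumerate(self.names)
        ]
        return pd.DataFrame(rows)


def extrapolate_timecourse(fpkm_5d, foldchanges) -> TimeCourse:
    """Overlay 5-day cell-type FPKM onto fold-change time courses.

    ``fpkm_5d`` maps ``(species, cell_type) -> FPKM at 120 h``;
    ``foldchanges`` maps ``(species, time_h) -> fold change``.  Fold changes
    are renormalised to their 120-h value, so the extrapolated series equals
    the 5-day FPKM exactly at the anchor::

        value(s, c, t) = fpkm_5d(s, c) * fc(s, t) / fc(s, 120)
    """
    fpkm_5d = dict(fpkm_5d)
    foldchanges = dict(foldchanges)
    rows = []
    species = sorted({s for s, _ in fpkm_5d})
    for s in species:
        missing = [t for t in SCHEDULE_GRID if (s, t) not in foldchanges]
        if missing:
            raise IncompleteGridError(
                f"fold changes for {s} missing at t = {missing}"
            )
        anchor = foldchanges[(s, 120.0)]
        if anchor <= 0:
            raise IncompleteGridError(f"fold change anchor for {s} at 120 h must be > 0")
        for (s2, c), v in fpkm_5d.items():
            if s2 != s:
                continue
            for t in SCHEDULE_GRID:
                rows.append(
                    {
                        "species": s,
                        "cell_type": c,
                        "time_h": float(t),
                        "fpkm": float(v) * foldchanges[(s, t)] / anchor,
                    }
                )
    return TimeCourse(pd.DataFrame(rows), provenance="extrapolated")


def _effective_loss_rate(model: RegulatoryModel, name: str) -> float:
    """Linear loss rate seen by a scheduled species (degradation + efflux)."""
    sp, ct = SCHEDULED_PRODUCTIONS[name]
    p = model.params
    if sp is Species.WOX5 and ct is CellType.QC:
        return p["d1_qc"] + p["b_qc"] + p["b_cei"]
    return p[f"d2_{ct.value.lower()}"]


def fit_production_schedule(
    model: RegulatoryModel, species, data: TimeCourse
) -> dict[str, np.ndarray]:
    """Fit piecewise-constant production rates for WOX5 or AN3.

    The scheduled species obey a scalar linear ODE per interval,
    ``x' = k - d_eff * x``, decoupled from the rest of the system, so the
    rate matching the data at each interval endpoint is available in closed
    form and is clipped at zero when the unconstrained optimum is negative.
    Returns one 7-value schedule per scheduled production of ``species``
    (the last value pads the final grid point).
    """
    species = Species(species)
    if species not in (Species.WOX5, Species.AN3):
        raise ConfigurationError("only WOX5 and AN3 have scheduled production")
    dt = float(SCHEDULE_GRID[1] - SCHEDULE_GRID[0])
    out: dict[str, np.ndarray] = {}
    for name, (sp, ct) in SCHEDULED_PRODUCTIONS.items():
        if sp is not species:
            continue
        target = data.series(sp.value, ct.value)
        d = _effective_loss_rate(model, name)
        decay = math.exp(-d * dt)
        rates = np.zeros(len(SCHEDULE_GRID))
        x = target[0]
        for i in range(len(SCHEDULE_GRID) - 1):
            if d > 0:
                k = d * (target[i + 1] - x * decay) / (1.0 - decay)
            else:
                k = (target[i + 1] - x) / dt
            if k < 0:
                warnings.warn(
                    f"{name}: unconstrained rate {k:.3g} on interval {i} clipped to 0",
                    stacklevel=2,
                )
                k = 0.0
            rates[i] = k
            x = x * decay + (k / d) * (1.0 - decay) if d > 0 else x + k * dt
        rates[-1] = rates[-2]
        out[name] = rates
    return out


def initial_state_from_timecourse(
    model: RegulatoryModel, data: TimeCourse, t: float = 96.0
) -> np.ndarray:
    """Initial condition from the 4-day column of a time course.

    Species without data — the SHR/SCR complex, repressor X and anything
    absent from the table (e.g. WOX5 in the vasculature, which is very lowly
    expressed) — start at zero.
    """
    init = np.zeros(model.n_states)
    for (ct, sp), i in model.state_index.items():
        try:
            init[i] = data.value(sp.value, ct.value, t)
        except KeyError:
            init[i] = 0.0
    return init


def objective(
    free_values,
    model: RegulatoryModel,
    data: TimeCourse,
    free_names,
    rules: DivisionRules | None = None,
    init: np.ndarray | None = None,
    t_span=(96.0, 144.0),
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Sum of squared FPKM errors between a simulated run and a time course.

    ``free_values`` replace the named parameters before simulating.  Cells of
    the grid whose (species, cell type) pair is not modelled are ignored.
    Solver failures return a large finite sentinel instead of raising.
    """
    free_names = list(free_names)
    if len(free_names) != len(free_values):
        raise ConfigurationError("free_values and free_names length mismatch")
    try:
        params = model.params.replace(**dict(zip(free_names, map(float, free_values))))
        candidate = build_model(model.variant, params, model.production_schedules)
        if init is None:
            init = initial_state_from_timecourse(candidate, data, t_span[0])
        # output only at the 8-h grid: the SSE is evaluated there anyway
        traj = simulate(
            candidate, init, t_span, rules,
            rtol=rtol, atol=atol, dt_out=8.0, state_cap=1e9,
        )
    except (IntegrationFailureError, OverflowError, FloatingPointError, RootNicheError):
        return OBJECTIVE_SENTINEL
    sse = 0.0
    for s, c in data.pairs:
        try:
            j = candidate.index(c, s)
        except KeyError:
            continue
        sim = np.interp(SCHEDULE_GRID, traj.times, traj.states[:, j])
        sse += float(np.sum((sim - data.series(s, c)) ** 2))
    if not np.isfinite(sse):
        return OBJECTIVE_SENTINEL
    return sse


def _anneal(
    fun,
    x0_log: np.ndarray,
    lo_log: np.ndarray,
    hi_log: np.ndarray,
    rng: np.random.Generator,
    n_temps: int,
    iters_per_temp: int,
    cooling: float,
    step: float,
    step_shrink: float = 0.93,
) -> tuple[np.ndarray, float]:
    """Simulated annealing in log10 space with Gaussian proposals.

    Geometric cooling with a matching geometric shrink of the proposal step,
    so the walk explores globally at high temperature and refines locally at
    low temperature; proposals are reflected back into the bounds.  Returns
    the best point (log10) and its objective.
    """
    x = x0_log.copy()
    f = fun(x)
    best_x, best_f = x.copy(), f
    T = max(abs(f), 1.0) * 0.3
    for _ in range(n_temps):
        for _ in range(iters_per_temp):
            prop = x + rng.normal(0.0, step, size=x.shape)
            # reflect into the box
            prop = np.where(prop < lo_log, 2 * lo_log - prop, prop)
            prop = np.where(prop > hi_log, 2 * hi_log - prop, prop)
            prop = np.clip(prop, lo_log, hi_log)
            fp = fun(prop)
            if fp <= f or rng.random() < math.exp(-(fp - f) / max(T, 1e-300)):
                x, f = prop, fp
                if f < best_f:
                    best_x, best_f = x.copy(), f
        # restart each temperature level from the incumbent best
        x, f = best_x.copy(), best_f
        T *= cooling
        step *= step_shrink
    return best_x, best_f


def estimate_parameters(
    model: RegulatoryModel,
    data: TimeCourse,
    free_names,
    bounds=None,
    n_runs: int = 40,
    seed: int | None = None,
    rules: DivisionRules | None = None,
    init: np.ndarray | None = None,
    n_temps: int = 40,
    iters_per_temp: int = 25,
    cooling: float = 0.9,
    step: float = 0.5,
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> ParameterEstimate:
    """Estimate free parameters by simulated annealing from Latin-hypercube starts.

    One Latin-hypercube sample of size ``n_runs`` (in log10 space over the
    bounds) provides the starting points; each start is refined by an
    independent annealing run and the arithmetic mean across runs is the
    reported estimate.  ``bounds`` maps name -> (lo, hi); the default is a
    factor of 100 either side of the nominal value.
    """
    free_names = list(free_names)
    if not free_names:
        raise ConfigurationError("free_names must not be empty")
    model.params.require(free_names)
    if bounds is None:
        bounds = {}
    b = np.empty((len(free_names), 2))
    for j, name in enumerate(free_names):
        if name in bounds:
            lo, hi = bounds[name]
        else:
            nominal = model.params[name]
            if nominal <= 0:
                raise ConfigurationError(
                    f"cannot derive default bounds for {name} with nominal value 0"
                )
            lo, hi = nominal / 100.0, nominal * 100.0
        if not (0 < lo < hi < math.inf):
            raise ConfigurationError(f"bounds for {name} must be finite and positive")
        b[j] = (lo, hi)
    lo_log, hi_log = np.log10(b[:, 0]), np.log10(b[:, 1])

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(free_names), seed=rng)
    starts = lo_log + sampler.random(n=n_runs) * (hi_log - lo_log)

    def fun(x_log):
        return objective(
            10.0**x_log, model, data, free_names,
            rules=rules, init=init, rtol=rtol, atol=atol,
        )

    runs = np.empty((n_runs, len(free_names)))
    objs = np.empty(n_runs)
    for r in range(n_runs):
        x_best, f_best = _anneal(
            fun, starts[r], lo_log, hi_log, rng,
            n_temps=n_temps, iters_per_temp=iters_per_temp,
            cooling=cooling, step=step,
        )
        runs[r] = 10.0**x_best
        objs[r] = f_best
    return ParameterEstimate(
        names=tuple(free_names), runs=runs, objectives=objs, bounds=b, seed=seed
    )


def _upward_crossings(x: np.ndarray, theta: float) -> int:
    below = x < theta
    return int(np.sum(below[:-1] & ~below[1:]))


def _threshold_for_crossings(
    x: np.ndarray, wanted: int, prefer: str = "widest", n_levels: int = 400
) -> float | None:
    """Deterministic threshold giving exactly ``wanted`` upward crossings.

    Scans candidate levels between the trace extrema and returns the centre
    of a contiguous feasible band (``prefer='widest'``: the widest band,
    i.e. midway between the most separated extrema; ``prefer='highest'``:
    the topmost band, between the two tallest peaks), or None if no level
    works.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return None
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    feasible = np.array([_upward_crossings(x, lv) == wanted for lv in levels])
    if not feasible.any():
        return None
    runs = []  # (start, length)
    cur_start = cur_len = 0
    for i, ok in enumerate(feasible):
        if ok:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
        else:
            if cur_len:
                runs.append((cur_start, cur_len))
            cur_len = 0
    if cur_len:
        runs.append((cur_start, cur_len))
    if prefer == "highest":
        start, length = runs[-1]
    else:
        start, length = max(runs, key=lambda r: r[1])
    band = levels[start : start + length]
    return float(band[len(band) // 2])


def calibrate_thresholds(traj: Trajectory) -> DivisionRules:
    """Division thresholds from an event-free wild-type trajectory.

    Sets the CEI CYCD6;1 threshold so the trace shows exactly two upward
    crossings, the QC SHR/SCR-complex threshold so it shows exactly one, and
    the QC WOX5 bound midway between the WOX5 level at that crossing and its
    window maximum.  Deterministic given the trajectory.  The repressor-X
    topology carries the 16-h CEI refractory window.
    """
    model = traj.model
    cyc = traj.series(CellType.CEI, Species.CYCD6)
    ssc = traj.series(CellType.QC, Species.SSC)
    wox = traj.series(CellType.QC, Species.WOX5)

    theta_cyc = _threshold_for_crossings(cyc, 2)
    # the QC divides once, on the rise of the tallest complex peak
    theta_ssc = _threshold_for_crossings(ssc, 1, prefer="highest")
    if theta_cyc is None or theta_ssc is None:
        peaks_c, _ = find_peaks(cyc)
        peaks_s, _ = find_peaks(ssc)
        raise CalibrationError(
            "no feasible thresholds: "
            f"CYCD6 extrema at t={list(np.round(traj.times[peaks_c], 2))} "
            f"values={list(np.round(cyc[peaks_c], 3))}; "
            f"SSC extrema at t={list(np.round(traj.times[peaks_s], 2))} "
            f"values={list(np.round(ssc[peaks_s], 3))}"
        )
    # WOX5 bound: midway between its level at the QC firing and its maximum
    below = ssc < theta_ssc
    cross_idx = int(np.nonzero(below[:-1] & ~below[1:])[0][0]) + 1
    w_at = float(wox[cross_idx])
    w_max = float(np.max(wox))
    theta_wox = (w_at + w_max) / 2.0 if w_max > w_at else w_at + max(w_at, 1.0)
    refractory = 16.0 if Species.X in model.roster[CellType.CEI] else 0.0
    return DivisionRules(
        theta_ssc_qc=theta_ssc,
        theta_wox5_qc=theta_wox,
        theta_cycd6=theta_cyc,
        refractory_cei=refractory,
    )
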