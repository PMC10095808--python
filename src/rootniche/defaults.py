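"""Canonical parameter values, tables and scenario builders.

No external calibration tables ship with the package; this module carries
its own canonical stand-ins: a default parameter registry, 5-day cell-type
FPKM values and stem-cell-niche fold-change time courses shaped like the
experimentally characterised dynamics (a WOX5 trough around day 4.3 and
again after day 5.3, driving two SHR/SCR-complex peaks).  ``default_wt_scenario`` wires
them through the full workflow — extrapolation, schedule fitting, threshold
calibration — and is the reference wild-type run used across the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import (
    TimeCourse,
    calibrate_thresholds,
    extrapolate_timecourse,
    fit_production_schedule,
    initial_state_from_timecourse,
)
from .model import SCHEDULE_GRID, ParameterSet, RegulatoryModel, build_model
from .simulate import DivisionRules, Trajectory, simulate

__all__ = [
    "DEFAULT_PARAMS",
    "X_REFIT_PARAMS",
    "CANONICAL_FPKM_5D",
    "CANONICAL_FOLDCHANGES",
    "default_parameter_set",
    "canonical_timecourse",
    "Scenario",
    "default_wt_scenario",
    "default_repressorx_scenario",
]

#: Default registry (wild type plus repressor-X extras).  Units: productions
#: k* in FPKM/h, degradations d* and movement rates a*/b* in 1/h, complex
#: formation kon* in 1/(FPKM h), affinities K_* in FPKM, exponents n_*
#: dimensionless.
DEFAULT_PARAMS: dict[str, float] = {
    # production
    "k1_qc": 5.0,
    "k2_qc": 6.0,
    "k2_cei": 6.0,
    "k2_endo": 5.0,
    "k3_qc": 20.0,
    "k3_cei": 20.0,
    "k3_endo": 24.0,
    "k4_vasc": 60.0,
    "k5_cei": 12.0,
    # degradation
    "d1_vasc": 0.2,
    "d1_qc": 0.2,
    "d1_cei": 0.2,
    "d2_qc": 0.2,
    "d2_cei": 0.2,
    "d2_endo": 0.2,
    "d3_qc": 0.15,
    "d3_cei": 0.15,
    "d3_endo": 0.15,
    "d4_vasc": 0.3,
    "d4_qc": 0.5,
    "d4_cei": 0.18,
    "d4_endo": 0.35,
    "d5_cei": 0.15,
    # movement
    "a_qc": 0.12,
    "a_cei": 0.08,
    "a_endo": 0.06,
    "b_qc": 0.1,
    "b_cei": 0.05,
    # complex formation / decay
    "kon_qc": 0.002,
    "kon_cei": 0.002,
    "kon_endo": 0.002,
    "dssc_qc": 0.55,
    "dssc_cei": 0.18,
    "dssc_endo": 0.35,
    # Hill affinities
    "K_wox5_shr": 5.0,
    "K_scr_qc": 60.0,
    "K_scr_cei": 60.0,
    "K_scr_endo": 60.0,
    "K_D2_qc": 10.0,
    "K_D2_cei": 10.0,
    "K_D2_endo": 10.0,
    "K_an3_qc": 30.0,
    "K_an3_cei": 30.0,
    "K_an3_endo": 30.0,
    "K_ssc_cycd6": 8.0,
    # Hill exponents
    "n_wox5_shr": 2.0,
    "n_scr_auto": 2.0,
    "n_ssc_scr": 2.0,
    "n_an3_scr": 2.0,
    "n_ssc_cycd6": 2.0,
    # repressor-X extras
    "k6_cei": 8.0,
    "d6_cei": 0.25,
    "K_an3_x": 30.0,
    "K_x_cycd6": 6.0,
    "n_an3_x": 2.0,
    "n_x_cycd6": 2.0,
}

#: Re-estimated values for the six repressor-X parameters (four existing,
#: two new), used by the revised-topology reference scenario.
X_REFIT_PARAMS: dict[str, float] = {
    "k3_endo": 24.0,
    "d3_endo": 0.15,
    "k3_cei": 20.0,
    "k5_cei": 45.0,
    "k6_cei": 16.0,
    "d6_cei": 0.6,
}

#: Canonical 5-day (120 h) cell-type FPKM values.
CANONICAL_FPKM_5D: dict[tuple[str, str], float] = {
    ("SHR", "VASC"): 120.0,
    ("WOX5", "QC"): 35.0,
    ("SHR", "QC"): 20.0,
    ("SCR", "QC"): 70.0,
    ("AN3", "QC"): 30.0,
    ("SHR", "CEI"): 25.0,
    ("SCR", "CEI"): 70.0,
    ("WOX5", "CEI"): 9.0,
    ("AN3", "CEI"): 30.0,
    ("CYCD6", "CEI"): 12.0,
    ("SHR", "ENDO"): 20.0,
    ("SCR", "ENDO"): 90.0,
    ("AN3", "ENDO"): 25.0,
}

#: Canonical stem-cell-niche fold changes on the 8-h grid (anchored at 1.0
#: at 120 h).  WOX5 shows troughs early and late in the window; the other
#: regulators vary mildly.
CANONICAL_FOLDCHANGES: dict[tuple[str, float], float] = {}


def _set_foldchanges(species: str, values) -> None:
    for t, v in zip(SCHEDULE_GRID, values):
        CANONICAL_FOLDCHANGES[(species, float(t))] = float(v)


_set_foldchanges("WOX5", [0.55, 0.50, 1.05, 1.00, 0.12, 0.12, 1.00])
_set_foldchanges("AN3", [0.90, 1.00, 1.05, 1.00, 0.60, 0.35, 0.30])
_set_foldchanges("SHR", [0.80, 1.10, 0.95, 1.00, 1.10, 1.20, 1.15])
_set_foldchanges("SCR", [0.90, 1.00, 1.00, 1.00, 1.05, 1.10, 1.05])
_set_foldchanges("CYCD6", [0.60, 1.20, 0.80, 1.00, 1.10, 1.40, 1.20])


def default_parameter_set(variant: str = "wt") -> ParameterSet:
    """The full default registry (covers every variant)."""
    return ParameterSet(DEFAULT_PARAMS)


def canonical_timecourse() -> TimeCourse:
    """Extrapolated canonical tables on the 4-to-6-day grid."""
    return extrapolate_timecourse(CANONICAL_FPKM_5D, CANONICAL_FOLDCHANGES)


@dataclass(frozen=True)
class Scenario:
    """A ready-to-simulate reference configuration."""

    model: RegulatoryModel
    data: TimeCourse
    init: np.ndarray
    rules: DivisionRules
    free_trajectory: Trajectory  # event-free run used for calibration


def _build_scenario(variant: str, params: ParameterSet) -> Scenario:
    data = canonical_timecourse()
    base = build_model(variant, params)
    schedules = {}
    schedules.update(fit_production_schedule(base, "WOX5", data))
    schedules.update(fit_production_schedule(base, "AN3", data))
    model = build_model(variant, params, schedules)
    init = initial_state_from_timecourse(model, data, 96.0)
    free = simulate(model, init, (96.0, 144.0), rules=None)
    rules = calibrate_thresholds(free)
    return Scenario(model=model, data=data, init=init, rules=rules, free_trajectory=free)


def default_wt_scenario() -> Scenario:
    """The reference wild-type configuration (17 states, calibrated rules)."""
    return _build_scenario("wt", default_parameter_set())


def default_repressorx_scenario() -> Scenario:
    """The revised-topology reference configuration with re-estimated parameters."""
    params = default_parameter_set().replace(**X_REFIT_PARAMS)
    return _build_scenario("repressorx", params)
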