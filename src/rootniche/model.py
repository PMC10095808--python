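"""Core regulatory model of the root stem-cell niche.

Four cell agents — vascular initials (VASC), quiescent center (QC), cortex
endodermis initial (CEI) and endodermis (ENDO) — each carry ODEs for the
regulators they express: SHR, SCR, WOX5, AN3, CYCD6;1, the SHR/SCR complex
(SSC) and, in the repressor variants, an AN3-activated repressor X of
CYCD6;1.  Transcriptional regulation uses Hill kinetics, SHR/SCR complex
formation uses irreversible mass action, movement of the mobile proteins
SHR (from VASC) and WOX5 (from QC) is linear, gradient-independent efflux
with mass-conserving influx, and every protein decays linearly.

Abundances are carried in FPKM units (the fitting data are FPKM); time is
hours post-germination, with simulations run on the 4-to-6-day window
t in [96, 144] h.
"""

from __future__ import annotations

import json
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np

from .errors import (
    DimensionError,
    InvalidParameterError,
    MissingParameterError,
    UnsupportedVariantError,
)

__all__ = [
    "Species",
    "CellType",
    "ParameterSet",
    "RegulatoryModel",
    "hill_activation",
    "hill_repression",
    "build_model",
    "evaluate_rhs",
    "required_parameter_names",
    "SCHEDULE_GRID",
    "SCHEDULED_PRODUCTIONS",
    "WT_STATE_ROSTER",
    "VARIANTS",
]


class Species(str, Enum):
    SHR = "SHR"
    SCR = "SCR"
    WOX5 = "WOX5"
    AN3 = "AN3"
    CYCD6 = "CYCD6"
    SSC = "SSC"  # the SHR/SCR complex
    X = "X"  # hypothesised AN3-activated repressor of CYCD6;1

    @property
    def role(self) -> str:
        if self is Species.SSC:
            return "complex"
        if self is Species.X:
            return "repressor"
        return "monomer"


class CellType(str, Enum):
    VASC = "VASC"
    QC = "QC"
    CEI = "CEI"
    ENDO = "ENDO"

    @property
    def division_capable(self) -> bool:
        return self in (CellType.QC, CellType.CEI)


#: Species carried by each agent in the wild-type topology (17 states).
WT_STATE_ROSTER: dict[CellType, tuple[Species, ...]] = {
    CellType.VASC: (Species.SHR, Species.WOX5),
    CellType.QC: (Species.SHR, Species.SCR, Species.WOX5, Species.AN3, Species.SSC),
    CellType.CEI: (
        Species.SHR,
        Species.SCR,
        Species.WOX5,
        Species.AN3,
        Species.SSC,
        Species.CYCD6,
    ),
    CellType.ENDO: (Species.SHR, Species.SCR, Species.AN3, Species.SSC),
}

#: The piecewise-constant production schedules fitted to time-course data:
#: WOX5 in the QC and AN3 in QC, CEI and endodermis.
SCHEDULED_PRODUCTIONS: dict[str, tuple[Species, CellType]] = {
    "k1_qc": (Species.WOX5, CellType.QC),
    "k2_qc": (Species.AN3, CellType.QC),
    "k2_cei": (Species.AN3, CellType.CEI),
    "k2_endo": (Species.AN3, CellType.ENDO),
}

#: 8-hour grid from 4 to 6 days post-germination (hours).
SCHEDULE_GRID = np.arange(96.0, 145.0, 8.0)

VARIANTS = ("wt", "wox5", "an3", "repressorx")

# Variants sharing the revised (repressor-X) topology: X added in the CEI,
# CYCD6;1 production gated by X, AN3->SCR activation removed in CEI and ENDO.
_X_TOPOLOGY_VARIANTS = ("repressorx", "an3")

_WT_PARAM_NAMES: tuple[str, ...] = (
    # production (FPKM/h); k1/k2 are schedule baselines, k3 the SCR Vmax shared
    # by its three sufficient activators, k4 SHR in the vasculature, k5 CYCD6;1
    "k1_qc",
    "k2_qc",
    "k2_cei",
    "k2_endo",
    "k3_qc",
    "k3_cei",
    "k3_endo",
    "k4_vasc",
    "k5_cei",
    # linear degradation (1/h): 1=WOX5, 2=AN3, 3=SCR, 4=SHR, 5=CYCD6
    "d1_vasc",
    "d1_qc",
    "d1_cei",
    "d2_qc",
    "d2_cei",
    "d2_endo",
    "d3_qc",
    "d3_cei",
    "d3_endo",
    "d4_vasc",
    "d4_qc",
    "d4_cei",
    "d4_endo",
    "d5_cei",
    # movement (1/h): SHR efflux from VASC per target, WOX5 efflux from QC
    "a_qc",
    "a_cei",
    "a_endo",
    "b_qc",
    "b_cei",
    # SHR/SCR complex formation (1/(FPKM h)) and complex decay (1/h)
    "kon_qc",
    "kon_cei",
    "kon_endo",
    "dssc_qc",
    "dssc_cei",
    "dssc_endo",
    # Hill affinities (FPKM); D2 = SHR/SCR dimer complex acting on SCR
    "K_wox5_shr",
    "K_scr_qc",
    "K_scr_cei",
    "K_scr_endo",
    "K_D2_qc",
    "K_D2_cei",
    "K_D2_endo",
    "K_an3_qc",
    "K_an3_cei",
    "K_an3_endo",
    "K_ssc_cycd6",
    # Hill exponents (dimensionless, >= 1)
    "n_wox5_shr",
    "n_scr_auto",
    "n_ssc_scr",
    "n_an3_scr",
    "n_ssc_cycd6",
)

_X_EXTRA_PARAM_NAMES: tuple[str, ...] = (
    "k6_cei",
    "d6_cei",
    "K_an3_x",
    "K_x_cycd6",
    "n_an3_x",
    "n_x_cycd6",
)

_HILL_EXPONENT_PREFIX = "n_"
_AFFINITY_PREFIX = "K_"


def required_parameter_names(variant: str = "wt") -> tuple[str, ...]:
    """Names every parameter table must provide for ``variant``."""
    if variant not in VARIANTS:
        raise UnsupportedVariantError(f"unknown model variant {variant!r}")
    if variant in _X_TOPOLOGY_VARIANTS:
        return _WT_PARAM_NAMES + _X_EXTRA_PARAM_NAMES
    return _WT_PARAM_NAMES


def hill_activation(x: float, K: float, n: float) -> float:
    """Hill activation fraction ``x^n / (K^n + x^n)``.

    Strictly increasing in ``x``; 0 at ``x=0`` and 1/2 at ``x=K`` for any
    exponent.  ``x`` is an abundance (FPKM), ``K`` the half-saturation
    affinity (FPKM) and ``n >= 1`` the Hill exponent.
    """
    if K <= 0:
        raise InvalidParameterError(f"Hill affinity K must be > 0, got {K}")
    if x < 0:
        raise InvalidParameterError(f"abundance must be >= 0, got {x}")
    if n < 1:
        raise InvalidParameterError(f"Hill exponent must be >= 1, got {n}")
    xn = (x / K) ** n
    return xn / (1.0 + xn)


def hill_repression(x: float, K: float, n: float) -> float:
    """Hill repression fraction ``K^n / (K^n + x^n) = 1 - hill_activation``."""
    return 1.0 - hill_activation(x, K, n)


class ParameterSet(Mapping):
    """Immutable named registry of nonnegative rates and affinities.

    Values are validated on construction: every value must be finite and
    >= 0, Hill exponents (``n_*``) must be >= 1 and affinities (``K_*``)
    must be > 0.
    """

    def __init__(self, values: Mapping[str, float]):
        vals = {}
        for name, value in values.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {value}")
            if name.startswith(_HILL_EXPONENT_PREFIX) and v < 1:
                raise InvalidParameterError(f"Hill exponent {name} must be >= 1, got {value}")
            if name.startswith(_AFFINITY_PREFIX) and v <= 0:
                raise InvalidParameterError(f"affinity {name} must be > 0, got {value}")
            vals[name] = v
        self._values = vals

    def __getitem__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise MissingParameterError([name]) from None

    def __iter__(self):
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:
        return f"ParameterSet({len(self)} entries)"

    def require(self, names) -> None:
        """Raise :class:`MissingParameterError` listing any absent names."""
        missing = [n for n in names if n not in self._values]
        if missing:
            raise MissingParameterError(missing)

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given entries replaced or added."""
        merged = dict(self._values)
        merged.update(updates)
        return ParameterSet(merged)

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)


@dataclass(frozen=True)
class RegulatoryModel:
    """A model variant binding a state roster, parameters and ODE right-hand side.

    ``state_index`` maps ``(cell_type, species)`` to a position in the state
    vector; ``rhs(t, y)`` returns the derivative vector in FPKM/h.  The
    production of WOX5 (QC) and AN3 (QC, CEI, ENDO) is time-dependent: a
    piecewise-constant rate per 8-h interval of ``SCHEDULE_GRID``, held in
    ``production_schedules`` (right-continuous; clamped outside [96, 144] h).
    """

    variant: str
    params: ParameterSet
    roster: dict[CellType, tuple[Species, ...]]
    state_index: dict[tuple[CellType, Species], int]
    production_schedules: dict[str, np.ndarray]
    rhs: Callable[[float, np.ndarray], np.ndarray] = field(repr=False)

    @property
    def n_states(self) -> int:
        return len(self.state_index)

    @property
    def state_labels(self) -> list[str]:
        ordered = sorted(self.state_index.items(), key=lambda kv: kv[1])
        return [f"{sp.value}_{ct.value.lower()}" for (ct, sp), _ in ordered]

    def index(self, cell_type: CellType | str, species: Species | str) -> int:
        ct = CellType(cell_type)
        sp = Species(species)
        try:
            return self.state_index[(ct, sp)]
        except KeyError:
            raise KeyError(f"{sp.value} is not modelled in {ct.value}") from None

    def agent_indices(self, cell_type: CellType | str) -> np.ndarray:
        ct = CellType(cell_type)
        return np.array(
            [i for (c, _), i in self.state_index.items() if c is ct], dtype=int
        )

    def schedule_rate(self, name: str, t: float) -> float:
        """Scheduled production rate at time ``t`` (clamped to [96, 144] h)."""
        values = self.production_schedules[name]
        i = int((t - SCHEDULE_GRID[0]) // 8.0)
        return float(values[min(max(i, 0), len(values) - 1)])

    def describe(self) -> str:
        """JSON dump of variant, ordered state roster and parameter values."""
        return json.dumps(
            {
                "variant": self.variant,
                "states": self.state_labels,
                "parameters": self.params.to_dict(),
                "production_schedules": {
                    k: list(v) for k, v in self.production_schedules.items()
                },
            },
            indent=2,
        )


def _make_roster(variant: str) -> dict[CellType, tuple[Species, ...]]:
    roster = {ct: tuple(sps) for ct, sps in WT_STATE_ROSTER.items()}
    if variant in _X_TOPOLOGY_VARIANTS:
        roster[CellType.CEI] = roster[CellType.CEI] + (Species.X,)
    return roster


def build_model(
    variant: str,
    params: ParameterSet | Mapping[str, float],
    production_schedules: Mapping[str, np.ndarray] | None = None,
) -> RegulatoryModel:
    """Assemble the ODE right-hand side for a model variant.

    Per agent the wild-type equations read (Hill terms written ``H+``/``H-``
    for activation/repression, schedules ``s(t)``):

    VASC:  SHR' = k4_vasc * H-(WOX5_vasc) - d4_vasc*SHR - (a_qc+a_cei+a_endo)*SHR
           WOX5' = b_qc*WOX5_qc - d1_vasc*WOX5
    QC:    SHR' = a_qc*SHR_vasc - d4_qc*SHR - kon_qc*SHR*SCR
           SCR' = k3_qc*[H+(SCR) + H+(SSC) + H+(AN3)] - d3_qc*SCR - kon_qc*SHR*SCR
           WOX5' = s_k1_qc(t) - d1_qc*WOX5 - (b_qc+b_cei)*WOX5
           AN3' = s_k2_qc(t) - d2_qc*AN3
           SSC' = kon_qc*SHR*SCR - dssc_qc*SSC
    CEI:   as QC with its own rates, WOX5 a passive pool (b_cei influx),
           plus CYCD6' = k5_cei * H+(SSC) - d5_cei*CYCD6
    ENDO:  as QC without WOX5/CYCD6 (a_endo influx of SHR).

    The three SCR activators (autoactivation, SHR/SCR complex, AN3) are
    additive because each alone suffices to induce SCR.  The revised
    (repressor-X) topology — used by the ``repressorx`` and ``an3``
    variants — adds in the CEI ``X' = k6_cei * H+(AN3) - d6_cei*X``, gates
    CYCD6;1 production by ``H-(X)`` and removes the AN3 activation of SCR
    in the CEI and endodermis.  The ``wox5`` variant shares the wild-type
    equations (only initial conditions differ; see ``simulate_mutant``).
    """
    if variant not in VARIANTS:
        raise UnsupportedVariantError(
            f"unknown model variant {variant!r}; expected one of {VARIANTS}"
        )
    if not isinstance(params, ParameterSet):
        params = ParameterSet(params)
    params.require(required_parameter_names(variant))

    roster = _make_roster(variant)
    state_index: dict[tuple[CellType, Species], int] = {}
    for ct, sps in roster.items():
        for sp in sps:
            state_index[(ct, sp)] = len(state_index)

    schedules: dict[str, np.ndarray] = {}
    n_points = len(SCHEDULE_GRID)
    for name in SCHEDULED_PRODUCTIONS:
        if production_schedules is not None and name in production_schedules:
            arr = np.asarray(production_schedules[name], dtype=float)
            if arr.shape != (n_points,):
                raise DimensionError(
                    f"schedule {name} must have {n_points} values, got {arr.shape}"
                )
            if np.any(arr < 0):
                raise InvalidParameterError(f"schedule {name} has negative rates")
        else:
            arr = np.full(n_points, params[name])
        schedules[name] = arr

    p = params
    x_topology = variant in _X_TOPOLOGY_VARIANTS

    ix = state_index
    i_shr_v = ix[(CellType.VASC, Species.SHR)]
    i_wox_v = ix[(CellType.VASC, Species.WOX5)]
    i_shr_q = ix[(CellType.QC, Species.SHR)]
    i_scr_q = ix[(CellType.QC, Species.SCR)]
    i_wox_q = ix[(CellType.QC, Species.WOX5)]
    i_an3_q = ix[(CellType.QC, Species.AN3)]
    i_ssc_q = ix[(CellType.QC, Species.SSC)]
    i_shr_c = ix[(CellType.CEI, Species.SHR)]
    i_scr_c = ix[(CellType.CEI, Species.SCR)]
    i_wox_c = ix[(CellType.CEI, Species.WOX5)]
    i_an3_c = ix[(CellType.CEI, Species.AN3)]
    i_ssc_c = ix[(CellType.CEI, Species.SSC)]
    i_cyc_c = ix[(CellType.CEI, Species.CYCD6)]
    i_x_c = ix.get((CellType.CEI, Species.X))
    i_shr_e = ix[(CellType.ENDO, Species.SHR)]
    i_scr_e = ix[(CellType.ENDO, Species.SCR)]
    i_an3_e = ix[(CellType.ENDO, Species.AN3)]
    i_ssc_e = ix[(CellType.ENDO, Species.SSC)]

    n_states = len(state_index)

    # Hoist parameters out of the mapping: the rhs runs inside solver loops.
    k1_qc, k2_qc, k2_cei, k2_endo = p["k1_qc"], p["k2_qc"], p["k2_cei"], p["k2_endo"]
    k3_qc, k3_cei, k3_endo = p["k3_qc"], p["k3_cei"], p["k3_endo"]
    k4_vasc, k5_cei = p["k4_vasc"], p["k5_cei"]
    d1_vasc, d1_qc, d1_cei = p["d1_vasc"], p["d1_qc"], p["d1_cei"]
    d2_qc, d2_cei, d2_endo = p["d2_qc"], p["d2_cei"], p["d2_endo"]
    d3_qc, d3_cei, d3_endo = p["d3_qc"], p["d3_cei"], p["d3_endo"]
    d4_vasc, d4_qc, d4_cei, d4_endo = p["d4_vasc"], p["d4_qc"], p["d4_cei"], p["d4_endo"]
    d5_cei = p["d5_cei"]
    a_qc, a_cei, a_endo = p["a_qc"], p["a_cei"], p["a_endo"]
    b_qc, b_cei = p["b_qc"], p["b_cei"]
    kon_qc, kon_cei, kon_endo = p["kon_qc"], p["kon_cei"], p["kon_endo"]
    dssc_qc, dssc_cei, dssc_endo = p["dssc_qc"], p["dssc_cei"], p["dssc_endo"]
    K_wox5_shr, n_wox5_shr = p["K_wox5_shr"], p["n_wox5_shr"]
    K_scr_qc, K_scr_cei, K_scr_endo = p["K_scr_qc"], p["K_scr_cei"], p["K_scr_endo"]
    K_D2_qc, K_D2_cei, K_D2_endo = p["K_D2_qc"], p["K_D2_cei"], p["K_D2_endo"]
    K_an3_qc, K_an3_cei, K_an3_endo = p["K_an3_qc"], p["K_an3_cei"], p["K_an3_endo"]
    K_ssc_cycd6 = p["K_ssc_cycd6"]
    n_scr_auto, n_ssc_scr = p["n_scr_auto"], p["n_ssc_scr"]
    n_an3_scr, n_ssc_cycd6 = p["n_an3_scr"], p["n_ssc_cycd6"]
    if x_topology:
        k6_cei, d6_cei = p["k6_cei"], p["d6_cei"]
        K_an3_x, K_x_cycd6 = p["K_an3_x"], p["K_x_cycd6"]
        n_an3_x, n_x_cycd6 = p["n_an3_x"], p["n_x_cycd6"]

    s_k1_qc = schedules["k1_qc"]
    s_k2_qc = schedules["k2_qc"]
    s_k2_cei = schedules["k2_cei"]
    s_k2_endo = schedules["k2_endo"]
    t0 = SCHEDULE_GRID[0]
    i_max = n_points - 1

    def _hill(x, K, n):
        # internal fast path: states may carry tiny negative solver noise
        if x <= 0.0:
            return 0.0
        xn = (x / K) ** n
        return xn / (1.0 + xn)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        if len(y) != n_states:
            raise DimensionError(
                f"state vector has length {len(y)}, model has {n_states} states"
            )
        si = int((t - t0) // 8.0)
        if si < 0:
            si = 0
        elif si > i_max:
            si = i_max

        dy = np.empty(n_states)

        shr_v, wox_v = y[i_shr_v], y[i_wox_v]
        shr_q, scr_q, wox_q, an3_q, ssc_q = (
            y[i_shr_q], y[i_scr_q], y[i_wox_q], y[i_an3_q], y[i_ssc_q],
        )
        shr_c, scr_c, wox_c, an3_c, ssc_c, cyc_c = (
            y[i_shr_c], y[i_scr_c], y[i_wox_c], y[i_an3_c], y[i_ssc_c], y[i_cyc_c],
        )
        shr_e, scr_e, an3_e, ssc_e = y[i_shr_e], y[i_scr_e], y[i_an3_e], y[i_ssc_e]

        # vasculature
        dy[i_shr_v] = (
            k4_vasc * (1.0 - _hill(wox_v, K_wox5_shr, n_wox5_shr))
            - (d4_vasc + a_qc + a_cei + a_endo) * shr_v
        )
        dy[i_wox_v] = b_qc * wox_q - d1_vasc * wox_v

        # quiescent center
        cplx_q = kon_qc * shr_q * scr_q
        dy[i_shr_q] = a_qc * shr_v - d4_qc * shr_q - cplx_q
        dy[i_scr_q] = (
            k3_qc
            * (
                _hill(scr_q, K_scr_qc, n_scr_auto)
                + _hill(ssc_q, K_D2_qc, n_ssc_scr)
                + _hill(an3_q, K_an3_qc, n_an3_scr)
            )
            - d3_qc * scr_q
            - cplx_q
        )
        dy[i_wox_q] = s_k1_qc[si] - (d1_qc + b_qc + b_cei) * wox_q
        dy[i_an3_q] = s_k2_qc[si] - d2_qc * an3_q
        dy[i_ssc_q] = cplx_q - dssc_qc * ssc_q

        # cortex endodermis initial
        cplx_c = kon_cei * shr_c * scr_c
        dy[i_shr_c] = a_cei * shr_v - d4_cei * shr_c - cplx_c
        scr_drive_c = _hill(scr_c, K_scr_cei, n_scr_auto) + _hill(
            ssc_c, K_D2_cei, n_ssc_scr
        )
        if not x_topology:
            scr_drive_c += _hill(an3_c, K_an3_cei, n_an3_scr)
        dy[i_scr_c] = k3_cei * scr_drive_c - d3_cei * scr_c - cplx_c
        dy[i_wox_c] = b_cei * wox_q - d1_cei * wox_c
        dy[i_an3_c] = s_k2_cei[si] - d2_cei * an3_c
        dy[i_ssc_c] = cplx_c - dssc_cei * ssc_c
        cyc_prod = k5_cei * _hill(ssc_c, K_ssc_cycd6, n_ssc_cycd6)
        if x_topology:
            x_c = y[i_x_c]
            cyc_prod *= 1.0 - _hill(x_c, K_x_cycd6, n_x_cycd6)
            dy[i_x_c] = k6_cei * _hill(an3_c, K_an3_x, n_an3_x) - d6_cei * x_c
        dy[i_cyc_c] = cyc_prod - d5_cei * cyc_c

        # endodermis
        cplx_e = kon_endo * shr_e * scr_e
        dy[i_shr_e] = a_endo * shr_v - d4_endo * shr_e - cplx_e
        scr_drive_e = _hill(scr_e, K_scr_endo, n_scr_auto) + _hill(
            ssc_e, K_D2_endo, n_ssc_scr
        )
        if not x_topology:
            scr_drive_e += _hill(an3_e, K_an3_endo, n_an3_scr)
        dy[i_scr_e] = k3_endo * scr_drive_e - d3_endo * scr_e - cplx_e
        dy[i_an3_e] = s_k2_endo[si] - d2_endo * an3_e
        dy[i_ssc_e] = cplx_e - dssc_endo * ssc_e

        return dy

    return RegulatoryModel(
        variant=variant,
        params=params,
        roster=roster,
        state_index=state_index,
        production_schedules=schedules,
        rhs=rhs,
    )


def evaluate_rhs(model: RegulatoryModel, state: np.ndarray, t: float) -> np.ndarray:
    """Evaluate the derivative vector (FPKM/h) at ``state`` and time ``t``.

    Times outside the schedule window [96, 144] h are clamped to the nearest
    scheduled interval.  Movement terms are mass-conserving by construction:
    summed over agents they cancel for each mobile species.
    """
    state = np.asarray(state, dtype=float)
    if state.ndim != 1 or len(state) != model.n_states:
        raise DimensionError(
            f"state vector has shape {state.shape}, model has {model.n_states} states"
        )
    t = float(t)
    if t < SCHEDULE_GRID[0] or t > SCHEDULE_GRID[-1]:
        warnings.warn(
            f"t={t} h outside the schedule window "
            f"[{SCHEDULE_GRID[0]}, {SCHEDULE_GRID[-1]}]; clamping to the nearest "
            "scheduled interval",
            stacklevel=2,
        )
    return model.rhs(t, state)
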