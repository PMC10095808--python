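"""Synthetic inputs emulating cell-sorted transcriptomic data products.

Everything the pipeline consumes can be generated here under a fixed seed:
5-day cell-type FPKM tables, stem-cell-niche fold-change time courses on
the 8-h grid (smooth two-bump curves anchored at 1.0 at 5 days), forward
simulated ground-truth time courses for parameter-recovery experiments and
random directed gene networks for the node statistics.  Noise, where
requested, is multiplicative log-normal — FPKM values are positive with
roughly scale-proportional spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import CANONICAL_FPKM_5D, default_parameter_set
from .errors import ConfigurationError
from .fitting import (
    TimeCourse,
    extrapolate_timecourse,
    fit_production_schedule,
    initial_state_from_timecourse,
)
from .model import SCHEDULE_GRID, RegulatoryModel, build_model
from .network import GeneNetwork
from .simulate import simulate

__all__ = [
    "SyntheticSpec",
    "generate_fpkm_and_foldchanges",
    "generate_ground_truth_run",
    "generate_toy_network",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Reproducible recipe for synthetic tables.

    ``noise_sigma`` is the standard deviation of the multiplicative
    log-normal noise (0 = noise-free); fold-change curves are sums of two
    Gaussian bumps with seeded centres and amplitudes, renormalised to 1 at
    the 120-h anchor.  ``pairs`` defaults to the (species, cell type)
    combinations of the wild-type roster that correspond to measured genes.
    """

    seed: int = 0
    noise_sigma: float = 0.1
    fpkm_range: tuple[float, float] = (5.0, 80.0)
    pairs: tuple[tuple[str, str], ...] = tuple(sorted(CANONICAL_FPKM_5D))
    bump_center_early: tuple[float, float] = (100.0, 112.0)
    bump_center_late: tuple[float, float] = (128.0, 140.0)
    bump_amplitude: tuple[float, float] = (0.3, 1.0)
    bump_width_h: float = 6.0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _two_bump_curve(t: np.ndarray, c1, c2, a1, a2, width) -> np.ndarray:
    base = (
        1.0
        + a1 * np.exp(-0.5 * ((t - c1) / width) ** 2)
        + a2 * np.exp(-0.5 * ((t - c2) / width) ** 2)
    )
    anchor = base[np.argmin(np.abs(t - 120.0))]
    return base / anchor


def generate_fpkm_and_foldchanges(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded 5-day FPKM table and fold-change time-course table.

    Returns tidy frames ``species, cell_type, fpkm`` and
    ``species, time_h, fold_change`` on the exact grid the fitting stage
    expects; the fold-change column at 120 h is exactly 1.
    """
    rng = spec.rng(stream=1)
    lo, hi = spec.fpkm_range
    fpkm_rows = []
    for s, c in spec.pairs:
        v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        if spec.noise_sigma > 0:
            v *= float(np.exp(rng.normal(0.0, spec.noise_sigma)))
        fpkm_rows.append({"species": s, "cell_type": c, "fpkm": v})

    species = sorted({s for s, _ in spec.pairs})
    fc_rows = []
    for s in species:
        c1 = rng.uniform(*spec.bump_center_early)
        c2 = rng.uniform(*spec.bump_center_late)
        a1 = rng.uniform(*spec.bump_amplitude)
        a2 = rng.uniform(*spec.bump_amplitude)
        curve = _two_bump_curve(SCHEDULE_GRID, c1, c2, a1, a2, spec.bump_width_h)
        if spec.noise_sigma > 0:
            curve = curve * np.exp(rng.normal(0.0, spec.noise_sigma, curve.shape))
            curve = curve / curve[np.argmin(np.abs(SCHEDULE_GRID - 120.0))]
        for t, v in zip(SCHEDULE_GRID, curve):
            fc_rows.append({"species": s, "time_h": float(t), "fold_change": float(v)})
    return pd.DataFrame(fpkm_rows), pd.DataFrame(fc_rows)


def generate_ground_truth_run(
    spec: SyntheticSpec, variant: str = "wt"
) -> tuple[RegulatoryModel, TimeCourse]:
    """Forward-simulated time course at known parameters, plus noise.

    The returned model carries the ground-truth parameter set and fitted
    production schedules; the time course samples an event-free forward
    simulation on the 8-h grid, perturbed by the spec's multiplicative
    log-normal noise.  With ``noise_sigma=0`` the objective at the truth is
    zero up to solver tolerance.
    """
    params = default_parameter_set()
    data0 = extrapolate_timecourse(
        CANONICAL_FPKM_5D,
        _foldchange_map(spec),
    )
    base = build_model(variant, params)
    schedules = {}
    schedules.update(fit_production_schedule(base, "WOX5", data0))
    schedules.update(fit_production_schedule(base, "AN3", data0))
    model = build_model(variant, params, schedules)
    init = initial_state_from_timecourse(model, data0, 96.0)
    traj = simulate(model, init, (96.0, 144.0), rules=None)

    rng = spec.rng(stream=2)
    rows = []
    for (ct, sp), j in model.state_index.items():
        if sp.value in ("SSC", "X"):
            continue
        sim = np.interp(SCHEDULE_GRID, traj.times, traj.states[:, j])
        noisy = sim * np.exp(rng.normal(0.0, spec.noise_sigma, sim.shape))
        for t, v in zip(SCHEDULE_GRID, noisy):
            rows.append(
                {
                    "species": sp.value,
                    "cell_type": ct.value,
                    "time_h": float(t),
                    "fpkm": float(v),
                }
            )
    return model, TimeCourse(pd.DataFrame(rows), provenance="synthetic")


def _foldchange_map(spec: SyntheticSpec) -> dict[tuple[str, float], float]:
    rng = spec.rng(stream=3)
    out = {}
    for s in sorted({sp for sp, _ in spec.pairs}):
        c1 = rng.uniform(*spec.bump_center_early)
        c2 = rng.uniform(*spec.bump_center_late)
        a1 = rng.uniform(*spec.bump_amplitude)
        a2 = rng.uniform(*spec.bump_amplitude)
        curve = _two_bump_curve(SCHEDULE_GRID, c1, c2, a1, a2, spec.bump_width_h)
        for t, v in zip(SCHEDULE_GRID, curve):
            out[(s, float(t))] = float(v)
    return out


def generate_toy_network(
    n_nodes: int,
    edge_density: float,
    seed: int | None = None,
    n_end_nodes: int | None = None,
) -> GeneNetwork:
    """Reproducible random directed network for the node statistics.

    Each ordered pair (no self-loops) receives an edge with probability
    ``edge_density``.  With ``n_end_nodes`` given, the last that many nodes
    are stripped of outgoing edges and every other node is guaranteed at
    least one, fixing the end-node proportion exactly.
    """
    if n_nodes < 1:
        raise ConfigurationError("n_nodes must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ConfigurationError("edge_density must be in [0, 1]")
    if n_end_nodes is not None and not 0 <= n_end_nodes <= n_nodes:
        raise ConfigurationError("n_end_nodes must be in [0, n_nodes]")
    rng = np.random.default_rng(seed)
    names = [f"g{i:02d}" for i in range(n_nodes)]
    edges = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < edge_density:
                sign = ("activation", "repression", "undetermined")[
                    int(rng.integers(3))
                ]
                edges.append((names[i], sign, names[j]))
    if n_end_nodes is not None and n_nodes > 1:
        sinks = set(names[n_nodes - n_end_nodes :])
        edges = [e for e in edges if e[0] not in sinks]
        if n_end_nodes < n_nodes:
            sources = names[: n_nodes - n_end_nodes]
            with_out = {e[0] for e in edges}
            for s in sources:
                if s not in with_out:
                    targets = [n for n in names if n != s]
                    t = targets[int(rng.integers(len(targets)))]
                    edges.append((s, "activation", t))
    elif edge_density < 1.0 and n_nodes > 1:
        with_out = {e[0] for e in edges}
        if len(with_out) == n_nodes:  # force at least one end-node
            edges = [e for e in edges if e[0] != names[-1]]
    return GeneNetwork.from_edges(edges, nodes=names)
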