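"""Variance-based global sensitivity analysis (total Sobol effect).

Total-effect indices are estimated with Saltelli's radial sampling scheme
and Jansen's estimator: with base matrices A and B (n x k) and AB_i equal
to A with column i taken from B,

    ST_i = [ (1/2n) sum_j (f(A_j) - f(AB_i,j))^2 ] / Var(f)

where Var(f) is taken over the pooled A and B evaluations.  The model
output is vector-valued (one scalar summary per ODE state), so an index is
obtained per (replicate, state, parameter).  Within each replicate and
state the indices are rescaled to [0, 1], averaged across states, and the
replicate averages are averaged again into a single score per parameter.
Parameters scoring significantly above the lowest-scoring parameter
(one-sided two-sample Student's t-test) form the sensitive set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .model import RegulatoryModel, build_model
from .simulate import simulate

__all__ = [
    "SobolResult",
    "total_effect_indices",
    "sobol_total_effect",
    "select_sensitive",
]


@dataclass(frozen=True)
class SobolResult:
    """Raw, rescaled and aggregated total-effect indices.

    ``raw`` has shape (n_replicates, n_outputs, n_params); ``rescaled`` is
    min-max rescaled within each (replicate, output) slice; ``per_param``
    (n_replicates x n_params) averages the rescaled indices across outputs;
    ``score`` averages ``per_param`` across replicates.
    """

    param_names: tuple[str, ...]
    raw: np.ndarray
    rescaled: np.ndarray
    per_param: np.ndarray
    score: np.ndarray
    n_samples: int
    seed: int | None

    @property
    def n_replicates(self) -> int:
        return self.raw.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.raw.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table ``replicate, ode, parameter, index`` of the raw tensor."""
        reps, odes, params = self.raw.shape
        rows = []
        for r in range(reps):
            for o in range(odes):
                for j in range(params):
                    rows.append(
                        {
                            "replicate": r,
                            "ode": o,
                            "parameter": self.param_names[j],
                            "index": self.raw[r, o, j],
                        }
                    )
        return pd.DataFrame(rows)

    def score_frame(self, selected=()) -> pd.DataFrame:
        sel = set(selected)
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "score": self.score,
                "selected": [n in sel for n in self.param_names],
            }
        ).sort_values("score", ascending=False, ignore_index=True)


def total_effect_indices(
    func,
    bounds: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Jansen total-effect estimator for a (possibly vector-valued) function.

    ``func`` maps a parameter vector (natural scale) to a scalar or 1-D
    output array; ``bounds`` is (k, 2) with uniform sampling between the
    columns.  Zero-width dimensions get index 0 with a warning.  Returns an
    array of shape (k, n_outputs).
    """
    bounds = np.asarray(bounds, dtype=float)
    k = bounds.shape[0]
    widths = bounds[:, 1] - bounds[:, 0]
    degenerate = widths <= 0
    if degenerate.any():
        names = np.nonzero(degenerate)[0]
        warnings.warn(
            f"zero-width sampling range for parameter(s) {list(names)}; "
            "their total-effect index is defined as 0",
            stacklevel=2,
        )

    def draw(u):
        return bounds[:, 0] + u * widths

    ua = rng.random((n_samples, k))
    ub = rng.random((n_samples, k))
    y_a = np.atleast_2d([np.atleast_1d(func(draw(u))) for u in ua])
    y_b = np.atleast_2d([np.atleast_1d(func(draw(u))) for u in ub])
    m = y_a.shape[1]
    var = np.var(np.vstack([y_a, y_b]), axis=0, ddof=0)
    st = np.zeros((k, m))
    for i in range(k):
        if degenerate[i]:
            continue
        u_ab = ua.copy()
        u_ab[:, i] = ub[:, i]
        y_ab = np.atleast_2d([np.atleast_1d(func(draw(u))) for u in u_ab])
        num = 0.5 * np.mean((y_a - y_ab) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            st[i] = np.where(var > 0, num / var, 0.0)
    return st


def _time_average_summary(traj) -> np.ndarray:
    """Default per-ODE scalar: the time average of each state over the window."""
    return np.trapezoid(traj.states, traj.times, axis=0) / (
        traj.times[-1] - traj.times[0]
    )


def sobol_total_effect(
    model: RegulatoryModel,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_samples: int = 150,
    n_reps: int = 10,
    output_summary=None,
    seed: int | None = None,
    init: np.ndarray | None = None,
    t_span=(96.0, 144.0),
    rtol: float = 1e-5,
    atol: float = 1e-8,
) -> SobolResult:
    """Total Sobol effect of model parameters on every ODE state.

    For each of ``n_reps`` technical replicates, ``n_samples`` Monte Carlo
    base samples are drawn per parameter (log-uniform within ``ranges``,
    default a factor of 10 either side of the nominal value for every
    registry parameter) and Jansen total-effect indices are computed for
    each state's scalar summary (default: its time average over the window;
    event detection is off, as division discontinuities would break the
    variance decomposition).  With the wild-type model this yields
    ``n_reps x 17`` indices per parameter.
    """
    if ranges is None:
        ranges = {
            name: (v / 10.0, v * 10.0)
            for name, v in model.params.to_dict().items()
            if v > 0
        }
    # canonical (sorted) parameter order: results are independent of the
    # order the caller listed the ranges in
    names = tuple(sorted(ranges))
    if not names:
        raise ConfigurationError("ranges must name at least one parameter")
    log_bounds = np.array(
        [
            (np.log10(lo), np.log10(hi)) if lo > 0 and hi > 0 else (0.0, 0.0)
            for lo, hi in (ranges[n] for n in names)
        ]
    )
    if init is None:
        init = np.zeros(model.n_states)

    def func(x_log):
        values = dict(zip(names, 10.0**x_log))
        params = model.params.replace(**values)
        candidate = build_model(model.variant, params, model.production_schedules)
        traj = simulate(
            candidate, init, t_span, rules=None,
            rtol=rtol, atol=atol, dt_out=2.0, state_cap=1e12,
        )
        if output_summary is not None:
            return np.atleast_1d(output_summary(traj))
        return _time_average_summary(traj)

    rng = np.random.default_rng(seed)
    raws = []
    for _ in range(n_reps):
        st = total_effect_indices(func, log_bounds, n_samples, rng)  # (k, m)
        raws.append(st.T)  # (m, k)
    raw = np.array(raws)  # (reps, m, k)

    lo = raw.min(axis=2, keepdims=True)
    hi = raw.max(axis=2, keepdims=True)
    span = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        rescaled = np.where(span > 0, (raw - lo) / span, 0.0)
    per_param = rescaled.mean(axis=1)  # (reps, k)
    score = per_param.mean(axis=0)
    return SobolResult(
        param_names=names,
        raw=raw,
        rescaled=rescaled,
        per_param=per_param,
        score=score,
        n_samples=n_samples,
        seed=seed,
    )


def select_sensitive(result: SobolResult, alpha: float = 0.01) -> list[str]:
    """Parameters scoring significantly above the lowest-scoring parameter.

    One-sided two-sample Student's t-test (equal variances) of each
    parameter's per-replicate scores against the reference (lowest score),
    at significance ``alpha``; the result is ordered by score descending.
    """
    if result.n_replicates < 2:
        raise ConfigurationError("need at least 2 replicates for the t-test")
    ref = int(np.argmin(result.score))
    ref_scores = result.per_param[:, ref]
    selected = []
    for j, name in enumerate(result.param_names):
        if j == ref:
            continue
        scores = result.per_param[:, j]
        if np.allclose(scores, ref_scores):
            continue
        t = stats.ttest_ind(scores, ref_scores, equal_var=True, alternative="greater")
        if t.pvalue < alpha:
            selected.append((result.score[j], name))
    return [name for _, name in sorted(selected, key=lambda p: -p[0])]
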