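"""Rank model parameters by total Sobol effect.

Samples parameters log-uniformly around their nominal values, computes
Jansen total-effect indices for each of the 17 ODE states, rescales and
averages them, and selects parameters scoring significantly above the
lowest-ranked one (Student's t-test across technical replicates).

This demo varies a handful of parameters at reduced sampling so it finishes
in ~20 s; raise ``n_samples``/``n_reps`` (150 x 10 is the full resolution)
and widen ``ranges`` for a production run.
"""

from rootniche import select_sensitive, sobol_total_effect
from rootniche.defaults import default_wt_scenario

scenario = default_wt_scenario()
p = scenario.model.params
ranges = {
    name: (p[name] / 10.0, p[name] * 10.0)
    for name in ("k4_vasc", "d3_qc", "kon_cei", "K_D2_qc")
}

result = sobol_total_effect(
    scenario.model, ranges=ranges, n_samples=30, n_reps=4, seed=0,
    init=scenario.init, rtol=1e-4, atol=1e-7,
)
selected = select_sensitive(result, alpha=0.01)

print(f"indices per parameter: {result.n_replicates} replicates x "
      f"{result.n_outputs} states = {result.n_replicates * result.n_outputs}")
print("\nparameter scores (rescaled total effect, averaged):")
for row in result.score_frame(selected).itertuples(index=False):
    mark = "*" if row.selected else " "
    print(f"  {mark} {row.parameter:<10} {row.score:.3f}")
print("\n* significantly above the lowest-scoring parameter (p < .01): these "
      "are the parameters worth estimating from data; the rest can be held "
      "at reference values.")
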