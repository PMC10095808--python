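"""Estimate sensitive parameters by simulated annealing from LHS starts.

Generates a noise-free synthetic time course from known ground-truth
parameters, then re-estimates two of them: independent annealing runs start
from a Latin-hypercube sample over bounds two orders of magnitude either
side of nominal, and the run average is the reported estimate.

Four runs keep this demo under a minute; the reference protocol uses 40.
"""

import numpy as np

from rootniche import estimate_parameters, initial_state_from_timecourse
from rootniche.synthetic import SyntheticSpec, generate_ground_truth_run

spec = SyntheticSpec(seed=3, noise_sigma=0.0)
model, data = generate_ground_truth_run(spec)
init = initial_state_from_timecourse(model, data, 96.0)

names = ["k4_vasc", "d3_qc"]
truth = np.array([model.params[n] for n in names])
estimate = estimate_parameters(
    model, data, names, n_runs=4, seed=0, init=init,
    n_temps=30, iters_per_temp=15, rtol=1e-4, atol=1e-7,
)

print(f"{'parameter':<10} {'truth':>8} {'estimate':>9} {'rel err':>8}")
for j, name in enumerate(names):
    rel = abs(estimate.mean[j] - truth[j]) / truth[j]
    print(f"{name:<10} {truth[j]:8.3f} {estimate.mean[j]:9.3f} {rel:7.1%}")
print(f"\nper-run best objectives (SSE, FPKM^2): "
      f"{np.round(estimate.objectives, 2)}")
print("The mean across runs recovers the truth to a few percent on "
      "noise-free data; residual objective reflects solver tolerance and "
      "annealing budget.")
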