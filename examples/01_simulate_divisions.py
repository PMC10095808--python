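"""Simulate wild-type stem-cell divisions in the root niche.

Builds the canonical wild-type configuration (extrapolated time courses,
fitted WOX5/AN3 production schedules, calibrated division thresholds), runs
the hybrid ODE/agent simulation from 4 to 6 days post-germination and prints
the located division events.
"""

from rootniche import simulate
from rootniche.defaults import default_wt_scenario

scenario = default_wt_scenario()
print(f"model: {scenario.model.variant}, {scenario.model.n_states} ODE states")
print(
    "division rules: CYCD6;1 threshold "
    f"{scenario.rules.theta_cycd6:.1f} FPKM (CEI), SHR/SCR-complex threshold "
    f"{scenario.rules.theta_ssc_qc:.1f} with WOX5 below "
    f"{scenario.rules.theta_wox5_qc:.1f} FPKM (QC)"
)

traj = simulate(scenario.model, scenario.init, (96.0, 144.0), scenario.rules)

print("\ndivision events:")
for event in traj.events:
    days, hours = divmod(event.time, 24.0)
    print(f"  {event.agent.value:>4} divides at {event.time:6.2f} h "
          f"({int(days)} d {hours:4.1f} h)")

print(
    "\nEach event is an upward threshold crossing of the trigger protein; "
    "the dividing cell's protein abundances are halved and integration "
    "restarts.  The CEI divides twice (early and late trough of WOX5) and "
    "the QC divides once, in between — divisions of the two cell types are "
    "interdependent through the mobile proteins SHR and WOX5."
)
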