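# Methods

## Model structure

The niche is modelled as four communicating agents — vascular initials
(VASC), quiescent center (QC), cortex endodermis initial (CEI), endodermis
(ENDO) — with one ODE per (protein, cell) pair.  The wild-type roster has
17 states: VASC {SHR, WOX5}; QC {SHR, SCR, WOX5, AN3, SSC}; CEI {SHR, SCR,
WOX5, AN3, SSC, CYCD6;1}; ENDO {SHR, SCR, AN3, SSC}.  The revised
(repressor-X) topology adds X in the CEI (18 states), multiplies CYCD6;1
production by a Hill repression in X, and removes the AN3 activation of SCR
in the CEI and endodermis.  SHR and SCR monomer and dimer are pooled into
one variable per cell, and the SHR/SCR complex (SSC) forms by irreversible
mass action `kon·SHR·SCR` with its own linear decay; no dissociation term
is included — the simplest scheme consistent with mass-action formation,
and one less parameter per cell.  Every protein decays linearly.

Movement is gradient-independent linear efflux with per-target rates: SHR
leaves the vasculature at `a_qc + a_cei + a_endo` and arrives in the QC,
CEI and endodermis at the matching rates; WOX5 leaves the QC at
`b_qc + b_cei` toward the vasculature and CEI.  Summed over agents the
movement terms cancel exactly per mobile species (mass conservation), which
is enforced by construction and property-tested.  WOX5 in the CEI is a
passive pool (influx and decay only); it has no regulatory target there in
the wild-type equations.

SCR production is a single maximal rate `k3_cell` multiplying the *sum* of
three Hill activations (autoactivation, SSC, AN3): each input alone is
sufficient to induce SCR, and an additive combination is the simplest
OR-like form with that property.  Sharing one Vmax across the three terms
(rather than one per term) keeps the registry small; the alternative is a
reparametrisation the data used here could not distinguish.  All Hill
exponents default to 2 (cooperative but shallow) and are exposed as
ordinary parameters.

WOX5 (QC) and AN3 (QC, CEI, ENDO) production is time-dependent: a
piecewise-constant rate per 8-h interval of the 96–144 h grid,
right-continuous and clamped outside the window.  Because each scheduled
species obeys a scalar linear ODE decoupled from the rest of the system,
the rate that matches the data at the interval endpoints is available in
closed form and is clipped at zero when negative.

Units: abundances are FPKM (the fitting data are FPKM), time is hours
post-germination, so productions are FPKM/h, first-order rates 1/h and
complex formation 1/(FPKM·h).  Protein abundance and transcript FPKM are
deliberately identified — transcriptional regulation and protein expression
are collapsed into one equation per species.

## Division rules and event handling

Divisions are threshold events: the QC fires when SSC crosses its threshold
upward while WOX5 is below its bound (high complex, low WOX5); the CEI
fires when CYCD6;1 crosses its threshold upward.  "Capacity doubling" at
division is represented solely by halving every abundance in the dividing
agent — concentrations are the only modelled quantities, and no division
plane or geometry is attempted.  Events latch: after a firing, or a gated
crossing that does not fire (WOX5 too high; refractory window active), the
trigger must fall a small hysteresis band (10⁻⁶ relative) below threshold
before it can fire again.  The hysteresis prevents chattering and, because
a restart begins exactly at the located root, keeps a gated crossing from
retriggering at the same instant.  The CEI refractory window is 16 h in the
repressor-X model and 0 in the wild type, where it was not needed; whether
the QC also carries one is left configurable (default 0).

Integration uses SciPy's adaptive explicit Runge–Kutta 4(5) with rtol 1e-6
and atol 1e-9 by default; events are located by the solver's root finder
(accuracy far below the 1e-3 h the rules require) and integration restarts
from the halved state.  If two triggers cross in the same step only the
earlier fires; the other re-fires on its next crossing.  An optional state
cap (used by the fitting objective at 1e9 FPKM) aborts diverging candidate
integrations with a failure signal instead of crawling through them.

## Canonical scenario and threshold calibration

No external calibration tables ship with the package, so
`rootniche.defaults` carries its own canonical stand-ins: a full parameter registry (50 wild-type entries plus
6 repressor-X extras), 5-day cell-type FPKM values, and fold-change time
courses anchored at 1.0 at 120 h.  The WOX5 curve has troughs early
(~0.5× at 4 d–4 d 8 h) and late (~0.12× after 5 d 8 h) with full recovery
at 6 d; since WOX5 represses SHR in the vasculature, each trough launches a
wave of SHR, SHR/SCR complex and CYCD6;1 through the niche.  AN3 declines
after 5 days, which in the revised topology lets repressor X decay late and
derepresses CYCD6;1.  Rate constants were chosen once so that the
characteristic response times of the SHR chain (~2–3 h per stage) and the
slower CEI complex/CYCD6;1 stages (~6 h) place the division events in the
expected order (CEI, then QC, then CEI); they are calibration constants of the package's reference
scenario, not measurements.

Division thresholds are calibrated from an event-free wild-type trajectory
(`calibrate_thresholds`): the CYCD6;1 threshold is the centre of the widest
band of levels crossed upward exactly twice; the QC complex threshold is
the topmost band crossed exactly once (the QC divides rarely, on the rise
of its tallest complex peak); the WOX5 bound lies midway between the WOX5
level at that crossing and its window maximum.  The procedure is
deterministic given the trajectory and fails loudly (listing the extrema
found) when no feasible level exists, e.g. on flat or monotone traces.

Under these conditions the hybrid wild-type run divides the CEI at 104.6 h
(4 d 8.6 h) and 138.7 h and the QC at 138.4 h — two CEI divisions and one
QC division with the QC strictly between, the structural signature of the
reference simulation.  The revised topology with its six re-estimated
parameters shortens the CEI inter-division interval from 34.0 h to 28.5 h
under the 16-h refractory rule.  Both firings are tied to the two
WOX5-trough-driven SHR/SCR waves, and the 120-h anchor pins WOX5 high at
5 days, so the second wave cannot begin earlier; this bounds how far the
interval can shrink and compresses the gap between the QC division and the
second CEI division relative to the biological timing.

## Mutant simulations

Loss-of-function lines are simulated purely through initial conditions, at
the residual expression measured in the mutants: every WOX5 component
starts at 0.47% of wild type (*wox5*), every AN3 component at 11.88%
(*an3*); the *an3* run uses the repressor-X topology and parameters.  The
*wox5* run shares the wild-type right-hand side — the only difference is
the scaled initial state — and gains at least one extra CEI division before
5 days, because removing WOX5's early repression of SHR accelerates complex
build-up and triggers a division cascade via the QC.  The *an3* run
depletes SCR in QC, CEI and endodermis relative to wild type, structurally:
the revised topology removes the AN3→SCR term in CEI/ENDO and the scaled
AN3 weakens the QC term.

## Sensitivity analysis

Total Sobol effect indices are estimated with Saltelli radial sampling and
Jansen's estimator: with base matrices A, B (n×k) and AB_i (A with column i
from B), `ST_i = mean[(f(A) − f(AB_i))²] / (2·Var f)`, at n×(k+2) model
evaluations per replicate.  Parameters are sampled log-uniformly, by
default over a factor of 10 either side of nominal.  The model output is
vector-valued — one scalar per ODE state, by default its time average over
the window, computed on event-free runs because division discontinuities
would break the variance decomposition.  Within each replicate and state
the indices are min–max rescaled to [0, 1], averaged across the 17 states,
and replicate averages are averaged into one score per parameter; with 10
replicates this yields 170 indices per parameter.  Parameters whose
per-replicate scores exceed the lowest-scoring parameter's by a one-sided
two-sample Student's t-test (equal variances, p < .01) form the sensitive
set.  Internally parameters are processed in sorted-name order, so results
are independent of the order the caller lists them.

## Parameter estimation

Sensitive parameters are estimated by simulated annealing in log10 space:
one Latin-hypercube sample over the bounds (default ×/÷100 around nominal)
provides the starting points, each start is refined by an independent
annealing run, and the arithmetic mean across runs is the reported
estimate.  The objective is the unweighted sum of squared FPKM errors over
every grid cell present in the data, with a large finite sentinel (1e12)
returned on solver failure so the search never crashes.  The annealer uses
geometric cooling (0.9 per level, 40 levels, 25 proposals per level by
default) with Gaussian proposals whose step shrinks geometrically alongside
the temperature and reflection at the bounds; each level restarts from the
incumbent best.  These defaults recover two-parameter synthetic truths
within a few percent on noise-free data at roughly a thousand objective
evaluations per run; harder problems should raise the budget, and all knobs
are arguments.  Non-estimated parameters are held at their reference
values.

## Synthetic data

The generators emulate the downstream products of cell-sorted
transcriptomics: 5-day FPKM tables (log-uniform between 5 and 80 FPKM),
fold-change curves (two seeded Gaussian bumps on the 8-h grid, renormalised
to 1 at 120 h) and forward-simulated ground-truth time courses.  Noise is
multiplicative log-normal (σ = 0.1 by default): FPKM values are positive
with roughly scale-proportional spread.  What the generators do *not*
emulate: read-level sampling noise, dropout, batch structure, or any
mismatch between transcript and protein dynamics — so passing recovery
tests show the estimator works when the model family is correct, not that
the model is identifiable from real sequencing data.  Toy networks draw
each ordered node pair independently at a given density; a variant pins the
end-node count exactly (the 20-node/4-end-node fixture mirrors the shape of
the inferred CEI network, R = 0.20).

## Network statistic

Node weight is `w(i) = 1 + O(i)/max_j O(j)` (1 on edgeless graphs), hence
in [1, 2] with the top outdegree at 2.  Impact is
`ASPL(i)·Σ_{j∈succ(i)} w(j) + R·Σ_{j∈pred(i)} w(j)`, where ASPL is the mean
directed shortest-path length from i over the nodes it can reach
(unreachable nodes are excluded rather than counted as infinite, keeping
the score finite on DAG-like regulatory networks; a sink has ASPL 0) and R
is the end-node proportion.  The weight and impact formulas are reconstructions: the minimal forms
satisfying every constraint of their verbal description
(range [1, 2], outdegree-proportional weights, ASPL scaling of the outgoing
sum, end-node-proportion scaling of the incoming sum), implemented as a
documented reconstruction and verified against brute-force oracles.  Edge
signs are parsed and carried but do not enter the statistic.  Overlap
enrichment is `fold = k·N/(nA·nB)` with the exact upper-tail
hypergeometric probability `P[X ≥ k]`.

## Numerical choices and limitations

Tolerances: simulation rtol 1e-6/atol 1e-9; sensitivity and estimation use
rtol 1e-4–1e-5 (the objective differences they resolve are far coarser).
Threshold calibration scans 400 candidate levels; ties in the impact table
break lexicographically by node id.  Degenerate inputs are defined, not
guessed: zero-width sensitivity ranges give index 0 with a warning,
all-zero data fit a zero schedule, fewer than two division events give an
empty interval list.

Known limitations: no spatial geometry or division-plane orientation; no
auxin signalling; deterministic dynamics between events (no stochastic
simulation); the canonical scenario is a calibrated stand-in whose division
times carry the structural pattern rather than exact biological clock times;
and the repressor-X interval shortening (34.0 → 28.5 h) is bounded by the
fold-change anchor as described above.
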