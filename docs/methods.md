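# Methods

## Model class and semantics

The engine implements continuous place/transition nets: markings are
nonnegative reals, transitions fire continuously, and the net induces an
ordinary-differential system dm/dt = C·v(m) over the marking vector, with
C the incidence matrix and v the vector of transition rates.

**Rate law.** Mass action with a per-transition rate constant k (default
1): v = k·∏ m_p^w over standard input arcs, kinetic order equal to the arc
weight.  This is the minimal continuous semantics consistent with a
qualitative, connectivity-driven model in which token levels mean relative
activity rather than concentration; k is exposed through the config for
calibration.  Source transitions fire at the constant rate k; sink
transitions drain their inputs.

**Inhibition.** An inhibitory arc (place → transition only; moves no
tokens) suppresses firing.  Exact threshold semantics ("stops firing once
the inhibitor reaches the arc weight") give a discontinuous right-hand
side, which adaptive stiff integrators handle badly, so the default gate is
the smooth decreasing sigmoid g(m, w) = w^h/(w^h + m^h) with steepness
h = 4: half suppression at m = w, near-total suppression a few multiples
above it.  A hard step gate (1 if m < w else 0) is available via
`SimulationSettings(hard_gate=True)` for semantics checks.  The gate is
monotone non-increasing in the inhibitor level, which is what the drug
dose-response behaviour relies on.

**Integration.** LSODA (adaptive, stiff-capable) with rel_tol 1e-6,
abs_tol 1e-9, dense output sampled on a uniform grid (default 201 points
over t_end = 100 dimensionless time units; the models carry no absolute
time calibration, so "time units" are nominal throughout).  Negative
excursions within 100·abs_tol are clipped to zero; anything larger aborts
with an error, because a large negativity indicates a modelling bug rather
than roundoff.  Identical (net, settings) inputs give identical
trajectories.

**Structural analysis.** P-invariants (nonnegative x with xᵀC = 0) are
computed by Farkas/Fourier–Motzkin elimination over exact rational
arithmetic and reduced to a minimal-support generating set, so returned
vectors satisfy the null-space identity exactly.  Every shipped variant
conserves its active/inactive protein pair totals (IRS-1, PI3K, Akt,
GLUT4) and its constant catalysts; trajectory tests verify the weighted
token sums stay constant to 1e-6 under default tolerances (observed drift
is at roundoff, ~1e-15, because catalytic wiring cancels exactly in the
right-hand side).

## The pathway variants

Signalling proteins are active/inactive place pairs linked by
activation/deactivation transitions; "activity" is the active place's
token level.  Catalysts — insulin receptor, PDK1, mTORC2, OGT, OGA,
upstream active kinases — appear on both sides of the transitions they
drive.  PDK1 and mTORC2 are therefore constant-capacity places: purely
catalytic, no source/sink pair, marking constant by construction (a
maintaining source feeding a decay sink at the same steady level would add
dynamics without changing behaviour).  PIP3 consumption during Akt
activation is likewise neglected (PIP3 acts catalytically); PIP3 turnover
is carried by its own production/degradation pair.

The backbone (20 places per variant) covers insulin supply/clearance,
receptor binding into an active complex, the IRS-1 → PI3K → PIP3 → Akt
cascade, GLUT4 internal/membrane translocation, an accumulating
cell-survival readout with first-order decay (so it reaches a steady level
rather than growing without bound — "cell survival" in the adipocyte
context and "cell proliferation" in the cancer context are the same
place), and the hexosamine branch: glucose supply → UDP-GlcNAc → OGT, with
OGT mRNA as a transcribed/decaying source of enzyme and OGA as a constant
antagonist.  The hexosamine flux rate constant (0.02 against a glucose
turnover of 0.5) routes ~4% of glucose consumption into the branch,
matching the few-percent split the pathway is known for; the split is a
fixed rate ratio, not an explicitly modelled branching process.

Variant wiring:

* **normal_adipocyte** — weak O-GlcNAc cycling on IRS-1 and Akt
  (OGT-driven deactivation, OGA-driven reactivation) at rate constants low
  enough to be balanced; insulin stimulation raises IRS-1, Akt, membrane
  GLUT4 and survival above their initial levels.
* **insulin_resistant_adipocyte** — identical topology; OGT transcription
  raised ~8× (yielding ~5× steady OGT after accounting for UDP-GlcNAc
  consumption saturating) and the OGT-driven deactivation constants of
  IRS-1 and Akt raised to 10 and 20.  All four readouts fall below the
  normal variant's.
* **cancer_hyperglycemia** — glucose supply and initial tokens raised 5×,
  which propagates linearly down the hexosamine chain to ~5× OGT — the
  same elevation as the resistant adipocyte, so the differential role of
  OGT (Akt fold < 1 in one, > 1 in the other) is attributable to wiring,
  not dose.  O-GlcNAcylation of Akt is *activating* here (a dedicated
  OGT-catalysed activation transition replaces the deactivating one), and
  OGT additionally appears as a catalyst of the GLUT4 translocation and
  proliferation transitions.  OGT does not touch IRS-1 in this variant (no
  reference data for that interaction), so the IRS-1 column of the disease
  table is reported not-applicable.  Keeping the proliferation transition
  unique matters: Metformin's mechanism is a single inhibitory arc onto
  it.

## Interventions

All interventions return a new net; the base net is immutable.  Default
doses are 10 tokens.

* **shRNA** — new `shrna` place (dose tokens) plus a sink transition
  consuming shRNA and OGT mRNA together (stoichiometric, rate constant
  0.3).  Finite supply: the dose bounds how much mRNA can ever be
  silenced, and with mRNA transcription at 0.05/time unit a dose of 10
  outlasts the 100-unit horizon.
* **BZX** — new `bzx` place plus an irreversible sequestration transition
  consuming BZX and OGT into an inert `ogt_bzx_complex` (rate constant
  0.1, no back-reaction; the complex place has no outgoing arcs at all).
  The incidence column moves ogt + bzx → complex 1:1, so OGT + complex
  inherits OGT's conservation role.  Escalating the dose (10/20/30) leaves
  more free BZX at the end of the horizon and hence a strictly lower
  quasi-steady OGT level.
* **Metformin** — new `metformin` place, a slow maintaining source
  (0.001·dose per time unit), and one inhibitory arc of weight 7 onto the
  proliferation transition.  With dose 10 the smooth gate sits near 0.19,
  i.e. roughly a five-fold suppression of proliferation, and nothing else
  in the net is touched — the OGT trajectory is bit-for-bit within
  integrator tolerance of the control's.

Zero-dose interventions are exact no-ops dynamically (empty drug places
multiply rates by zero; the metformin source is omitted at dose 0 so the
gate stays exactly 1).

## Fold-change reporting

A comparison is two simulations reduced by a readout statistic, default
`mean_tail`: the mean over the last 20% of the grid, which damps residual
transients while tracking the quasi-steady terminal level (all shipped
timescales equilibrate well before 80 time units).  Direction calls use
fold ≥ 1.2 = up, ≤ 0.8 = down, symmetric on the log scale; the underlying
models provide no thresholds, so these are reporting conventions, not
biology.  A baseline below 1e-9 makes the ratio meaningless and raises an
error instead of returning infinity.  Because "n-fold decrease" is
ambiguous between a residual ratio and a reduction factor, summary tables
carry both `fold` (perturbed/baseline) and `reduction_factor`
(baseline/perturbed) and state the convention per row.

## Calibration of the shipped defaults

Exact markings and rate constants for qualitative nets of this kind are
rarely reported, so the shipped `defaults.yaml` is a reconstruction.  Unit
rate constants and
unit arc weights are the default everywhere; the handful of calibrated
constants (Akt operating point 0.34, the OGT-branch gains, the elevated
O-GlcNAcylation constants, the cancer variant's OGT-boost constants 12/25/40,
the intervention mechanism constants and the metformin gate weight 7) were
chosen once, jointly, from steady-state balance calculations so that the
full set of reference fold-change bounds holds simultaneously under a
single configuration — no per-experiment re-tuning.  Measured values under
that one configuration: hyperglycemia OGT 5.0× and proliferation 16.4×;
shRNA residual OGT 0.061; BZX reductions 10.3× (OGT) and 28.0×
(proliferation); Metformin 6.8× proliferation reduction with OGT
unchanged; BZX + Metformin 191× proliferation reduction.  These are
recomputed, not stored, by `scripts/acceptance.py` and the test suite.

## What the synthetic models do and do not show

The generator-style builders (`build_model`, `random_net`) emulate the
*topology-driven* behaviour of a qualitative signalling model: relative
activity changes, direction calls and dose orderings that follow from
connectivity plus mass action.  They do not emulate measured kinetics,
absolute concentrations, cell-to-cell variability, transcriptional
feedback, or pharmacokinetics; the time axis is dimensionless.  Passing
tests therefore establish that the engine integrates these nets correctly
and that the reference qualitative/fold-bound behaviour follows from the
reconstructed wiring under one fixed parameterisation — not that the
parameter values are biologically identified (they are not: many
configurations satisfy the same bounds).

## Numerical and design choices, in brief

* Real-valued arc weights allowed (calibration freedom), default 1;
  duplicate parallel arcs forbidden — use weight instead.
* Read/test arcs not implemented; no discrete token game, no stochastic
  firing, no reachability analysis (out of scope).
* Rates with empty input places are exactly zero (no epsilon leakage);
  0^0 = 1 by convention for zero-weight entries.
* PNML export writes rounded-integer `initialMarking` for foreign-tool
  compatibility and exact real markings, rate constants, transition kinds,
  role tags and inhibitory arc types in a namespaced `toolspecific` block;
  the reader prefers the exact values, ignores unknown tool blocks with a
  warning, and defaults missing rate constants to 1.
* Fixed-step explicit Euler (h = 1e-4) is kept in the code base purely as
  an independent cross-check of the adaptive integrator; it is never used
  for production runs.
* Problem sizes used by the test suite and the acceptance script: the
  three 20-place variants at 101–201 grid points over 100 time units, and
  batches of 50 random nets with at most 6 places/transitions for
  engine-vs-oracle and round-trip checks — sizes at which the whole
  pipeline runs in seconds while exercising every code path.

## Known limitations

* The inhibitory-gate steepness h = 4 is an assumption; exact threshold
  semantics are available but change drug efficacy quantitatively.
* OGA is a constant-capacity antagonist; whether it should be dynamically
  consumed is unresolved and unmodelled.
* The shRNA + BZX combination carries no reference bound of its own (it is
  characterised only qualitatively); its very large reduction factors
  reflect two multiplicative knockdowns of the same target.
* Calibration reproduces bounds, not curves: trajectory shapes are not fit
  to anything.
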