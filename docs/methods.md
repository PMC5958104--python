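# Methods

## The model

`thalnet` simulates the minimal motif of intrathalamic connectivity: two
thalamocortical relay cells (TC1, TC2), each reciprocally connected to its
own thalamic reticular nucleus cell (TRN1, TRN2), with a single electrical
synapse (gap junction) joining the two TRN cells.  Each TC excites its TRN
through an AMPA synapse; each TRN inhibits its TC through a GABA_A synapse;
external transient inputs are AMPAergic events delivered only to the TC
cells.  All four cells are identical single compartments obeying

    C_m dV_i/dt =  Σ_chn  g_chn(t) (E_chn − V_i)          ionic currents
                 + Σ_syn  g_syn(t) (E_syn − V_i)          chemical synapses
                 + g_elec (V_j − V_i)                     gap junction (TRN only)
                 + Σ_in   g_in(t) (E_AMPA − V_i)          external inputs
                 + i_DC

with C_m = 1 µF/cm² and every conductance a density (mS/cm²) on equal-area
compartments, so no membrane-area bookkeeping is needed.  Simulations run
for 250 ms by default.

Channel complement (ḡ in mS/cm², E in mV):

| current                         | gating | ḡ     | E    |
|---------------------------------|--------|-------|------|
| fast transient Na⁺ (NaF)        | m³h    | 60.5  |  50  |
| delayed-rectifier K⁺ (KDR)      | m⁴     | 60    | −100 |
| transient A-type K⁺ (KA)        | m⁴h    | 5     | −100 |
| slowly inactivating K⁺ (K2)     | mh     | 0.5   | −100 |
| anomalous rectifier (H)         | m      | 0.025 | −40  |
| low-threshold Ca²⁺ (CaT)        | m²h    | 0.67  |  125 |
| leak                            | —      | 0.06  | −75  |

The CaT reversal is the fixed ohmic value +125 mV (no GHK/Nernst
computation).  The T current is what makes the cells fire the
burst-of-spikes responses typical of thalamic neurons: a single AMPA event
de-inactivates nothing but rides on the ~13–15% of T channels available at
rest, producing a 20–40 ms burst.

## Kinetics provenance

The gating rate functions are not free inventions: they follow the classic
single-compartment thalamic-reticular (nRT) Hodgkin–Huxley formulation used
by conductance-based TRN models of this family (the Traub-style nRT channel
set, with the A- and H-current kinetics of the Huguenard–McCormick
tradition and the TRN T current of the Huguenard–Prince/Destexhe
tradition).  Every rate function is `x' = (x_inf(V) − x)/tau_x(V)` with:

| gate    | x_inf(V)                          | tau_x(V) (ms) |
|---------|-----------------------------------|---------------|
| NaF m   | 1/(1+e^{(−V'−38)/10}), V' = V + s | 0.0125 + 0.1525·e^{(V'+30)/10} for V'<−30, else 0.02 + 0.145·e^{(−V'−30)/10} |
| NaF h   | 1/(1+e^{(V+62.9)/10.7})           | 0.225 + 1.125/(1+e^{(V+37)/15}) |
| KDR m   | 1/(1+e^{(−V−29.5)/10})            | 0.25 + 4.35·e^{(V+10)/10} for V<−10, else 0.25 + 4.35·e^{(−V−10)/10} |
| KA m    | 1/(1+e^{(−V−60)/8.5})             | 0.185 + 0.5/(e^{(V+35.8)/19.7} + e^{(−V−79.7)/12.7}) |
| KA h    | 1/(1+e^{(V+78)/6})                | 0.5/(e^{(V+46)/5} + e^{(−V−238)/37.5}) for V≤−63, else 9.12 |
| K2 m    | 1/(1+e^{(−V−10)/17})              | 4.95 + 0.5/(e^{(V−81)/25.6} + e^{(−V−132)/18}) |
| K2 h    | 1/(1+e^{(V+58)/10.6})             | 60 + 0.5/(e^{(V−1.33)/200} + e^{(−V−130)/7.1}) |
| H m     | 1/(1+e^{(V+75)/5.5})              | 1/(e^{−14.59−0.086V} + e^{−1.87+0.0701V}) |
| CaT m   | 1/(1+e^{(−V−52)/7.4})             | a_m + b_m/(e^{(V+27)/10} + e^{(−V−102)/15}) |
| CaT h   | 1/(1+e^{(V+80)/5})                | a_h + b_h/(e^{(V+48)/4} + e^{(−V−407)/50}) |

Published variants of this cell model differ in a handful of constants —
chiefly a voltage shift `s` of the NaF activation curve and the CaT
time-constant coefficients (a_m, b_m, a_h, b_h), which exist in the
literature in a fast (temperature-corrected) and a slow form.  These are
exposed on `CellParams` (`naf_shift`, `cat_taum`, `cat_tauh`) so any
variant can be substituted.  The shipped defaults are a calibration, chosen
once and fixed:

- `cat_taum = (0.44, 0.15)` (fast published form) and
  `cat_tauh = (28.3, 0.33)` (slow published form).  This pairing reproduces
  the reference model's burst time-course: vigorous burst onset (fast
  activation) with trains lasting tens of ms (slow inactivation).  The
  fast/fast and slow/slow pairings give bursts that are respectively too
  brief and too sluggish against the reference behaviour.
- `naf_shift = 0.856 mV`, set so the input-free cell rests at exactly the
  reference resting potential V₀ = −70.6837 mV (the one printed
  sub-millivolt anchor available for identifying the variant).  The rest is
  dynamically stable there; shifts beyond about +1.5 mV destabilize the
  rest into spontaneous firing.

Residual quantitative differences from the reference study that remain
after this identification are listed under *Known limitations* below; all
of them are of the size expected when the exact rate-function variant of a
cited source model must be reconstructed.

## Chemical synapses

GABA_A: E = −75 mV, τ_fall = 5 ms.  AMPA: E = 0 mV, τ_fall = 2 ms.  Both
use τ_rise = 0.1·τ_fall.  Kinetics follow the standard two-state
difference-of-exponentials scheme (NEURON's Exp2Syn): state variables A and
B decay exponentially with τ_rise and τ_fall, each presynaptic event
increments both by f_s per unit weight, and

    g(t) = ḡ (B − A),   t_peak = (τ_fall τ_rise)/(τ_fall − τ_rise) · ln(τ_fall/τ_rise).

The increment is the peak-normalizing factor

    f_s = 1 / (e^{−t_peak/τ_fall} − e^{−t_peak/τ_rise}),

so a single event produces a conductance transient whose maximum is exactly
ḡ, at t_peak after the event.  (A common printed closed form of this factor
carries an extra τ_fall/e, tied to a different ODE convention for the
two-state scheme; with the event-increment convention used here the factor
above is the one that satisfies peak normalization, and the package's tests
enforce max_t g(t) = ḡ to 0.5% against a brute-force dense-grid maximum.)

Presynaptic events for the four internal synapses are the spike times of
the presynaptic cell, detected online during integration, with zero
synaptic delay (none is specified for this circuit; the delay is
configurable only in the sense that events are applied at step boundaries,
see below).  External inputs are scheduled (strength, time) events on
dedicated AMPA synapses, one synapse per event, so per-event strengths are
exact.

Gap junctions are linear and symmetric: I_i = g_elec (V_j − V_i), and the
current into j is the exact negative, so charge is conserved pairwise at
every instant.

## Numerics

The coupled system (4 × (V + 10 gating) + 2 per synapse ≈ 56 states) is
integrated by an adaptive Bogacki–Shampine 2(3) embedded Runge–Kutta pair —
the method behind MATLAB's `ode23` and SciPy's `RK23` — with relative
tolerance 1e-3, absolute tolerance 1e-6, and a hard step-size cap of
0.01 ms (configurable).  The step grid is aligned to scheduled external
event times, and internal spike events are applied at the end of the
accepted step on which the threshold crossing is detected, so all synaptic
increments land within one max-step (≤ 0.01 ms) of their true time.  Spike
detection is an upward crossing of 0 mV with a 1-ms minimum inter-event
interval; action potentials in this model overshoot 0 mV robustly, and the
detected times shift by < 1 ms when the threshold is moved to −20 mV.
Halving the solver tolerances moves spike times by < 0.1 ms.  The pipeline
contains no randomness: identical configurations produce identical outputs.

Steady-state initialization relaxes a single cell from −75 mV (gating at
its steady state) for 5000 ms, then polishes the landing point to the exact
fixed point by solving the scalar current balance I(V, x_inf(V)) = 0 —
at a fixed point every gating variable sits on its steady-state curve, so
this is exact, and it removes solver tolerance noise that would otherwise
leave |dV/dt| at ~1e-4 mV/ms (the H-current activation time constant is
~750 ms near rest, and the fast NaF gate carries a persistent
tolerance-proportional lag).  The returned state satisfies |dV/dt| <
1e-6 mV/ms; an oscillatory rest raises a flagged error with the relaxation
trace attached.  All four cells start network simulations from this state,
with synaptic states at zero.

## Measurement protocols

Membrane conductance G_m: steady hyperpolarizing currents (−0.025 to −0.1
µA/cm²) are injected into an isolated cell, the steady-state voltage
deflection is measured after a 6000-ms settle, and G_m is the
through-origin slope of current against deflection.  The shipped model
measures G_m = 0.0663 mS/cm².  Note the subthreshold I–V curve rectifies
(H current), so single-current estimates vary by ~10–15% across the
protocol range; the multi-current slope is the reported quantity.

Coupling coefficient: steady current into TRN1 with chemical synapses held
at zero and the gap junction attached; cc = ΔV_TRN2/ΔV_TRN1 at steady
state, averaged over the injected currents.  At the maximal gap conductance
(0.025 mS/cm²) the shipped model measures cc = 0.299, matching the
two-point steady-state prediction cc = g_elec/(G_m + g_elec) with the
measured G_m.  (The reference study states the theoretical form
G_m/(G_m + G_elec), which contradicts both cc → 0 as G_elec → 0 and its own
printed cc value; the measurement protocol is the ground truth here, and
the printed reference pair G_m = 0.0551, cc = 0.2883 is itself mutually
inconsistent with the two-point formula — that cc implies an effective
G_m of 0.0617, within 8% of the value this package measures.)

## Spike-train metrics

The spiking window of a TC cell is σ = [first spike, last spike + 5 ms]
(the 5-ms tail allows for EPSP decay in a downstream cortical reader); a
silent cell has an empty window, |σ| = 0.  Per-cell independence is
ψ_i = 1 − |σ₁∩σ₂|/|σ_i|, combined as ψ = sqrt((ψ₁²+ψ₂²)/2); if either
window is empty the pair is defined fully independent (ψ = ψ₁ = ψ₂ = 1).
Separation ϕ is the gap between the leading window's end and the following
window's start when ψ = 1 (both spiking), minus the overlap length when
ψ < 1, and undefined (NaN) when either cell is silent.  Undefined values
propagate as NaN through every aggregation; they are never coerced to
zero.  Intervals are closed; windows that exactly touch count as overlap
zero, hence ψ = 1 and ϕ = 0.  ψ is stored as a fraction and reported as a
percentage in user-facing tables.  TC2 latency is its first spike time
minus its input arrival time.

Note one boundary subtlety: shrinking a window never increases the overlap
(so the *other* cell's ψ never decreases), but the shrinking cell's own
fractional overlap can grow, so combined ψ is not monotone under window
shrinkage in general.

## Sweeps, gains, strata

Sweeps run one simulation per point of a grid over (G_elec, G_GABA, G_in2,
t_in2) with TC1's input fixed at 0.06 mS/cm² / 60 ms and G_AMPA at 0.05
mS/cm².  Default grid steps (configurable): G_elec 0–0.025 by 0.001,
G_GABA 0–0.05 by 0.005, G_in2 0.02–0.1 by 0.01, t_in2 10–110 by 10 ms —
28 314 points in full; the uncoupled slice G_elec = 0 is always included.
Gains are per-point differences from the uncoupled slice at matched
parameters (zero there by construction; NaN stays NaN).  Input differences
are summarized by r = sqrt((ΔG/max ΔG)² + (Δt/max Δt)²), binned into five
equal-width strata over the observed [0, max r] (the bands are visually
uniform in the reference display; the count is configurable).  The
per-stratum summary reports the mean of non-negative and of non-positive
gains separately (the top/bottom semi-arc convention), with contributing
and missing counts; means are the neutral default since no aggregation
statistic is specified, and the raw per-point gains are always exported.

## What the numbers in the tests mean

The metric layer is tested against synthetic spike trains with exactly
known window geometry (`thalnet.fixtures`), against hand-evaluated
examples, and against a brute-force 0.01-ms grid-counting overlap oracle.
The simulator is tested for rest stability, determinism, pair symmetry,
decoupled-pair independence, gating bounds, solver-refinement stability,
and the measurement protocols' limiting cases (leak-only cell, uncoupled
pair).  Passing these shows the machinery is faithful to its stated
equations; it does not show the cell matches any particular biological TRN
neuron beyond the reference parameter set.

## Known limitations

- The exact rate-function variant of the reference study's source cell
  model is not published in the study itself; after identifying the variant
  against the printed resting potential, some spike-level quantities remain
  outside the ±10% / ±1 spike / ±1.5 ms band the acceptance tests use:
  first-spike latency to a 0.06 mS/cm² input is 5.3 ms here vs 8.5 ms
  reported; the delayed-input configuration's separation is 5.3 ms vs 9.2;
  the truncation configuration's independence/separation are 78%/−6.0 ms vs
  55%/−12.7.  The corresponding acceptance tests fail by design rather than
  being loosened; every mismatch is consistent with the cell here being
  slightly more excitable after its first spike and its feedback loop
  engaging a few ms differently than the reference variant.  G_m measures
  0.0663 vs 0.0551 printed (see the protocol note above on the reference
  pair's internal inconsistency).
- Separation vs G_GABA in the strong-early-input configuration rises from
  −30 ms to +8.6 ms across the sweep but is not pointwise monotone here:
  last-spike times move in discrete jumps as the truncation boundary
  crosses individual spikes, producing ±5 ms zigzags.  The endpoints and
  the overall trend match the reference behaviour.
- No cortical feedback, neuromodulation, convergent connectivity,
  heterogeneous cells, synaptic plasticity/NMDA/GABA_B, conduction delays,
  or noise: the motif is deliberately minimal, and the package scope is the
  motif.
- Single compartment, no temperature scaling, deterministic channels.
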