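# Methods

## Scope and assumptions

`cb6f` solves the steady state of C3 leaf photosynthesis at 25 °C with the
cytochrome b6f complex as the kinetic bottleneck of intersystem electron
transport.  The model is deliberately "top down": it starts from the demands
of carbon metabolism (Farquhar-type Rubisco kinetics) and works backwards to
the minimum rates of linear (LEF) and cyclic (CEF1) electron flow that close
the Fd, NADPH and ATP budgets simultaneously.  No metabolite pools, lumen pH,
membrane potential or transient dynamics are represented; regulation (NPQ,
photosynthetic control, CEF1, state transitions) enters only through the
balance conditions it must satisfy in steady state.  Reaction centers are
two-state (open/closed): PS II closes on the acceptor side, PS I on the donor
side, both as consequences of b6f turnover.  PS I acceptor-side closure and
triose-phosphate-utilization limitation are out of scope, as are temperature
response functions (all constants are 25 °C values).

Absolute complex concentrations never appear.  All rate laws are written in
ratio form (closure fractions, yield ratios); the b6f maximum activity
V_max(CB6F) (µmol e⁻ m⁻² s⁻¹) carries the only absolute scale, and the
catalytic constant k_q enters only through the ratio k*/k_q.

## Parameters

| symbol | default | units | meaning |
|---|---|---|---|
| α (alpha_total) | 0.85 | mol mol⁻¹ | leaf PAR absorbance |
| α1, α2 | 0.41, 0.44 | mol mol⁻¹ | PS I / PS II cross sections (α1+α2=α) |
| V_max(CB6F) | 350 | µmol e⁻ m⁻² s⁻¹ | maximum b6f activity |
| V_max(RUBC) | 100 | µmol CO2 m⁻² s⁻¹ | maximum Rubisco carboxylase activity |
| R_d | 0.01·V_max(RUBC) | µmol CO2 m⁻² s⁻¹ | day respiration ("0.01" read as a fraction of V_max; independent override available) |
| g_m | 0.084 | mol CO2 m⁻² s⁻¹ bar⁻¹ | mesophyll conductance |
| K_P1, K_D1, K_F1 | 14.5, 0.55, 0.05 | ns⁻¹ | PS I photochemistry / heat / fluorescence |
| K_X1 | = K_P1 | ns⁻¹ | heat loss at closed (oxidized) PS I centers |
| K_P2, K_D2, K_F2 | 4.5, 0.55, 0.05 | ns⁻¹ | PS II rate constants |
| K_U2 | 0 | ns⁻¹ | PS II exciton sharing (0 = puddle; 2 ≈ real leaves; 10³ stands in for the lake limit) |
| K_N2 | solved | ns⁻¹ | regulated heat loss (qE/qZ NPQ) — a state variable, never a parameter |
| k_c, k_o | 3.6, 0.9 | mol mol⁻¹ sites s⁻¹ | Rubisco catalytic constants |
| K_c, K_o | 260 µbar, 179 mbar | | Rubisco Michaelis constants |
| n_L, n_C | 0.75, 1.00 | mol ATP mol⁻¹ e⁻ | coupling efficiencies (below) |
| C, O | 200 µbar, 209 mbar | | chloroplast gas partial pressures |

The rate-constant scaling fixes the maximum photochemical yields at 96 %
(PS I) and 88 % (PS II) and the PS II fluorescence yield range at 1 % (open)
to 8 % (closed).  The implied PS I fluorescence yield is K_F1/ΣK⁰ = 0.33 %;
the lifetime literature quotes 0.35 % for the same scaling — the rate-constant
definition is used and the 0.06-point discrepancy accepted.

**Proton ledger.**  Per electron, linear flow deposits 1 H⁺ at water oxidation
plus 2 (Q-cycle) or 1 (no Q-cycle) at b6f; cyclic flow deposits the b6f
protons plus 2 when NDH pumps.  Dividing by the synthase stoichiometry (4
thermodynamic or 14/3 structural H⁺/ATP) gives n_L and n_C.  The reference
scenario (Q-cycle, NDH, 4 H⁺/ATP) yields n_L = 0.75, n_C = 1.00 and a CEF1
share of 3 % at the reference conditions; relaxing NDH, the synthase ratio,
the Q-cycle, or all three gives 6, 14, 27 and 62 % respectively.  The
component stoichiometries are literature values; the additive ledger is this
package's reconstruction, fixed because it reproduces the n_L/n_C pairs and
four of the five published percentages exactly (the all-relaxed case computes
to 62.4 %, one rounding step below the published 63 % — consistent with that
figure having been derived from two-decimal n_L = 0.43, n_C = 0.21).

## Solution

For a given light Q and chloroplast CO2 C the solver evaluates both limiting
rates and applies A = min{A_j, A_c}; a tie is classified b6f-limited, making
k*/k_q left-continuous (it equals 1 up to and including the saturation point).

*b6f-limited:* closure f = Q/(V_max/a + Q) with a = α1·K_P1/ΣK⁰_P700 is
shared by f2, fb and f1; J_P700 = f·V_max; J_P680 = J_P700/η.  With fixed
cross sections the NPQ constant K_N2 is back-solved so PS II supply matches;
with state transitions K_N2 = 0 and the α split is solved instead.

*Rubisco-limited:* J_P680 follows from Rubisco kinetics; the PQ poise stays at
the light-driven value f (the pool "remains poised to maximize potential
flow").  In **minimal-CEF1** mode J_CB6F = η·J_P680 and photosynthetic control
reduces the turnover constant, k*/k_q = J_CB6F/(fb·V_max) < 1.  In
**regulatory-CEF1** mode k* stays maximal, J_CB6F stays at its light-limited
value, and the excess J_P700 − J_P680 is an uncoupled cyclic flux.  Both modes
back-solve the same K_N2 and produce identical gas-exchange and fluorescence
observables (PS I fluorescence is independent of f1 because K_X1 = K_P1); they
differ only in f1 and k*.  Two further switches expose the single-mechanism
scenarios: `npq_enabled=False` (control by b6f alone, K_N2 ≡ 0, the PS II
closure solved self-consistently) and `b6f_control=False` (control by NPQ
alone, k* ≡ k_q, the PQ poise dropping to η·J_P680/V_max above saturation).

**Closed forms.**  Substituting the exciton-sharing yield algebra into the
PS II balance makes every back-solve algebraic: K_N2 is the unique
non-negative root of a quadratic, the no-NPQ closure is the root of a
quadratic (linear when K_U2 = 0), and the Rubisco-limited no-NPQ closure is
linear.  This replaces bracketed root-finding (which remains as an independent
oracle in the tests) and makes the entire solve broadcastable with numpy —
the property the inversion exploits to evaluate whole GA populations at once.

**State transitions.**  Under limiting light the balanced split satisfies
α2/α1 = [(1−f)·K_P1/ΣK⁰/η] / Φ_P2(f; K_U2), which depends on f when K_U2 > 0;
the solver iterates a damped (0.5) fixed point between f and the split to
1e-10, seeded from the closed-form K_U2 = 0 split.  At light saturation the
closure is f_sat = η·J_P680(rubisco)/V_max — notably independent of the split
itself, which is why the PQ poise at the transition is invariant when both
V_max values are scaled together.  Above saturation the split is frozen at its
f_sat value.  Because the balanced split at f → 0 is fully determined by the
rate constants, the *dark-adapted* split is a separate quantity: it is the
α2 the inversion fits, used for the dark reference levels F_m and F_o, while
light records use the solved split.  Physically this is the state 1 → state 2
transition; mathematically it decouples the fitted α2 from the light-limited
balance.

**Degenerate inputs.**  C ≤ Γ* raises a domain error.  Q = 0 gives the dark
state (A = −R_d, all closures 0, K_N2 = 0) without special-casing.  If the
PS II supply at K_N2 = 0 cannot reach the b6f-limited flux (tiny α2 against a
large α1), the solver falls back to a self-consistent PS II-limited closure
and flags the state `psii_limited` rather than failing.

## Fluorescence conventions

Detector-space levels use F/S = α2·Φ_F2·ε_F2 + α1·Φ_F1·ε_F1.  The extreme
levels (F_m, F_m', F_o, F_o') use the conventional per-unit rate-constant
sums, which omit K_U2 even though the steady-state yields include it; the
package follows the printed convention and records the inconsistency here.
F_o' is modeled as the light-adapted all-open state (same K_N2 as the steady
state); the far-red/dark-pulse measurement mechanics are not simulated.
The apparent-LEF convention multiplies by α2 = 0.85·0.5 = 0.425 regardless of
the model's α2 — the diagnostic mimics what an experimenter computes.

The V_max(CB6F) estimator (median of k_Lake = LEF/(1−qL) over limiting-light
records) is exact only on lake-type antennae with negligible CEF1: on
puddle-type data 1 − qL = f·ΣK⁰/(ΣK⁻ + f·K_P2) overstates the PQ-pool
reduction severely at low light, and CEF1 inflates LEF's η-divisor, so the
estimate biases low in both cases (by design — the same caveats apply to the
experimental diagnostic).  The validation suite therefore checks the 2 %
round trip under the diagnostic's validity conditions (K_U2 = 10³, C = 1000
µbar, α2 = 0.425) and the direction of the bias off them.

## Synthetic data

The generator emulates an 8-h sine-wave light protocol (peak 200–2400 µmol
PPFD m⁻² s⁻¹, 8-min sampling, 61 records whose endpoints are dark and provide
F_m/F_o).  Chloroplast CO2 is held constant across light — the simulations'
convention; there is no stomatal model — and the cuvette CO2 is synthesized
backwards through g_m and the ternary-corrected stomatal/boundary-layer path
so the diffusion equations invert exactly.  Noise is multiplicative lognormal
with unit mean and configurable CV per stream (fluorescence, gas), all drawn
from one seeded generator; fixed seeds give byte-identical CSVs.  Real data
differ in ways the generator does not emulate: stomatal dynamics and C_c
drift, flash artifacts, drift in detector sensitivity, autocorrelated errors,
and transitions between steady states.  Passing the closed-loop tests
therefore demonstrates the *identifiability machinery*, not field accuracy.

## Inversion

Two objectives are minimized: a gas-exchange misfit over A and a fluorescence
misfit over {F_s, F_m', F_o', dark F_m, dark F_o}.  Each observable is
normalized by σ = 2 % of its dynamic range (configurable); the unknown
detector scale S·ε_F2 is profiled out of the fluorescence objective in closed
form, making the fit invariant to common rescaling of all fluorescence
observations.  Solver failures map to a large finite penalty, never an
exception.  By default only the ascending light phase is fitted (dark rows
are always kept as references).  Default bounds: α2 ∈ (0.2, 0.7)·α,
K_U2 ∈ [0, 10] ns⁻¹, V_max(CB6F) ∈ [50, 1000], V_max(RUBC) ∈ [20, 300],
g_m ∈ [0.01, 0.5], ε_F1/ε_F2 ∈ [0, 10].

The optimizer is an elitist NSGA-II (population 200, generations 300, binary
tournament on rank/crowding, (µ+λ) truncation) whose brood combines SBX +
polynomial mutation with a differential-evolution move toward the current
best-compromise member, plus 5 % random immigrants.  The final front is
refined by a parallel (1+1)-ES polish in which each member descends its own
weighted scalarization of the two objectives, so members converge to their
own Pareto positions rather than a common point.  Rationale: on the smooth
landscapes of this model, SBX/mutation alone stagnates 1.5–2.5 % from the
optimum at this budget; the DE move and the polish supply the missing
exploitation while the Pareto machinery keeps genuinely conflicting fits
(noisy data) represented as a front.  All randomness flows from one seeded
generator: fixed seed ⇒ bit-identical front.  On noiseless synthetic data
the Pareto-front medians recover all six free parameters within 1 % of truth
(the closed-loop check in the test suite), in seconds on one CPU.

Parameter summaries are reported as 50th (25th, 75th) percentiles across the
front; fit quality as Type I regressions (R², RMSE, intercept, slope) of the
median model against the measurements, with an explicit outlier keep-mask.

## Problem sizes

Light responses are evaluated on Q = 0:25:2400 (97 points) — also the grid on
which the maximum absorbed quantum yields are reported (0.0640 at 200 µbar,
0.1099 at 5000 µbar; the maximum sits at the lowest nonzero grid point since
the potential quantum yield decreases monotonically with light).  The
recovery test uses the full 61-sample protocol and the default GA budget.

## Known limitations

Steady-state only; no temperature kinetics; no TPU limitation; no PS I
acceptor-side closure (donor-side only); no lumen-pH mechanics — regulation
is inferred from balance, not simulated mechanistically; the stomatal path is
consumed, not modeled; `alpha_2` identifiability in the inversion rests
entirely on the dark reference levels, so datasets without dark records
cannot constrain it (the Dataset container rejects them).
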