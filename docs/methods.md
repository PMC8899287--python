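# Methods

## Model structure

A Cx36 gap-junction channel is modelled as two hemichannels in series, one
per cell, gating independently (except under the optional trapping
mechanism below). Each hemichannel follows a linear 3-state chain
`S0 <-> S1 <-> S2` whose first state is open, whose terminal state is
closed, and whose intermediate state is either open or closed. Each of the
two transitions is either ligand-independent or a Mg²⁺-binding step whose
forward rate scales as `k · mgⁿ` (Hill; mass action fixes n = 1).
Enumerating these choices and discarding the two schemes with no Mg²⁺
dependence plus the scheme with a redundant ligand-independent transition
between two open states leaves five basic schemes; crossed with the two
binding laws this yields the ten-model catalogue addressable as
`"Model 1"`…`"Model 5"` with an optional `", Hill"` suffix.

Assumptions baked into the catalogue: hemichannels transit only between
fully open and fully closed conductance (no sub-conductance levels);
gating is deterministic at the population level (state probabilities, not
single-channel trajectories); both cells of a pair have equal volume and
express the same variant.

## Parameters

| name | units | meaning |
|---|---|---|
| k1, k2 | min⁻¹ | forward/backward rates of the first transition (for the terminal-binding family: closing/opening of the ligand-independent gate) |
| k3 | min⁻¹·mM⁻ⁿ | Mg²⁺ binding rate; `k3·mgⁿ` is a rate in min⁻¹ with mg in mM |
| k4 | min⁻¹ | Mg²⁺ unbinding rate |
| n | — | Hill exponent (frozen at 1 for mass-action schemes, never fitted there) |
| P | min⁻¹ | junctional Mg²⁺ permeability per unit normalised conductance |
| P_leak | min⁻¹ | leak of Mg²⁺ from an unclamped cell into its pipette; fixed by the recording configuration, never fitted, excluded from the AIC parameter count. Default 0 — its magnitude depends on pipette access resistance and is supplied per experiment when known. |

`k3`'s units follow from dimensional consistency of the ODE: one shared
exponent n applies per scheme (schemes with two binding transitions share
it), which keeps the free-parameter count at 5 (mass action: k1–k4, P) or
6 (Hill: + n) per scheme.

Built-in parameter sets (`VARIANT_PARAMS`) hold published point estimates
for wild-type Cx36 and the N-terminal variants E3Q, E8Q, A13K and H18K
under the terminal-binding Hill scheme; they are the defaults of the
synthetic-data generator and of the simulation presets.

## Cell-pair system and protocols

State vector: two 3-state probability vectors plus the two cytosolic Mg²⁺
concentrations. Hemichannel i binds its own cell's Mg²⁺. Normalised
junctional conductance is the product of the two open fractions and every
simulated g_j series is normalised to its initial value. Unclamped cells
exchange Mg²⁺ through the junction by Fick's law, `+P·g_j·(mg_j − mg_i)`,
minus the pipette leak. The sign of the flux term is chosen so that Mg²⁺
flows down its concentration gradient; this is required for the recipient
cell's indicator signal to rise, and makes closed-system Mg²⁺ mass exactly
conserved.

Initial conditions: cytosolic Mg²⁺ starts at the pipette value in clamped
cells and at 0 in unclamped cells (configurable); hemichannel states start
at the ligand-free equilibrium, because the initial conductance is
recorded before the channels have responded to pipette dialysis, and
normalisation to g_j,init absorbs any residual mismatch.

Fluorescence proxy: the Mg²⁺ indicator signal is modelled as
`fi_norm(t) = 1 + c·(mg1(t) − mg1(0))` with c = 1 mM⁻¹. Only
proportionality matters — any instrument scale factor is absorbed into the
fitted permeability P — so the generator and the fitting objective share
the same convention and no separate calibration parameter is introduced.

Transjunctional voltage: V_j splits equally across the two hemichannels
with opposite polarities, and modulates the gating rates exponentially,
`k1' = k1·exp(z_open·s·V_j/2)`, `k2' = k2·exp(−z_close·s·V_j/2)` (s = ±1
per hemichannel). Defaults z_open = z_close = 0.1 mV⁻¹ with a 60 mV,
0.1-min rectangular pulse: strong enough to close one hemichannel almost
completely during the pulse, brief enough that a non-binding variant
reopens essentially fully afterwards. These slopes are protocol constants
shared between generator and fitter, not fitted parameters; a full
contingent-gating treatment of V_j dependence is out of scope and the
exponential modulation is a deliberate surrogate.

Deep-closed trapping: the joint 9-state master equation of the hemichannel
pair is the Kronecker sum of the two 3-state generators, with the
unbinding rate k4 multiplied by a factor ε only in the joint state where
both hemichannels are Mg²⁺-bound closed. ε defaults to 0 (absorbing trap);
ε = 1 recovers independent hemichannels exactly. Only the terminal-binding
("Model 5") family supports the trap, since it alone has a Mg²⁺-bound
closed state.

## Numerics

- Clamped-concentration protocols (including rectangular V_j pulses) are
  piecewise linear-time-invariant and are propagated exactly through the
  eigendecomposition of the generator (matrix-exponential fallback when
  the eigenbasis is ill-conditioned). This is both the fast path used in
  fitting and, by construction, exact.
- Protocols with evolving Mg²⁺ are integrated with LSODA (rtol 1e-8,
  atol 1e-10 for simulation; 1e-7/1e-9 inside fitting objectives). The
  chain is stiff — k2 ≈ 400 min⁻¹ against binding rates of order
  0.1 min⁻¹ — so a stiff-capable integrator is the default.
- A fixed-step explicit Euler integrator (default step 1e-3 min) is
  provided for replication purposes and agrees with the reference solution
  to <1e-4 in normalised conductance over 30 min for all built-in
  parameter sets.
- Probability conservation is checked after every integration
  (|Σp − 1| ≤ 1e-6) and violations raise a simulation error rather than
  being re-projected silently.
- Equilibria use the closed-form birth–death stationary distribution
  (products of forward/backward rate ratios); a forward rate with no
  return path raises a degenerate-chain error.

## Fitting

The objective is the pooled SSE over all traces and enabled channels
(normalised conductance everywhere; the fluorescence proxy only for
protocols with an unclamped recipient cell). Replicates of the same
protocol share one simulated prediction per objective evaluation. Traces
are averaged-data style: no per-trace variance weighting. Solver failures
inside the objective return a large finite penalty (logged) so global
search continues.

Global search is a seeded multi-start: Latin-hypercube starting points
within box bounds (defaults: rates 1e-6–1e4 min⁻¹, P 1e-6–1 min⁻¹,
n 0.01–5), each refined by trust-region least squares; rates and P are
searched in log10 space. The fit is bit-reproducible given (seed,
n_restarts, dataset). Best-of-restarts is reported together with every
restart's terminal SSE. Recovery studies default to bounds spanning the
generating values by a factor of ten each way.

Model comparison uses `AIC = 2(k+1) + n·ln(SSE) − n·ln(n)` (the +1 is the
error-variance parameter) and `ΔAIC = 2k + n·ln(SSE)`; the two differ by
the model-independent constant `2 − n·ln(n)`, which is asserted as an
identity. n counts every fitted sample across traces and channels. Akaike
weights are computed by a min-subtracted softmax, stable for |ΔAIC| well
beyond 10⁴. Multi-variant comparisons pool by summing SSE per scheme
across per-variant fits before applying the formulas (per-variant tables
can be produced instead). Ties in AIC are broken lexicographically by
label; the best-vs-second comparison is flagged significant only when the
ΔAIC difference exceeds 2.

## Synthetic data

The generator reproduces the study conditions: the five variant parameter
sets; asymmetric 5 and 10 mM donor protocols with simultaneous
conductance + fluorescence readout, symmetric 5 mM decay, a 0.01 mM
low-Mg control, and the V_j-pulse closure/recovery protocol; 5-minute
recordings sampled every 0.05 min (the cadence of the repeated
low-amplitude voltage ramps used to track g_j); additive Gaussian noise of
σ = 0.02 on both normalised channels (the published data report standard
errors of averaged traces rather than a noise model; 0.02 makes recovery
non-trivial but feasible); five replicates per condition. Noise is
observational only — concentrations and state probabilities inside the
generator stay exact — and negative noisy samples are clipped at zero with
a recorded clip count. Every trace receives a child seed spawned
deterministically from the master seed, and a dataset can be regenerated
byte-identically from its manifest.

What the generator does not emulate: photobleaching and dye kinetics,
series-resistance artifacts, cell-volume variation, plaque-size dynamics
and channel turnover, and trace-level correlations of real replicates
(real noise is neither white nor homoscedastic). Passing recovery tests
therefore demonstrate correctness of the pipeline under the assumed noise
model, not robustness to every artefact of real recordings.

## Problem sizes used in the automated checks

The parameter-recovery study fits 5 replicates of the asymmetric 10 mM and
symmetric 5 mM protocols (1,515 points per fit) over 5 seeds with 6
restarts each. The model-recovery study fits all ten schemes to 2
replicates of the asymmetric 10 mM, symmetric 5 mM and V_j-pulse protocols
over 5 seeds with 3 restarts per scheme. The V_j-pulse protocol is
included there deliberately: decay-only protocols cannot separate
open-state from closed-state binding (both families produce the same
`rate = a·mgⁿ + b` exponential observables), whereas post-pulse recovery
is qualitatively different when binding targets the closed state — it is
the discriminating experiment, and a two-state or open-binding scheme that
fits the decays cannot reproduce the impeded recovery.

## Known limitations

- **Partial identifiability.** Under the standard decay protocols the
  ligand-independent gate equilibrates ~20× faster than the 0.05-min
  sampling interval, and normalisation removes the equilibrium open
  fraction from the observables. The identifiable quantities are n, k4, P
  and the effective binding rate `k3·k1/(k1+k2)`; (k1, k2, k3)
  individually lie on a flat ridge and their point estimates from decay
  data alone should not be interpreted. Recovery studies reflect this:
  n, k4 and P return to within a few percent, while k1–k3 scatter along
  the ridge. Identifying k1 and k2 separately requires V_j-dependent data.
- For data with no Mg²⁺ response the SSE profile over k3 is flat near
  zero; the fitter reports a near-zero binding rate (the response index of
  the fitted model is ~1) rather than an arbitrary interior value, but k4
  is then unidentifiable.
- Uncertainty quantification (confidence intervals, bootstrap, profile
  likelihood) is out of scope; all estimates are point estimates.
- The exponential V_j modulation is a surrogate for full contingent
  gating; absolute voltage-dependence predictions should not be taken
  quantitatively.
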