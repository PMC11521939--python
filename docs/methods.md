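# Methods

This note documents the models implemented in `oem`, the choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not establish.

## Overview

`oem` simulates the first three stages of the fruit-fly early olfactory
system as a cascade of spatio-temporal divisive normalization processors
(DNPs): the Antenna (odorant transduction in olfactory sensory neurons,
OSNs), the Antennal Lobe (AL; per-glomerulus channels normalized by local
neurons) and the Mushroom Body Calyx (random expansion onto Kenyon cells,
KCs, normalized by the APL feedback neuron).  The scientific question the
cascade addresses is how odorant *identity* (the per-receptor
binding/dissociation profile, "semantics") is separated from odorant
*concentration* (the stimulus waveform, "syntax"), given that
transduction couples the two multiplicatively.  The final readout is the
first-spike-sequence code: the time-ordered first spikes of the active
KCs, which is approximately invariant to concentration but specific to
identity.

## Odorant space

An odorant is a pair of tensors `b[o,r,n]` (binding rate, 1/(ppm s)) and
`d[o,r,n]` (dissociation rate, 1/s) over odorants x receptor types x
OSNs-per-type, together with a concentration waveform `u_o(t)` (ppm).
The affinity `a = b/d` (1/ppm) is the quantity that sets receptor
responses.  `N` (OSNs per receptor type) defaults to 1; the axis is kept
so that N > 1 can be configured, in which case same-type OSN spike trains
are pooled into one AL channel (glomerular convergence).

The synthetic generator produces the two affinity-profile regimes used
throughout the characterization:

* **sparse-k** (k = 1: acetone-like, k = 3: nerol-like): background
  affinities log-uniform in [1e-5, 2.5e-4] 1/ppm and k dominant entries
  log-uniform in [8e-3, 2e-2] 1/ppm, boosted if necessary so the dominant
  set carries at least 80% of the summed affinity.  With these ranges the
  dominant channels have `a*u` crossing binding half-saturation inside
  the 50-200 ppm window -- their OSN rates stay concentration sensitive,
  which is the regime in which downstream normalization is a nontrivial
  claim -- while background channels stay essentially silent.
* **broad** (ethyl-butyrate-like): all receptors log-uniform in
  [1e-5, 2e-2] 1/ppm; several comparable receptors respond, none
  dominates, and the KC dendritic-input rank curve is smooth.

The dominant entries are drawn from a fixed strong range rather than by
scaling background draws: scaling produces dominants of widely varying
strength, and for k = 3 the weakest "dominant" channel then crosses its
firing threshold only at some concentrations, which destabilizes the
active-KC set across levels -- contrary to the multi-peak profiles the
generator is meant to emulate, in which the top receptors are of
comparable sensitivity.  Dissociation rates are log-uniform in [5, 50]
1/s (binding relaxation well inside the one-second stimulus).

Concentrations are ppm, times seconds, everywhere.

## Transduction (Antenna)

Per receptor channel, for mixture components `o` in `O`:

1. **Peri-receptor filter**: `v = Re[(h*u) + gamma (h*du)]`, with
   `h(t) = exp(-t/tau_h)/tau_h`, `tau_h` = 10 ms, `gamma` = 0.1.  The
   kernel is a unit-DC-gain low-pass (so steady-state analyses carry
   through unchanged); the derivative term adds a rectified onset
   transient.  Discretized as the exact zero-order-hold recursion.
2. **Competitive (syntopic) binding**:
   `dx1_o/dt = b_o v_o (1 - sum_p x1_p) - d_o x1_o`.  All components
   compete for the same unbound receptor pool; the steady state is the
   divisive form `x1_o* = a_o v_o / (sum a_p v_p + 1)`.  A mixture at a
   fixed ratio behaves exactly like a pure odorant with the
   concentration-weighted mean ("effective") affinity -- an algebraic
   identity the tests verify numerically.
3. **Co-receptor channel with calcium feedback**:
   `dx2/dt = a2 X (1-x2) - b2 x2 - kappa x2^{2/3} x3^{2/3}`,
   `dx3/dt = a3 x2 - b3 x3`, with `X = sum_o x1_o`.  Defaults
   `a2 = 10, b2 = 2, kappa = 10, a3 = 1, b3 = 1` (1/s).  `a3/b3 = 1`
   keeps the calcium state's fixed point `x3* = x2` inside [0, 1], so the
   gating-variable bounds are exact invariants rather than clipped
   approximations.
4. **Transduction current**: Hill function
   `I = x2^rho/(x2^rho + c^rho) * I_max` with `rho = 2`, `c = 0.45`,
   `I_max = 50 uA/cm^2`, used in its fast steady state (a `dynamic` mode
   integrating the relaxation ODE is available; note its literal rates
   `x2^rho`, `c^rho` are O(0.1)/s, i.e. tens of seconds to settle, which
   is why the steady form is the default).
5. **Spike generation** by the Connor-Stevens neuron below.

The co-receptor and current constants were chosen with a bundled
parameter sweep so that, for the synthetic fixtures, the 23 OSN channels
span silent to ~185 Hz and the mid-affinity channels remain concentration
sensitive across 50-200 ppm; with substantially larger `a2` or smaller
`c` every channel saturates and the sparse/broad distinction disappears.

## Spike generation

All populations use the standard Connor-Stevens point neuron (Na,
delayed-rectifier K, transient A-current, leak; standard constants,
resting potential ~ -68 mV) integrated by forward Euler at dt = 1e-5 s
(stability bound 2e-5 s; deterministic spike times shift < 1% when dt is
halved).  The A-current makes the neuron Type I: firing rises
continuously from zero at rheobase (~8.15 uA/cm^2 for the default
constants, found by bisection) and first-spike latency decreases
monotonically with drive -- the property the first-spike-sequence code
rests on.  Optional noise is additive white current noise
(Euler-Maruyama); its intensity tunes the smoothness of the f-I curve
around rheobase.  Useful intensities are O(0.1-1) uA/cm^2 s^1/2; all
characterization runs use sigma = 0 so the cascade is bit-reproducible.
Spikes are upward crossings of 0 mV with a 2 ms lockout.

## Antennal Lobe

Each of the R channels contains:

* an **OSN axon terminal** feedback DNP: per OSN spike
  `x += a1 (1-x)`, decay `b1 x`, and per Pre-LN spike `x -= k1 x`
  (`a1 = 0.1, b1 = 10/s, k1 = 0.05`); neurotransmitter output
  `NT = NT_max x`.  Under Poisson rates (lam, mu) its mean is the
  divisive `a1 lam / (a1 lam + b1 + k1 mu)` (verified against
  event-driven simulation to 5%).
* a **Pre-LN** (one per AL): Connor-Stevens neuron driven by
  conductance synapses from all channels' NT (alpha = 100/s per unit
  drive, beta = 10/s, g = 0.04 mS/cm^2, E = 0 mV), spiking back onto
  every axon terminal.  This is the spatio-temporal normalization: the
  more total activity, the more presynaptic suppression.
* **Post-eLN / Post-iLN** onset/offset extractors.  Their exact kinetic
  forms are an open design point; here a kinetic rate estimate of the
  OSN train (jump 0.005 per spike, decay 20/s) is low-passed
  (tau = 50 ms), and the rectified positive (negative) analytic
  derivative drives the excitatory (inhibitory) local neuron with gain
  40 uA/cm^2 per unit.  The jump size is set so that steady-state
  spiking flicker in the derivative stays below the local-neuron
  rheobase: the eLN fires only at stimulus onset, the iLN only at
  offset.  The eLN excites (E = 0 mV) and the iLN inhibits (E = -80 mV)
  the channel's PN through spike-driven synapses.
* a **PN** integrating the three synaptic currents
  (axon-terminal synapse: alpha = 20/s, g = 0.45, E = 0 mV).

Dirac spike trains in the kinetic equations are handled as impulsive
state updates at spike times with exact exponential decay between events,
so the update is dt-independent in the event semantics.

The axon-terminal synapse constants put the PN in a regime where the AL
reduces but does not eliminate concentration dependence: for the sparse
fixtures the per-channel CV of steady rates across 50-200 ppm falls from
~0.07-0.15 (OSN) to ~0.02-0.03 (PN).  Full flattening at the PN would
leave the calyx-level normalization nothing to do and is also not the
modeled biology, where PN responses remain visibly level dependent.

## Calyx

Each of the M KCs (default 500; the anatomical ~2,000 is configurable)
samples exactly Q PNs (default 6) uniformly without replacement -- the
random bipartite expansion.  The KC dendrite is a feedback DNP: per PN
spike `x += a1 (1-x)` (a1 = 0.1), continuous decay `(b1 + k1 x_APL) x`
(b1 = 5/s, k1 = 25/s), output current `I = I_max x`.  The APL state
integrates total KC spiking (jump 0.001 per spike, decay 10/s).  PN-KC
and KC-APL synaptic dynamics are deliberately omitted; spikes act
directly on the kinetic states.  KC spike generators are noiseless.

`I_max` is calibrated as twice the Connor-Stevens rheobase, so the
dendritic threshold x = 0.5 and the spiking threshold coincide: "active
KC" means the same thing whether read from steady dendritic output or
from the spike raster.  With the defaults, roughly 16-28% of KCs are active for
the sparse fixtures at threshold 0.5, and the fraction is monotone in
both Q and the threshold.

`k1 = 25/s` was chosen (with the APL constants) from the bundled sweep as
the value at which APL feedback most reliably removes the residual
concentration dependence of supra-threshold dendritic outputs across
wiring seeds; substantially stronger coupling overcompensates (the APL
level itself becomes the dominant source of across-level variation) and
weaker coupling undercompensates.

## Readouts

* **Rank curves**: stable descending sort (ties by original index).
* **Active set**: steady `x_KCD` > threshold (default 0.5).
* **First-spike sequence**: the earliest spike of each active KC after
  stimulus onset, merged and sorted; onset-aligned times.  Active KCs
  that never spike (possible under parameter mismatch) are dropped with
  a warning rather than imputed.
* **Sequence distance**: the package reports two numbers separately, a
  Jaccard overlap of active sets and a normalized Kendall-tau distance of
  the first-spike orders restricted to shared KCs (0 if fewer than two
  are shared).  No canonical similarity exists for this code; reporting
  both lets alternatives be applied downstream.
* **Cumulative interspike curve**: `t_k - t_0` along the sequence.
* **Gap ratio**: largest adjacent difference of a rank curve over the
  median adjacent difference; >= 5 flags the single-dominant signature.

## Numerical choices

* One global clock, dt = 1e-5 s, explicit Euler for all kinetics and
  neurons; impulsive updates are applied within the bin in which the
  spike falls (multiple spikes per bin accumulate as repeated updates).
* Kinetic states are validated against [0, 1] with tolerance 1e-9 and
  clipped only after that check.
* The steady-state window is the last 0.5 s of the odor step; rates are
  spike counts over that window.
* Two independent RNG streams: graph wiring vs neuron noise, so wiring
  studies can fix one while varying the other.
* The default stimulus protocol is 0.3 s silence, 1.0 s odor step,
  0.2 s tail.  The test-suite and acceptance-script runs use a 0.2 s
  lead-in and 0.1 s tail at the same dt -- long enough for transduction
  and AL transients to settle well before the steady window -- and
  M = 500 KCs, which keeps the full battery of cascade runs at desk
  scale.

## What the synthetic fixtures do and do not show

The generator reproduces the *structure* of measured receptor panels
(one dominant receptor vs several comparable ones vs broad tuning) but
not any measured affinity values, and its concentration steps are clean
square pulses without turbulence, adaptation or trial-to-trial noise.
Passing tests therefore establish that the implemented circuit performs
the claimed computation -- progressive removal of concentration
dependence and a concentration-invariant, identity-specific first-spike
sequence -- under the stated kinetic models and parameter defaults.  They
do not establish quantitative agreement with physiological recordings,
masking or ephaptic interactions between odorants (not modeled), the
lateral horn or multiglomerular PN pathways (out of scope), or behavior
under fluctuating natural odor plumes.

## Known limitations

* Explicit Euler with a fixed global dt trades speed for simplicity;
  stiff parameter choices outside the tested ranges may need a smaller
  dt.
* The Post-eLN/Post-iLN kinetic forms are a declared design (rectified
  rate derivative); other onset/offset extractors are plausible.
* The `dynamic` transduction-current mode integrates the relaxation ODE
  exactly as written, which settles on tens of seconds; the steady-state
  form is the intended operating mode.
* The Pre-LN -> axon-terminal feedback uses a uniform suppression
  fraction across channels.
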