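# Methods

`is3sim` models how hippocampal IS3 cells (interneuron-specific type 3,
CA1; VIP+/CR+ interneurons that inhibit other interneurons) respond to
in-vivo-like synaptic bombardment. This note documents the model, the
synthetic-data generator, the numerical choices, and what the package's
tests do and do not establish about real IS3 cells.

## The cell model

### Morphology

The default morphology is a synthetic stand-in for a reconstructed IS3
cell, built to honor the counts the analysis depends on rather than any
particular tracing:

- 221 compartments: 1 soma (10 x 10 um cylinder), a 50-compartment axon
  initial segment, and 10 unbranched dendrites of 17 compartments each.
- Each dendrite spans 425 um. Compartment lengths are uniform within the
  proximal span (0-300 um, the stratum-radiatum zone receiving CA3 input)
  and within the distal span (300-425 um, the stratum-lacunosum-moleculare
  zone receiving entorhinal-cortex layer-III input). Half the dendrites
  carry 9 proximal + 8 distal compartments and half 8 + 9, so exactly 85
  dendritic compartments lie on each side of the 300 um boundary. A naive
  uniform-25-um layout cannot produce this split (each dendrite would have
  12 compartments below 300 um), which is why the lengths differ slightly
  between the two sections.
- Dendrite diameter tapers linearly from 1.0 um at the soma to 0.4 um at
  the tip. The taper matters: with thick uniform dendrites the distal
  pathway is electrotonically almost as effective at the soma as the
  proximal one, and the two theta-locked excitatory volleys (0 deg and
  180 deg, below) then cancel into a 16 Hz output rhythm. Thin distal
  dendrites attenuate the distal pathway under conductance load, which is
  what lets an 8 Hz component emerge - and is also the realistic geometry
  for SLM-projecting interneuron dendrites.

Morphologies serialize to SWC (node = distal endpoint of a compartment;
round-trip is lossless for chain geometries) and arbitrary SWC files can be
read back, so a user can substitute a reconstructed morphology.

### Channels and kinetics

Two variants differ in their A-type potassium distribution, with maximal
densities (mS/cm^2) as tabulated for the original models:

| variant | G_Na,t | G_Na,p | G_Ka | G_Kdrf | layout |
|---|---|---|---|---|---|
| AType+ | 70 | 0.075 | 70 | 250 | uniform over soma + first 70 um of dendrite; Na,p soma only |
| AType- | 55 | 0.15 | 30 | 295 | as above, but Ka soma only |

The AIS is passive; all four conductances vanish beyond 70 um of dendritic
path distance.

The gating kinetics of the original reconstructed models are not public,
so `is3sim.kinetics` implements standard sigmoid HH-style gates shaped for
a fast-spiking interneuron and collected in one swappable file. Three
features of these curves carry scientific weight:

- the delayed rectifier activates steeply around -25 mV, so its very high
  maximal density contributes almost nothing at subthreshold voltages
  (otherwise the cell cannot spike at all);
- transient-Na inactivation recovers slowly at subthreshold voltages
  (tau_h up to ~100 ms). Sustained high-rate firing then depletes h
  cumulatively and spikes shrink - the depolarization-block (DB)
  mechanism. The more excitable AType- variant enters DB before AType+;
- spike threshold sits near -45 mV, comfortably above the resting
  potential (-70 mV), so firing under bombardment is fluctuation-driven
  and irregular (ISICV approaching 1) rather than pacemaker-like.

Because the kinetics are stand-ins, two quantities are *calibrated* to the
measured anchors instead of being asserted: the uniform leak density
`g_leak` is fitted (bracketing root search) until the no-input somatic
input resistance measured by the -100 pA / 4.5-5.5 s step protocol equals
388.71 MOhm (AType+) or 406.57 MOhm (AType-) within 0.5 MOhm, and the
somatic white-noise amplitude is rescaled until the subthreshold sigma_Vm
of a 10 s quiescent run averages 0.22 mV (+/-0.02) over several seeds.
Passive parameters: Cm = 1 uF/cm^2, Ra = 300 Ohm cm, E_leak = -70 mV,
E_Na = +55 mV, E_K = -90 mV; no temperature corrections.

### Numerics

Backward Euler at dt = 0.025 ms with a Hines-ordered tridiagonal-tree
elimination per step (compartments are indexed parents-before-children, so
the elimination is a single O(n) backward/forward pass). Gates advance by
exponential (Rush-Larsen) integration evaluated at the pre-step voltage;
ionic and synaptic conductances enter the implicit system linearly in
V(t+dt), which keeps the scheme stable under stiff synaptic bombardment.
Synaptic state is aggregated per kinetic class per compartment as two
exponentially decaying accumulators, so cost per step is independent of
the number of synapses; presynaptic spikes are snapped to the nearest
solver step. Somatic noise is a per-step Gaussian current scaled by
1/sqrt(dt), making its voltage statistics dt-invariant. The step loop is
numba-compiled; identical seeds and configs give bit-identical traces, and
a non-finite state aborts with the offending time and compartment.

The ideal somatic voltage clamp pins the soma row of the linear system and
reports the electrode current from the somatic membrane and axial balance;
it has zero series resistance by construction.

## Synapses

Double-exponential conductance synapses, i = G (V - E_R), with the
single-event peak normalized exactly to the slot's weight. Weights follow
the printed linear distance rules (excitatory 0.00230814 d + 0.22016666 nS;
inhibitory 0.00469125 d + 0.2695779 nS; d = the compartment's path
distance, since synapses sit at compartment midpoints) and kinetics are
fixed per class: proximal excitatory (tau_r, tau_d) = (2.9936e-4, 2.4216) ms,
distal excitatory (6.1871e-4, 3.1975) ms, inhibitory (0.1013, 4.8216) ms;
E_R = 0 mV excitatory, -70 mV inhibitory.

The full bank holds 1530 excitatory slots (9 per dendritic compartment;
765 per zone) and 344 inhibitory slots (2 per compartment, with the first
4 compartments carrying a third - the printed per-compartment inhibitory
densities of 2 and 4 cannot both reproduce the printed total of 344 on 170
compartments, so the totals win). Bank construction is deterministic.

## The input generator

The generator *is* the study's stimulus definition, not a test fixture:

- **Background trains.** A rate-r train over T ms is exactly
  round(r T / 1000) spike times sampled uniformly on [0, T] and sorted;
  its inter-spike intervals are near-exponential (the sorted-uniform
  spacings construction). Rates span 0-30 Hz (excitatory) and 0-100 Hz
  (inhibitory), matching CA3/EC3 pyramidal and CA1 interneuron rates.
- **Selection.** Active synapses are drawn by unique uniform sampling,
  with the excitatory actives split equally between proximal and distal
  zones (so N_E must be even at selection time).
- **Common inputs.** Actives of each stream partition into consecutive
  groups of k (k_E for each excitatory zone vector, k_I for inhibitory);
  every member of a group references the *same* train object, and n mod k
  leftover synapses form a remainder group. k = 1 is fully independent.
- **Streams.** Each scenario seed fans out (via `SeedSequence`) into
  independent placement, spike-time and noise streams, so noise can be
  toggled or theta inputs added while the background drive stays
  bit-identical.
- **Theta protocol.** Deterministic 8 Hz drive: each population fires one
  spike per 125 ms cycle at a fixed phase. CA3 (proximal excitatory)
  anchors 0 deg; CA3-driven inhibitory populations (bistratified, IS1;
  proximal) follow at 90 deg; EC3 (distal excitatory) at 180 deg;
  EC3-driven inhibitory populations (neurogliaform, OLM, IS2; distal) at
  270 deg. Default counts are 27 synapses per excitatory population and 8
  per inhibitory population (AType-: 27/4 proximal, 18/4 distal). Theta
  synapses are chosen deterministically but *strided evenly* through the
  zone's slot list; taking the lowest slot ids instead would pile the whole
  population onto the first dendrite's first compartments, a geometric
  artifact of the synthetic fixture.

What the generator does **not** emulate: oscillatory or rate-modulated
background trains, sharp-wave-ripple events, synaptic failures or
short-term plasticity, NMDA-type voltage dependence, and spatial
correlation between synapse placement and train identity. Passing tests
therefore speak to stationary, rate-defined bombardment only.

## Measurements and classification

All features are computed over the last 9 s of a 10 s simulation. Spikes
are detected at an upward crossing of -20 mV; the spike begin is the last
upward crossing of dV/dt >= 20 mV/ms before the peak, the end is the
return below the begin voltage (capped at 10 ms past the peak so DB
plateaus are not swallowed), and the begin-to-end span is cut from the
subthreshold trace. Amplitude is peak minus begin voltage - shrinking
amplitudes are exactly what flags DB, which is why a threshold-relative
measure is used. ISICV is sd/mean of the inter-spike intervals, defined 0
below 3 spikes; a spikeless trace is not DB by convention (its amplitude
term contributes 0).

The in-vivo-like score combines four indicator terms:

    IVL = (mean Vm > -66.7 mV) + (sigma_Vm > 2.2 mV) + (ISICV > 0.8)
          - 4 (mean amplitude < 40 mV)

3 = IVL, 0 = NIVL, negative = DB, else PARTIAL.

Input resistance uses a -100 pA step over 4.5-5.5 s; the hyperpolarized
mean skips the first 200 ms of the step (settling), the baseline averages
0-4.5 and 5.5-10 s with spikes cut. Spike-train spectra bin spikes at 1 ms
into an instantaneous rate (spikes/s), then Welch with Hann-windowed
2048-sample segments at 50% overlap (about 0.49 Hz resolution; at least 7
averaged segments in the 9 s window); the 8 Hz value is read at the
nearest bin. These segment choices are this package's (the original
analysis did not state its Welch parameters).

## Sweep, pools, representatives

The production grid is f_E in {0,5,...,30} Hz, f_I in {0,10,...,100} Hz,
N_E in {18,36,...,1530}, N_I in {4,8,...,344}, crossed with two variants
and four common-input modes ((1,1),(9,1),(1,4),(9,4)) - 4,502,960
ten-second simulations. The package enumerates this grid exactly (with
deterministic per-scenario seeds hashed from the coordinates) but executes
sweeps on configurable coarsened grids; the built-in reduction keeps every
2nd rate value and every 5th count value. Full execution is cluster-scale
work outside this package's scope.

Pools split each parameter into printed Low/High ranges, labelled in the
order (N_I, N_E, f_I, f_E). One anomaly is inherited from the printed
ranges: the N_E grid value 774 lies strictly between the Low maximum (765)
and the High minimum (783), so pool assignment rejects it; sweeps that
need pools use grids avoiding it.

A pool's representative is its first IVL scenario - candidates ordered by
(f_E, f_I, N_E, N_I, seed) ascending - whose re-simulations with fresh
placement and spike-time seeds remain IVL every time. The package default
re-confirms 10 times as in the original procedure; the desk-scale test
suite confirms 3 times and scans small in-pool candidate lists, and when
no candidate survives the filter it falls back to the pool's first IVL
scenario (that fallback is exercised by the high-input HHHH pool at test
scale). CBDR (clutter-based dimensional reordering) images nest the 4-D
grid into 2-D with rows = (f_E outer, N_E inner) and columns = (f_I outer,
N_I inner); a JSON sidecar maps any pixel back to its four parameters.

## Conductance isolation and theta experiments

Isolation replicates the simulated voltage-clamp protocol: active
conductances removed everywhere, every compartment's leak reversal set to
the holding potential (so leak vanishes at the clamp instead of being
subtracted post hoc), ideal somatic clamp at -70 mV (recording excitatory
currents) or 0 mV (inhibitory), G = I / (V_hold - E_R). Method 1 removes
the opposite class's trains entirely; method 2 leaves both active, so
dendritic inhibition depresses the apparent excitatory conductance - the
space-clamp artifact the comparison exposes. Intrinsic noise is off during
clamp runs. The E/I ratio is the temporal mean of the element-wise ratio
g_E/g_I, excluding samples where g_I < 1e-3 nS (the ratio is undefined at
zeros; the excluded fraction is available to the caller). Theta-cycle
averages stack the 9 s window into its 72 consecutive 125 ms cycles.

Theta synapse-number estimation increments one population's count from 1
until the output spike train satisfies the stopping rule (excitatory: PSD
at 8 Hz > 50 spikes^2/Hz and more than 10 spikes; inhibitory, on top of a
holding current first calibrated to drive at least 350 spikes per 10 s:
PSD at 8 Hz > 80 spikes^2/Hz and fewer than 240 spikes), with a
configurable cap that raises naming the unmet criterion. The printed
holding currents (27.5 / 24 pA) and per-zone counts are properties of the
original models' kinetics; this package recomputes both for its own
calibrated stand-in rather than asserting them.

## Problem sizes used by the test suite

The default suite calibrates both variants from scratch, then runs on the
order of 150 ten-second simulations: a 24-point core subset in two
common-input modes for the common-input and high-excitation results, a
6-point matched set per variant for the DB comparison, 16 + 8 in-pool
candidates plus 5 reseeded before/after pairs per pool for the theta
experiment. These sizes are the package's chosen desk-scale defaults;
larger sweeps run through the CLI or library against the same code paths.

## Known limitations

- The gating kinetics are calibrated stand-ins; quantities that depend on
  their details (Table-5-style synapse counts, absolute E/I ratios,
  holding currents) are reproduced qualitatively, not numerically.
- The synthetic morphology is radially symmetric and unbranched; branch-
  point effects and realistic diameter profiles are absent.
- Exact IVL-state counts of the production sweep are not reproducible at
  desk scale (and depend on the original kinetics); the package tests the
  qualitative orderings instead.
- The equal-proximal/distal excitatory split requires even N_E; odd values
  are representable as scenarios but rejected at selection time.
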